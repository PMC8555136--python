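"""Likelihood-based topology hypothesis tests.

Three families of analysis built on stored per-site log-likelihoods:

* **per-partition ΔpL** — each gene's log-likelihood difference between
  placement hypotheses; the sign says which hypothesis the gene favors.
* **four-cluster likelihood mapping (FcLM)** — quartets drawn one taxon
  per group are scored by ML under the three resolved quartet topologies;
  the relative-likelihood weight triple maps each quartet onto the
  2-simplex, tallied by basin (argmax) and by the 7-region refinement.
  The paraphyly-aware variants prune one of the two subgroups of a
  paraphyletic cluster and rerun the mapping on the four remaining groups.
* **KH / SH / AU tests** — RELL bootstrap of the site log-likelihood
  matrix; the AU test fits multiscale bootstrap proportions to
  z = d·sqrt(r) + c/sqrt(r) by weighted least squares and reports
  p = 1 − Φ(d − c).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alignment import Alignment, PartitionMap
from .likelihood import (
    PruningEngine,
    SiteLogLikMatrix,
    optimize_branch_lengths,
    site_loglik_matrix,
    tree_loglik,
)
from .models import SubstitutionModel
from .trees import Tree
from .alphabet import Alphabet

__all__ = [
    "DeltaPLTable",
    "per_partition_delta_pl",
    "count_favoring",
    "FcLMResult",
    "fclm",
    "fclm_paraphyly_variants",
    "rell_resample",
    "TopologyTestReport",
    "topology_test_suite",
]

_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Per-partition log-likelihood differences
# ---------------------------------------------------------------------------

@dataclass
class DeltaPLTable:
    """Per-gene log-likelihoods under each hypothesis plus ΔpL columns."""

    table: pd.DataFrame
    tree_names: list[str]
    pairs: list[tuple[str, str]]
    totals: dict
    fitted_trees: dict = field(default_factory=dict)

    def delta(self, pair: tuple[str, str]) -> np.ndarray:
        a, b = pair
        return self.table[f"delta_{a}_{b}"].to_numpy()

    def ranked(self, pair: tuple[str, str]) -> pd.DataFrame:
        """Genes sorted by descending ΔpL (ranked-distribution plotting)."""
        a, b = pair
        return self.table.sort_values(
            f"delta_{a}_{b}", ascending=False
        ).reset_index(drop=True)


def per_partition_delta_pl(
    aln: Alignment,
    parts: PartitionMap,
    trees: "dict[str, Tree]",
    model: SubstitutionModel,
    optimize: bool = True,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    tol: float = 1e-6,
    max_cycles: int = 20,
) -> DeltaPLTable:
    """Score every gene against each hypothesis tree.

    Branch lengths are, by default, optimized per tree on the full matrix
    once; per-gene log-likelihoods are then read off the fixed trees. With
    ``optimize=False`` the supplied branch lengths are used as-is.
    """
    parts.validate_against(aln)
    if len(parts) == 0:
        raise ValueError("empty partition map")
    names = list(trees)
    if pairs is None:
        pairs = [(names[0], other) for other in names[1:]]
    fitted = {}
    for name in names:
        t = trees[name]
        fitted[name] = (
            optimize_branch_lengths(t, aln, model, tol=tol, max_cycles=max_cycles)
            if optimize
            else t
        )
    per_site = {n: tree_loglik(fitted[n], aln, model)[1] for n in names}
    rows = {"gene": parts.names}
    bounds = [(p.start, p.end) for p in parts]
    for n in names:
        v = per_site[n]
        rows[f"lnl_{n}"] = [float(v[s:e].sum()) for s, e in bounds]
    df = pd.DataFrame(rows)
    for a, b in pairs:
        df[f"delta_{a}_{b}"] = df[f"lnl_{a}"] - df[f"lnl_{b}"]
    totals = {n: float(per_site[n].sum()) for n in names}
    return DeltaPLTable(df, names, list(pairs), totals, fitted)


def count_favoring(
    table: DeltaPLTable, pair: tuple[str, str], tie_tol: float = _TIE_TOL
) -> tuple[int, int, int]:
    """Sign-based gene counts (favor first, favor second, ties)."""
    if tuple(pair) not in [tuple(p) for p in table.pairs]:
        raise KeyError(f"pair {pair} not present in table")
    d = table.delta(tuple(pair))
    ties = np.abs(d) <= tie_tol
    return (
        int(((d > 0) & ~ties).sum()),
        int(((d < 0) & ~ties).sum()),
        int(ties.sum()),
    )


# ---------------------------------------------------------------------------
# Four-cluster likelihood mapping
# ---------------------------------------------------------------------------

def _quartet_trees(a: str, b: str, c: str, d: str, init: float = 0.1):
    """The three resolved unrooted quartet topologies over (a, b, c, d)."""
    from .trees import Node, Tree as _Tree

    def make(p1, p2, q1, q2):
        root = Node()
        cherry = Node(length=init)
        for lab in (p1, p2):
            cherry.add_child(Node(lab, length=init))
        root.add_child(cherry)
        root.add_child(Node(q1, length=init))
        root.add_child(Node(q2, length=init))
        return _Tree(root)

    return [
        make(a, b, c, d),  # pairing 0: (a,b)|(c,d)
        make(a, c, b, d),  # pairing 1: (a,c)|(b,d)
        make(a, d, b, c),  # pairing 2: (a,d)|(b,c)
    ]


_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass
class FcLMResult:
    group_names: tuple
    quartets: list
    weights: np.ndarray  # (n_quartets, 3)
    n_dropped: int
    seed: int

    @property
    def n_quartets(self) -> int:
        return len(self.quartets)

    @property
    def basins(self) -> np.ndarray:
        return self.weights.argmax(axis=1)

    def pairing_label(self, j: int) -> str:
        (i1, i2), (i3, i4) = _PAIRINGS[j]
        g = self.group_names
        return f"{g[i1]}+{g[i2]} | {g[i3]}+{g[i4]}"

    def basin_counts(self) -> dict:
        b = self.basins
        return {self.pairing_label(j): int((b == j).sum()) for j in range(3)}

    def basin_percent(self) -> dict:
        n = max(self.n_quartets, 1)
        return {k: 100.0 * v / n for k, v in self.basin_counts().items()}

    @property
    def regions7(self) -> np.ndarray:
        """Region code per quartet: 0-2 corners, 3-5 edges (01, 02, 12), 6
        center. Corner j iff w_j >= 2/3; else an edge iff the smallest
        weight <= 1/6 and the two largest are unambiguous; else center."""
        out = np.empty(self.n_quartets, dtype=int)
        for i, w in enumerate(self.weights):
            order = np.argsort(w)[::-1]
            if w[order[0]] >= 2.0 / 3.0:
                out[i] = order[0]
            elif w[order[2]] <= 1.0 / 6.0 and w[order[1]] > w[order[2]]:
                pair = tuple(sorted(order[:2]))
                out[i] = 3 + {(0, 1): 0, (0, 2): 1, (1, 2): 2}[pair]
            else:
                out[i] = 6
        return out

    def region7_counts(self) -> dict:
        r = self.regions7
        labels = (
            [f"corner:{self.pairing_label(j)}" for j in range(3)]
            + ["edge:01", "edge:02", "edge:12", "center"]
        )
        return {lab: int((r == k).sum()) for k, lab in enumerate(labels)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.weights, columns=["w1", "w2", "w3"]
        )
        for k in range(4):
            df.insert(k, f"taxon{k + 1}", [q[k] for q in self.quartets])
        df["basin"] = [self.pairing_label(j) for j in self.basins]
        return df


def _normalize_groups(groups, names=None):
    if isinstance(groups, dict):
        names = tuple(groups)
        sets = [tuple(groups[k]) for k in names]
    else:
        sets = [tuple(g) for g in groups]
        names = tuple(names) if names else tuple(
            f"group{i + 1}" for i in range(len(sets))
        )
    return names, sets


def fclm(
    aln: Alignment,
    groups,
    model: SubstitutionModel,
    max_quartets: int = 1000,
    seed: int = 0,
    min_sites: int = 10,
    group_names=None,
) -> FcLMResult:
    """Four-cluster likelihood mapping over four disjoint taxon groups.

    Quartets (one taxon per group) are enumerated exhaustively, or sampled
    uniformly without replacement when more than ``max_quartets`` exist.
    Each quartet is scored on its own columns (sites where all four taxa
    carry data), branch lengths optimized per quartet topology; posterior
    weights are the normalized relative likelihoods. Quartets with fewer
    than ``min_sites`` usable sites are dropped and tallied.
    """
    names, sets = _normalize_groups(groups, group_names)
    if len(sets) != 4:
        raise ValueError("FcLM needs exactly four groups")
    flat = [t for g in sets for t in g]
    if len(set(flat)) != len(flat):
        raise ValueError("groups must be disjoint")
    for g, name in zip(sets, names):
        if not g:
            raise ValueError(f"group {name} is empty")
        missing = set(g) - set(aln.labels)
        if missing:
            raise ValueError(f"taxa not in alignment: {sorted(missing)}")
    combos = list(itertools.product(*sets))
    rng = np.random.default_rng(seed)
    if len(combos) > max_quartets:
        idx = rng.choice(len(combos), size=max_quartets, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    kept, weights = [], []
    n_dropped = 0
    for quartet in combos:
        sub = aln.subset_taxa(list(quartet))
        usable = ~np.any(
            aln.alphabet.is_fully_ambiguous(sub.codes), axis=0
        )
        if usable.sum() < min_sites:
            n_dropped += 1
            continue
        qaln = sub.subset_sites(np.flatnonzero(usable))
        lnls = np.empty(3)
        for j, qt in enumerate(_quartet_trees(*quartet)):
            eng = PruningEngine(qt, qaln, model)
            lnls[j] = eng.optimize_branch_lengths(tol=1e-4, max_cycles=8)
        w = np.exp(lnls - lnls.max())
        kept.append(quartet)
        weights.append(w / w.sum())
    weights = (
        np.array(weights) if weights else np.empty((0, 3))
    )
    return FcLMResult(names, kept, weights, n_dropped, seed)


def fclm_paraphyly_variants(
    aln: Alignment,
    group1,
    group2a,
    group2b,
    group3,
    model: SubstitutionModel,
    max_quartets: int = 1000,
    seed: int = 0,
    outgroup=None,
) -> tuple[FcLMResult, FcLMResult]:
    """The two FcLM runs for a paraphyletic second cluster.

    Variant A drops all group-2b taxa and maps (group1, group2a, group3,
    outgroup); variant B symmetrically drops group 2a. The outgroup
    cluster defaults to every alignment taxon outside the four groups.
    """
    used = set(group1) | set(group2a) | set(group2b) | set(group3)
    if outgroup is None:
        outgroup = [t for t in aln.labels if t not in used]
    if not outgroup:
        raise ValueError("no outgroup taxa available for the FcLM variants")
    keep_a = [t for t in aln.labels if t not in set(group2b)]
    keep_b = [t for t in aln.labels if t not in set(group2a)]
    without_2b = fclm(
        aln.subset_taxa(keep_a),
        {
            "group1": group1,
            "group2a": group2a,
            "group3": group3,
            "outgroup": outgroup,
        },
        model,
        max_quartets=max_quartets,
        seed=seed,
    )
    without_2a = fclm(
        aln.subset_taxa(keep_b),
        {
            "group1": group1,
            "group2b": group2b,
            "group3": group3,
            "outgroup": outgroup,
        },
        model,
        max_quartets=max_quartets,
        seed=seed + 1,
    )
    return without_2b, without_2a


# ---------------------------------------------------------------------------
# RELL resampling and the KH / SH / AU tests
# ---------------------------------------------------------------------------

def rell_resample(
    site_ll: SiteLogLikMatrix,
    scale: float = 1.0,
    replicates: int = 1000,
    seed: Union[int, np.random.Generator] = 0,
) -> np.ndarray:
    """Per-replicate total log-likelihood per tree, (n_trees, replicates).

    Each replicate draws round(scale × n_sites) site indices with
    replacement and sums the stored per-site values; nothing is
    re-optimized.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    m = site_ll.n_sites
    if m == 0:
        raise ValueError("empty site log-likelihood matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_rep = max(1, int(round(scale * m)))
    out = np.empty((len(site_ll.tree_names), replicates))
    chunk = max(1, int(4e6 // m_rep))
    vals = site_ll.values
    for lo in range(0, replicates, chunk):
        hi = min(lo + chunk, replicates)
        idx = rng.integers(0, m, size=(hi - lo, m_rep))
        out[:, lo:hi] = vals[:, idx].sum(axis=2)
    return out


@dataclass
class TopologyTestReport:
    """Per-tree totals, differences to the best tree, and test p-values."""

    table: pd.DataFrame
    replicates: int
    scales: tuple
    seed: int

    def p_value(self, tree: str, test: str) -> float:
        return float(self.table.loc[self.table.tree == tree, f"p_{test}"].iloc[0])


_DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


def topology_test_suite(
    site_ll: SiteLogLikMatrix,
    replicates: int = 1000,
    scales: Sequence[float] = _DEFAULT_SCALES,
    seed: int = 0,
) -> TopologyTestReport:
    """KH, SH, and AU tests from a site log-likelihood matrix.

    KH: one-sided pairwise test of each tree against the ML tree, with a
    centered RELL null at scale 1. SH: joint centered-maximum null. AU:
    multiscale bootstrap proportions, probit-transformed and fitted by
    weighted least squares to d·sqrt(r) + c/sqrt(r); p = 1 − Φ(d − c).
    Bootstrap proportions are clamped to [1/(2B), 1 − 1/(2B)].
    """
    ntrees = len(site_ll.tree_names)
    if ntrees < 2:
        raise ValueError("need at least two trees")
    rng = np.random.default_rng(seed)
    totals = site_ll.totals()
    best = int(np.argmax(totals))
    obs = totals[best] - totals  # >= 0

    # --- KH / SH at scale 1
    rep = rell_resample(site_ll, 1.0, replicates, rng)
    centered = rep - rep.mean(axis=1, keepdims=True)
    p_kh = np.empty(ntrees)
    for t in range(ntrees):
        if t == best:
            p_kh[t] = 1.0
        else:
            null = centered[best] - centered[t]
            p_kh[t] = float((null >= obs[t] - _TIE_TOL).mean())
    mmax = centered.max(axis=0)
    p_sh = np.array(
        [float(((mmax - centered[t]) >= obs[t] - _TIE_TOL).mean())
         for t in range(ntrees)]
    )

    # --- AU multiscale bootstrap
    scales = tuple(float(s) for s in scales)
    bp = np.empty((ntrees, len(scales)))
    for si, r in enumerate(scales):
        rr = rell_resample(site_ll, r, replicates, rng)
        mx = rr.max(axis=0)
        ties = rr >= mx[None, :] - _TIE_TOL
        bp[:, si] = (ties / ties.sum(axis=0, keepdims=True)).sum(axis=1) / replicates
    never_best = bp.max(axis=1) <= 0.0
    floor = 1.0 / (2.0 * replicates)
    bp_c = np.clip(bp, floor, 1.0 - floor)
    z = norm.ppf(1.0 - bp_c)
    sqrt_r = np.sqrt(np.asarray(scales))
    X = np.column_stack([sqrt_r, 1.0 / sqrt_r])
    p_au = np.empty(ntrees)
    au_d = np.full(ntrees, np.nan)
    au_c = np.full(ntrees, np.nan)
    au_rss = np.full(ntrees, np.nan)
    degenerate = np.zeros(ntrees, dtype=bool)
    half = 0.5 / replicates
    for t in range(ntrees):
        # scales where the proportion saturates at 0 or 1 carry no curvature
        # information; they are excluded from the probit fit
        usable = (bp[t] > half) & (bp[t] < 1.0 - half)
        if usable.sum() < 2:
            degenerate[t] = True
            p_au[t] = floor if bp[t].max() < 0.5 else 1.0 - floor
            continue
        zu, xu, bu = z[t][usable], X[usable], bp_c[t][usable]
        w = replicates * norm.pdf(zu) ** 2 / (bu * (1.0 - bu))
        wx = xu * w[:, None]
        beta, *_ = np.linalg.lstsq(wx.T @ xu, wx.T @ zu, rcond=None)
        d, c = float(beta[0]), float(beta[1])
        au_d[t], au_c[t] = d, c
        au_rss[t] = float(w @ (zu - xu @ beta) ** 2)
        p_au[t] = float(1.0 - norm.cdf(d - c))
    p_au[never_best] = floor

    flags = []
    for t in range(ntrees):
        f = []
        if never_best[t]:
            f.append("never-best")
        elif degenerate[t]:
            f.append("saturated-bp")
        if t != best and abs(obs[t]) <= _TIE_TOL:
            f.append("tie-with-best")
        flags.append(",".join(f))
    table = pd.DataFrame(
        {
            "tree": site_ll.tree_names,
            "logL": totals,
            "delta": obs,
            "p_KH": p_kh,
            "p_SH": p_sh,
            "p_AU": p_au,
            "au_d": au_d,
            "au_c": au_c,
            "au_fit_rss": au_rss,
            "flags": flags,
        }
    )
    return TopologyTestReport(table, replicates, scales, seed)
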