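"""Felsenstein pruning likelihoods and branch-length / parameter fitting.

The engine compresses alignment columns to unique site patterns, runs the
postorder pruning recursion over discrete rate categories with per-node
scaling factors accumulated in log space, and exposes:

* :func:`tree_loglik` — total and per-site log-likelihoods;
* :func:`optimize_branch_lengths` — cyclic Brent optimization of each
  branch against cached inside/outside partial vectors;
* :func:`optimize_model_parameters` — fitting of gamma shape, equilibrium
  frequencies, or binary trait rates;
* :func:`site_loglik_matrix` — the tree × site matrix feeding the
  resampling topology tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .alignment import Alignment
from .models import SubstitutionModel
from .trees import Node, Tree, TreeError

__all__ = [
    "PruningEngine",
    "tree_loglik",
    "optimize_branch_lengths",
    "optimize_model_parameters",
    "site_loglik_matrix",
    "SiteLogLikMatrix",
]

_MIN_BRANCH = 1e-8
_MAX_BRANCH = 50.0


def _compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, per-site pattern index, and pattern counts."""
    patterns, inverse, counts = np.unique(
        codes, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, inverse.ravel(), counts


class PruningEngine:
    """Pruning-algorithm likelihood for one tree/alignment/model triple."""

    def __init__(self, tree: Tree, aln: Alignment, model: SubstitutionModel):
        if aln.alphabet.name != model.alphabet.name:
            raise ValueError("alignment and model alphabets differ")
        self.tree = tree.copy()
        self.model = model
        self.aln = aln
        missing = tree.taxon_set() - set(aln.labels)
        if missing:
            raise TreeError(
                f"taxa in tree but not in alignment: {sorted(missing)}"
            )
        order = [n.label for n in self.tree.tips()]
        codes = np.stack([aln.row(lab) for lab in order])
        self.patterns, self.pattern_index, self.pattern_counts = _compress(codes)
        self.n_patterns = self.patterns.shape[1]
        # postorder node bookkeeping
        self.nodes: list[Node] = list(self.tree.postorder())
        self.node_index = {id(n): i for i, n in enumerate(self.nodes)}
        tip_row = {lab: i for i, lab in enumerate(order)}
        self.tip_pattern = {
            id(n): self.patterns[tip_row[n.label]] for n in self.tree.tips()
        }
        for n in self.nodes[:-1]:  # all but root need a branch length
            if n.length is None:
                raise TreeError(f"missing branch length above {n.label!r}")
        self.rates, self.weights = model.category_rates_weights
        self.code_matrix = model.alphabet.code_matrix  # (codes, states)

    # -- plumbing ------------------------------------------------------
    def branch_lengths(self) -> np.ndarray:
        return np.array([n.length for n in self.nodes[:-1]], dtype=float)

    def set_branch_lengths(self, lengths: np.ndarray) -> None:
        for n, t in zip(self.nodes[:-1], lengths):
            n.length = float(t)

    def _edge_pmats(self, lengths: np.ndarray) -> np.ndarray:
        """(n_edges, n_cat, n, n) transition matrices."""
        ts = np.multiply.outer(np.asarray(lengths), self.rates)
        return self.model.transition_matrices(ts)

    def _tip_contrib(self, pmat: np.ndarray, codes: np.ndarray) -> np.ndarray:
        """(n_cat, n_states, n_patterns) child contribution for a tip edge."""
        # pmat (cat, n, n) @ compat (codes, n)^T then gather pattern codes
        lookup = pmat @ self.code_matrix.T  # (cat, n, n_codes)
        return lookup[:, :, codes]

    def _down_pass(
        self, lengths: Optional[np.ndarray] = None
    ) -> tuple[dict, dict]:
        """Inside (below-node) partials and per-node log scale factors."""
        if lengths is None:
            lengths = self.branch_lengths()
        pmats = self._edge_pmats(lengths)
        partial: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        for n in self.nodes:
            if n.is_tip:
                continue
            acc = None
            scale = np.zeros(self.n_patterns)
            for child in n.children:
                ei = self.node_index[id(child)]
                pm = pmats[ei]
                if child.is_tip:
                    contrib = self._tip_contrib(pm, self.tip_pattern[id(child)])
                else:
                    contrib = pm @ partial[id(child)]
                    scale += logscale[id(child)]
                acc = contrib if acc is None else acc * contrib
            mx = acc.max(axis=(0, 1))
            safe = np.where(mx > 0, mx, 1.0)
            acc /= safe
            scale += np.where(mx > 0, np.log(safe), -np.inf)
            partial[id(n)] = acc
            logscale[id(n)] = scale
        return partial, logscale

    def pattern_logliks(
        self, lengths: Optional[np.ndarray] = None
    ) -> np.ndarray:
        root = self.nodes[-1]
        pi = self.model.frequencies
        if root.is_tip:  # degenerate single-taxon tree
            lik = self.code_matrix[self.tip_pattern[id(root)]] @ pi
            return np.log(lik)
        partial, logscale = self._down_pass(lengths)
        lik = np.einsum(
            "c,i,cip->p", self.weights, pi, partial[id(root)]
        )
        with np.errstate(divide="ignore"):
            return np.log(lik) + logscale[id(root)]

    def site_logliks(self) -> np.ndarray:
        return self.pattern_logliks()[self.pattern_index]

    def loglik(self) -> float:
        return float(self.pattern_logliks() @ self.pattern_counts)

    # -- branch-length optimization ------------------------------------
    def _down_partials(self):
        """Inside partials D and log scales for every node (tips included),
        plus S_v = P_v(t_v) D_v for every edge, at the current lengths."""
        pmats = self._edge_pmats(self.branch_lengths())
        ncat, nst = len(self.rates), self.model.alphabet.n_states
        D: dict[int, np.ndarray] = {}
        Dsc: dict[int, np.ndarray] = {}
        S: dict[int, np.ndarray] = {}
        for n in self.nodes:
            if n.is_tip:
                D[id(n)] = np.broadcast_to(
                    self.code_matrix[self.tip_pattern[id(n)]].T,
                    (ncat, nst, self.n_patterns),
                )
                Dsc[id(n)] = np.zeros(self.n_patterns)
            else:
                acc = None
                scale = np.zeros(self.n_patterns)
                for child in n.children:
                    s = S[id(child)]
                    scale += Dsc[id(child)]
                    acc = s if acc is None else acc * s
                mx = acc.max(axis=(0, 1))
                safe = np.where(mx > 0, mx, 1.0)
                acc = acc / safe
                scale = scale + np.where(mx > 0, np.log(safe), -np.inf)
                D[id(n)] = acc
                Dsc[id(n)] = scale
            if n.parent is not None:
                S[id(n)] = pmats[self.node_index[id(n)]] @ D[id(n)]
        return D, Dsc, S

    @staticmethod
    def _rescaled(acc: np.ndarray, scale: np.ndarray):
        mx = acc.max(axis=(0, 1))
        safe = np.where(mx > 0, mx, 1.0)
        return acc / safe, scale + np.where(mx > 0, np.log(safe), -np.inf)

    def _edge_loglik(self, t, a, d, const_scale) -> float:
        pm = self.model.transition_matrices(np.asarray(t) * self.rates)
        lik = np.einsum("c,cip,cip->p", self.weights, a, np.matmul(pm, d))
        with np.errstate(divide="ignore"):
            site = np.log(lik) + const_scale
        return float(site @ self.pattern_counts)

    def _optimize_cycle(self, xatol: float = 1e-6) -> None:
        """One sweep: fresh inside partials, then a preorder pass that
        builds outside partials with already-updated ancestor and sibling
        branch lengths and Brent-optimizes each edge in place."""
        D, Dsc, S = self._down_partials()
        A: dict[int, np.ndarray] = {}
        Asc: dict[int, np.ndarray] = {}
        ncat, nst = len(self.rates), self.model.alphabet.n_states
        pi = self.model.frequencies
        for n in reversed(self.nodes):  # parents before children
            if n.parent is None:
                base = np.broadcast_to(
                    pi[None, :, None], (ncat, nst, self.n_patterns)
                )
                base_sc = np.zeros(self.n_patterns)
            else:
                pm = self.model.transition_matrices(
                    np.asarray(n.length) * self.rates
                )
                base = np.matmul(pm.transpose(0, 2, 1), A[id(n)])
                base, base_sc = self._rescaled(base, Asc[id(n)])
            for child in n.children:
                acc = base
                scale = base_sc.copy()
                for sib in n.children:
                    if sib is child:
                        continue
                    acc = acc * S[id(sib)]
                    scale += Dsc[id(sib)]
                a, asc = self._rescaled(acc, scale)
                A[id(child)], Asc[id(child)] = a, asc
                const = Dsc[id(child)] + asc
                d = D[id(child)]
                cur = self._edge_loglik(child.length, a, d, const)
                res = minimize_scalar(
                    lambda t: -self._edge_loglik(t, a, d, const),
                    bounds=(_MIN_BRANCH, _MAX_BRANCH),
                    method="bounded",
                    options={"xatol": xatol},
                )
                if not np.isfinite(res.fun):
                    raise ValueError(
                        "non-finite likelihood while optimizing branch "
                        f"above {child.label!r}"
                    )
                if -res.fun > cur:
                    child.length = float(res.x)
                    S[id(child)] = (
                        self.model.transition_matrices(
                            np.asarray(child.length) * self.rates
                        )
                        @ d
                    )

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_cycles: int = 20, xatol: float = 1e-6
    ) -> float:
        best = self.loglik()
        if not np.isfinite(best):
            raise ValueError("non-finite starting log-likelihood")
        best_lengths = self.branch_lengths()
        for _ in range(max_cycles):
            self._optimize_cycle(xatol)
            new = self.loglik()
            if new > best:
                improved = new - best
                best = new
                best_lengths = self.branch_lengths()
                if improved < tol:
                    break
            else:
                break
        self.set_branch_lengths(best_lengths)
        return best


# ---------------------------------------------------------------------------
# Public functional interface
# ---------------------------------------------------------------------------

def tree_loglik(
    tree: Tree, aln: Alignment, model: SubstitutionModel
) -> tuple[float, np.ndarray]:
    """Total log-likelihood and the per-site log-likelihood vector.

    The total is computed as the sum of the per-site vector, so the two are
    consistent by construction.
    """
    engine = PruningEngine(tree, aln, model)
    per_site = engine.site_logliks()
    return float(per_site.sum()), per_site


def optimize_branch_lengths(
    tree: Tree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_cycles: int = 20,
) -> Tree:
    """Maximum-likelihood branch lengths by cyclic per-branch Brent search.

    Returns a new tree whose log-likelihood is >= the input tree's.
    """
    engine = PruningEngine(tree, aln, model)
    engine.optimize_branch_lengths(tol=tol, max_cycles=max_cycles)
    return engine.tree.copy()


def _with_frequencies(model: SubstitutionModel, logits: np.ndarray):
    z = np.concatenate([[0.0], logits])
    z -= z.max()
    f = np.exp(z)
    return model.replace(frequencies=f / f.sum())


def optimize_model_parameters(
    tree: Tree,
    aln: Alignment,
    model: SubstitutionModel,
    free: Iterable[str] = (),
) -> SubstitutionModel:
    """Fit a subset of {"gamma_shape", "frequencies", "binary_rates"}.

    The returned model's likelihood on (tree, aln) is never below the
    input model's.
    """
    if aln.n_sites == 0:
        raise ValueError("empty alignment")
    free = set(free)
    allowed = {"gamma_shape", "frequencies", "binary_rates"}
    if free - allowed:
        raise ValueError(f"unknown free parameters: {sorted(free - allowed)}")
    if not free:
        return model

    def score(m: SubstitutionModel) -> float:
        return PruningEngine(tree, aln, m).loglik()

    start_ll = score(model)
    fitted = model

    if "gamma_shape" in free:
        res = minimize_scalar(
            lambda a: -score(fitted.replace(gamma_shape=float(a))),
            bounds=(0.02, 100.0),
            method="bounded",
            options={"xatol": 1e-4},
        )
        fitted = fitted.replace(gamma_shape=float(res.x))

    if "frequencies" in free:
        x0 = np.log(fitted.frequencies[1:] / fitted.frequencies[0])
        res = minimize(
            lambda x: -score(_with_frequencies(fitted, x)),
            x0,
            method="L-BFGS-B",
        )
        fitted = _with_frequencies(fitted, res.x)

    if "binary_rates" in free:
        if fitted.alphabet.n_states != 2:
            raise ValueError("binary_rates requires a two-state model")
        from .models import binary_model

        def score_rates(logq):
            q01, q10 = np.exp(logq)
            m = binary_model(
                q01, q10, gamma_shape=fitted.gamma_shape,
                n_categories=fitted.n_categories,
            )
            return -score(m)

        cur = fitted.rate_matrix
        x0 = np.log([max(cur[0, 1], 1e-3), max(cur[1, 0], 1e-3)])
        res = minimize(
            score_rates, x0, method="L-BFGS-B",
            bounds=[(np.log(1e-6), np.log(1e3))] * 2,
        )
        q01, q10 = np.exp(res.x)
        fitted = binary_model(
            q01, q10, gamma_shape=fitted.gamma_shape,
            n_categories=fitted.n_categories,
        )

    return fitted if score(fitted) >= start_ll else model


# ---------------------------------------------------------------------------
# Site log-likelihood matrices for the resampling tests
# ---------------------------------------------------------------------------

@dataclass
class SiteLogLikMatrix:
    """Per-tree, per-site natural-log likelihoods."""

    tree_names: list[str]
    values: np.ndarray  # (n_trees, n_sites)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.tree_names):
            raise ValueError("values must be (n_trees, n_sites)")

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tree_names)


def site_loglik_matrix(
    trees: "dict[str, Tree]", aln: Alignment, model: SubstitutionModel
) -> SiteLogLikMatrix:
    names = list(trees)
    rows = [tree_loglik(trees[k], aln, model)[1] for k in names]
    return SiteLogLikMatrix(names, np.stack(rows))
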