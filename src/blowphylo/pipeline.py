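"""Supermatrix utilities, run configuration, and end-to-end orchestration.

The assembly helpers re-implement the conventions used when building
transcriptomic supermatrices: gene-wise concatenation with ambiguity
padding, the Ca completeness statistic (fraction of fully specified
cells), codon-position subsetting (NT2 / NT12), and terminal-gap recoding
to N/X. :func:`run_analysis` drives every stage from a seeded
:class:`RunConfig` and writes deterministic TSV reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import asr as asr_mod
from .alignment import Alignment, Partition, PartitionMap
from .alphabet import AA, DNA
from .likelihood import site_loglik_matrix
from .models import (
    SubstitutionModel,
    binary_model,
    dayhoff6_model,
    dayhoff6_recode,
    jc,
    lg,
    poisson_aa,
)
from .parsimony import annotate_support, jackknife_support, parsimony_best_tree
from .quartets import exact_quartet_species_tree
from .simulate import (
    backbone_fixture,
    simulate_binary_trait,
    simulate_gene_trees_msc,
    simulate_supermatrix,
    study_gene_specs,
)
from .topotests import (
    count_favoring,
    fclm_paraphyly_variants,
    per_partition_delta_pl,
    topology_test_suite,
)
from .trees import Tree, restrict_to_taxa, write_newick

__all__ = [
    "concat_supermatrix",
    "completeness_ca",
    "codon_subsets",
    "mask_terminal_gaps",
    "RunConfig",
    "run_analysis",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Supermatrix assembly and diagnostics
# ---------------------------------------------------------------------------

_AMBIG = {"dna": "N", "aa": "X", "dayhoff6": "X", "binary": "?"}


def concat_supermatrix(
    gene_alignments: Mapping[str, Alignment]
) -> tuple[Alignment, PartitionMap]:
    """Concatenate per-gene alignments in gene-name order.

    The taxon set is the union over genes (sorted); taxa absent from a
    gene are padded with the alphabet's missing symbol.
    """
    names = list(gene_alignments)
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names")
    names.sort()
    alphabet = gene_alignments[names[0]].alphabet
    taxa = sorted({t for a in gene_alignments.values() for t in a.labels})
    pad = alphabet.code_of[_AMBIG[alphabet.name]]
    blocks, parts, pos = [], [], 0
    for name in names:
        aln = gene_alignments[name]
        if aln.alphabet.name != alphabet.name:
            raise ValueError(f"gene {name} uses a different alphabet")
        block = np.full((len(taxa), aln.n_sites), pad, dtype=np.int16)
        for ti, t in enumerate(taxa):
            if t in aln.labels:
                block[ti] = aln.row(t)
        blocks.append(block)
        parts.append(Partition(name, pos, pos + aln.n_sites))
        pos += aln.n_sites
    return Alignment(taxa, np.concatenate(blocks, axis=1), alphabet), PartitionMap(parts)


def split_supermatrix(
    aln: Alignment, parts: PartitionMap, drop_all_missing: bool = True
) -> dict:
    """Inverse of concatenation: per-gene alignments, optionally dropping
    taxa that are entirely missing within a gene."""
    out = {}
    for p in parts:
        block = aln.codes[:, p.start : p.end]
        if drop_all_missing:
            present = ~np.all(
                aln.alphabet.is_fully_ambiguous(block), axis=1
            )
        else:
            present = np.ones(len(aln.labels), dtype=bool)
        labels = [t for t, keep in zip(aln.labels, present) if keep]
        out[p.name] = Alignment(labels, block[present].copy(), aln.alphabet)
    return out


def completeness_ca(aln: Alignment) -> float:
    """Fraction of matrix cells holding a fully specified character."""
    if aln.codes.size == 0:
        raise ValueError("empty alignment")
    return float(aln.alphabet.is_certain(aln.codes).mean())


def codon_subsets(
    nt_aln: Alignment, parts: PartitionMap, which: str
) -> tuple[Alignment, PartitionMap]:
    """Extract NT2 (2nd positions) or NT12 (1st+2nd) codon subsets.

    Reading frames start at each gene's first column; every partition
    length must be divisible by 3.
    """
    offsets = {"NT2": (1,), "NT12": (0, 1)}.get(which.upper())
    if offsets is None:
        raise ValueError("which must be 'NT2' or 'NT12'")
    parts.validate_against(nt_aln)
    cols, new_parts, pos = [], [], 0
    for p in parts:
        if p.length % 3 != 0:
            raise ValueError(
                f"partition {p.name} has length {p.length}, not divisible by 3"
            )
        gene_cols = [
            c
            for c in range(p.start, p.end)
            if (c - p.start) % 3 in offsets
        ]
        cols.extend(gene_cols)
        new_parts.append(Partition(p.name, pos, pos + len(gene_cols), p.model))
        pos += len(gene_cols)
    sub = nt_aln.subset_sites(np.asarray(cols, dtype=int))
    return sub, PartitionMap(new_parts)


def mask_terminal_gaps(aln: Alignment) -> Alignment:
    """Replace leading/trailing gap runs with N (nucleotide) or X (amino
    acid); internal gaps are untouched."""
    if aln.alphabet.name not in ("dna", "aa"):
        raise ValueError("terminal-gap masking applies to DNA or AA data")
    gap = aln.alphabet.code_of["-"]
    repl = aln.alphabet.code_of[_AMBIG[aln.alphabet.name]]
    codes = aln.codes.copy()
    for row in codes:
        nongap = np.flatnonzero(row != gap)
        if nongap.size == 0:
            row[:] = repl
            continue
        row[: nongap[0]] = np.where(
            row[: nongap[0]] == gap, repl, row[: nongap[0]]
        )
        row[nongap[-1] + 1 :] = np.where(
            row[nongap[-1] + 1 :] == gap, repl, row[nongap[-1] + 1 :]
        )
    return Alignment(list(aln.labels), codes, aln.alphabet)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Seeded configuration for a full analysis run."""

    seed: int
    outdir: str
    model: dict = field(default_factory=lambda: {"type": "lg", "gamma_shape": 0.8})
    simulate: dict = field(
        default_factory=lambda: {
            "hypothesis": "T1",
            "n_genes": 30,
            "gene_length": 80,
            "missing_prob": 0.291,
            "rate_sigma": 0.5,
        }
    )
    delta_pl: dict = field(default_factory=lambda: {"enabled": True})
    fclm: dict = field(default_factory=lambda: {"enabled": True, "max_quartets": 100})
    au_test: dict = field(
        default_factory=lambda: {"enabled": True, "replicates": 1000}
    )
    mp_jackknife: dict = field(
        default_factory=lambda: {"enabled": True, "replicates": 100, "deletion": 0.36}
    )
    quartet_tree: dict = field(
        default_factory=lambda: {"enabled": True, "n_loci": 100, "branch_cu": 1.0}
    )
    asr: dict = field(
        default_factory=lambda: {
            "enabled": True,
            "q01": 0.5,
            "q10": 0.5,
            "generations": 2000,
            "burnin": 500,
            "thin": 5,
        }
    )

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("run config requires an explicit seed")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "seed" not in data:
            raise ValueError("run config requires an explicit seed")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _build_model(spec: dict) -> SubstitutionModel:
    kind = spec.get("type", "lg")
    gs = spec.get("gamma_shape")
    k = spec.get("categories", 4)
    if kind == "lg":
        return lg(gamma_shape=gs, n_categories=k)
    if kind == "poisson":
        return poisson_aa(gamma_shape=gs, n_categories=k)
    if kind == "jc":
        return jc(gamma_shape=gs, n_categories=k)
    if kind == "dayhoff6":
        return dayhoff6_model(gamma_shape=gs, n_categories=k)
    raise ValueError(f"unknown model type {kind!r}")


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def run_analysis(config: RunConfig) -> dict:
    """Execute every configured stage; returns a result bundle dict.

    Stage seeds are derived deterministically from the master seed, so two
    runs with equal configs produce byte-identical TSV outputs.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"# config_hash={chash}\tseed={config.seed}\n"
    master = np.random.default_rng(config.seed)
    stage_seed = {
        name: int(master.integers(0, 2**31 - 1))
        for name in (
            "simulate", "fclm", "au_test", "mp_jackknife", "quartet", "asr",
        )
    }
    warnings: list[str] = []
    results: dict = {"config_hash": chash, "seeds": stage_seed}
    timings: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(
                    f"stage {name!r} failed: {exc}; partial outputs kept in "
                    f"{outdir}"
                ) from exc
            timings[name] = time.time() - t0
        return deco

    model = _build_model(config.model)

    # --- data
    sim = config.simulate
    fixture = backbone_fixture(sim.get("hypothesis", "T1"))
    taxa = fixture.tree.tip_labels()
    specs = study_gene_specs(
        taxa,
        n_genes=sim.get("n_genes", 30),
        length=sim.get("gene_length", 80),
        seed=stage_seed["simulate"],
        missing_prob=sim.get("missing_prob", 0.291),
        rate_sigma=sim.get("rate_sigma", 0.5),
    )
    aln, parts = simulate_supermatrix(
        fixture.tree, specs, model, stage_seed["simulate"]
    )
    results["completeness_ca"] = completeness_ca(aln)
    trees = {h: backbone_fixture(h).tree for h in ("T1", "T2", "T3")}

    # --- per-partition delta pL + topology tests (share optimized trees)
    site_ll = None
    if config.delta_pl.get("enabled", True):
        @stage("delta_pl")
        def _():
            nonlocal site_ll
            table = per_partition_delta_pl(aln, parts, trees, model)
            site_ll = site_loglik_matrix(table.fitted_trees, aln, model)
            _write_tsv(table.table, outdir / "delta_pl.tsv", header)
            counts = {}
            for pair in table.pairs:
                counts["_vs_".join(pair)] = count_favoring(table, pair)
            results["delta_pl_totals"] = table.totals
            results["delta_pl_counts"] = counts

    if site_ll is not None and config.au_test.get("enabled", True):
        @stage("au_test")
        def _():
            report = topology_test_suite(
                site_ll,
                replicates=config.au_test.get("replicates", 1000),
                seed=stage_seed["au_test"],
            )
            _write_tsv(report.table, outdir / "topology_tests.tsv", header)
            results["topology_tests"] = report

    # --- FcLM paraphyly variants
    if config.fclm.get("enabled", True):
        @stage("fclm")
        def _():
            g = fixture.groups
            without_2b, without_2a = fclm_paraphyly_variants(
                aln, g["group1"], g["group2a"], g["group2b"], g["group3"],
                model,
                max_quartets=config.fclm.get("max_quartets", 100),
                seed=stage_seed["fclm"],
            )
            for tag, res in (("without2b", without_2b), ("without2a", without_2a)):
                _write_tsv(
                    res.to_frame(), outdir / f"fclm_{tag}.tsv", header
                )
                if res.n_dropped:
                    warnings.append(
                        f"fclm {tag}: {res.n_dropped} quartets dropped"
                    )
            results["fclm"] = {"without2b": without_2b, "without2a": without_2a}

    # --- maximum parsimony on the Dayhoff-recoded matrix
    if config.mp_jackknife.get("enabled", True) and aln.alphabet.name == "aa":
        @stage("mp_jackknife")
        def _():
            recoded = dayhoff6_recode(aln)
            best, score = parsimony_best_tree(
                recoded, seed=stage_seed["mp_jackknife"]
            )
            support = jackknife_support(
                recoded,
                deletion=config.mp_jackknife.get("deletion", 0.36),
                replicates=config.mp_jackknife.get("replicates", 100),
                seed=stage_seed["mp_jackknife"],
                best_tree=best,
            )
            annotated = annotate_support(best, support)
            (outdir / "mp_tree.nwk").write_text(write_newick(annotated) + "\n")
            rows = pd.DataFrame(
                {
                    "split": ["|".join(sorted(s)) for s in sorted(support, key=sorted)],
                    "support_pct": [support[s] for s in sorted(support, key=sorted)],
                }
            )
            _write_tsv(rows, outdir / "mp_support.tsv", header)
            results["mp"] = {"tree": best, "score": score, "support": support}

    # --- quartet-coalescent species tree on a reduced exemplar set
    if config.quartet_tree.get("enabled", True):
        @stage("quartet")
        def _():
            keep = config.quartet_tree.get(
                "taxa",
                ["Chrysomyinae", "Phumosiinae", "Rhiniidae", "Luciliinae",
                 "Ameniinae", "Outgroup"],
            )
            cu = config.quartet_tree.get("branch_cu", 1.0)
            sp = restrict_to_taxa(fixture.tree, keep)
            sp.rooted = True
            for node in sp.postorder():
                if node.parent is not None:
                    node.length = cu
            gene_trees = simulate_gene_trees_msc(
                sp, config.quartet_tree.get("n_loci", 100),
                stage_seed["quartet"],
            )
            optima, score = exact_quartet_species_tree(gene_trees, keep)
            (outdir / "species_tree.nwk").write_text(
                "\n".join(write_newick(t, include_support=False) for t in optima)
                + "\n"
            )
            results["quartet"] = {
                "optima": optima,
                "score": score,
                "true_tree": sp,
            }

    # --- ancestral state of a simulated binary trait
    if config.asr.get("enabled", True):
        @stage("asr")
        def _():
            acfg = config.asr
            trait_sim = simulate_binary_trait(
                fixture.tree, acfg.get("q01", 0.5), acfg.get("q10", 0.5),
                stage_seed["asr"],
            )
            trait = asr_mod.BinaryTrait(trait_sim.tip_states)
            q01, q10, lnl = asr_mod.fit_mk2(fixture.tree, trait)
            ml = asr_mod.marginal_asr(fixture.tree, trait, q01, q10)
            bayes = asr_mod.bbm_asr(
                fixture.tree, trait,
                generations=acfg.get("generations", 2000),
                burnin=acfg.get("burnin", 500),
                thin=acfg.get("thin", 5),
                seed=stage_seed["asr"],
            )
            if bayes.extras["warning"]:
                warnings.append(f"asr: {bayes.extras['warning']}")
            gains, losses, _ = asr_mod.count_origins(fixture.tree, ml)
            rows = []
            for clade in sorted(ml.node_prob, key=lambda c: (len(c), sorted(c))):
                rows.append(
                    {
                        "clade": "|".join(sorted(clade)),
                        "p1_ml": ml.node_prob[clade],
                        "p1_bayes": bayes.node_prob[clade],
                    }
                )
            _write_tsv(pd.DataFrame(rows), outdir / "asr.tsv", header)
            results["asr"] = {
                "q01": q01, "q10": q10, "lnl": lnl,
                "gains": gains, "losses": losses,
                "ml": ml, "bayes": bayes, "truth": trait_sim,
            }

    # --- provenance
    prov = [
        f"config_hash={chash}",
        f"master_seed={config.seed}",
        *(f"seed.{k}={v}" for k, v in stage_seed.items()),
        *(f"warning: {w}" for w in warnings),
        *(f"timing.{k}={v:.2f}s" for k, v in timings.items()),
        f"total={time.time() - t_start:.2f}s",
    ]
    (outdir / "provenance.log").write_text("\n".join(prov) + "\n")
    results["warnings"] = warnings
    return results
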