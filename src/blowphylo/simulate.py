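"""Synthetic-data generators emulating a multi-gene transcriptomic study.

The generators cover the statistical structure the downstream analyses
need: a multi-gene amino-acid supermatrix with per-gene rate variation and
taxon-by-gene missing data, gene trees under the multispecies coalescent,
a binary trait evolved by a two-state CTMC, and the fixed subfamily-level
backbone topologies (T1/T2/T3) with their four-cluster group assignments.

Every generator is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .alignment import Alignment, Partition, PartitionMap
from .models import SubstitutionModel
from .trees import Node, Tree, TreeError, parse_newick

__all__ = [
    "GeneSpec",
    "BackboneFixture",
    "TraitSimulation",
    "simulate_alignment",
    "simulate_supermatrix",
    "simulate_gene_trees_msc",
    "simulate_binary_trait",
    "backbone_fixture",
    "study_gene_specs",
    "BACKBONE_GROUPS",
]

_MISSING_SYMBOL = {"dna": "N", "aa": "X", "dayhoff6": "X", "binary": "?"}


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: Tree,
    model: SubstitutionModel,
    n_sites: int,
    seed: Union[int, np.random.Generator],
) -> Alignment:
    """Evolve ``n_sites`` characters down ``tree`` under ``model``.

    Root states are drawn from the equilibrium frequencies; each site draws
    one rate category; states then evolve branch by branch through the
    transition probabilities.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(seed)
    rates, weights = model.category_rates_weights
    cats = rng.choice(len(rates), size=n_sites, p=weights)
    n = model.alphabet.n_states
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(n, size=n_sites, p=model.frequencies)
    }
    for node in tree.preorder():
        if node.parent is None:
            continue
        if node.length is None:
            raise TreeError(f"missing branch length above {node.label!r}")
        pmats = model.transition_matrices(node.length * rates)  # (cat, n, n)
        rows = pmats[cats, states[id(node.parent)]]  # (n_sites, n)
        u = rng.random(n_sites)
        states[id(node)] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
    tips = tree.tips()
    codes = np.stack([states[id(t)] for t in tips]).astype(np.int16)
    return Alignment([t.label for t in tips], codes, model.alphabet)


@dataclass(frozen=True)
class GeneSpec:
    """One synthetic gene: length, relative rate, and absent taxa."""

    name: str
    length: int
    rate: float = 1.0
    missing_taxa: frozenset = frozenset()

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"gene {self.name}: length must be >= 1")
        if self.rate <= 0:
            raise ValueError(f"gene {self.name}: rate must be positive")


def study_gene_specs(
    taxa: Sequence[str],
    n_genes: int,
    length: int,
    seed: Union[int, np.random.Generator],
    missing_prob: float = 0.291,
    rate_sigma: float = 0.5,
) -> list[GeneSpec]:
    """Gene specifications with the structure of a transcriptomic supermatrix:
    lognormal per-gene rate multipliers (mean 1) and whole-gene taxon
    dropout at probability ``missing_prob`` (default tuned to ~0.709 overall
    completeness); at least one taxon is always retained per gene."""
    rng = _rng(seed)
    specs = []
    width = len(str(n_genes))
    for gi in range(n_genes):
        rate = float(np.exp(rng.normal(-rate_sigma**2 / 2, rate_sigma)))
        missing = frozenset(
            t for t in taxa if rng.random() < missing_prob
        )
        if len(missing) == len(taxa):
            missing = frozenset(list(missing)[1:])
        specs.append(
            GeneSpec(f"gene{gi + 1:0{width}d}", length, rate, missing)
        )
    return specs


def simulate_supermatrix(
    tree: Tree,
    genes: Sequence[GeneSpec],
    model: SubstitutionModel,
    seed: Union[int, np.random.Generator],
) -> tuple[Alignment, PartitionMap]:
    """Concatenate per-gene simulations; rate multipliers scale the tree,
    missing taxa are filled with the alphabet's missing symbol."""
    names = [g.name for g in genes]
    if len(set(names)) != len(names):
        raise ValueError("gene names must be unique")
    rng = _rng(seed)
    gene_seeds = rng.integers(0, 2**31 - 1, size=len(genes))
    taxa = [t.label for t in tree.tips()]
    missing_code = model.alphabet.code_of[_MISSING_SYMBOL[model.alphabet.name]]
    blocks, parts, pos = [], [], 0
    for g, gseed in zip(genes, gene_seeds):
        if set(g.missing_taxa) >= set(taxa):
            raise ValueError(f"gene {g.name} is missing every taxon")
        scaled = tree.copy()
        for node in scaled.postorder():
            if node.length is not None:
                node.length *= g.rate
        aln = simulate_alignment(scaled, model, g.length, int(gseed))
        codes = np.stack([aln.row(t) for t in taxa])
        for ti, t in enumerate(taxa):
            if t in g.missing_taxa:
                codes[ti, :] = missing_code
        blocks.append(codes)
        parts.append(Partition(g.name, pos, pos + g.length))
        pos += g.length
    return (
        Alignment(taxa, np.concatenate(blocks, axis=1), model.alphabet),
        PartitionMap(parts),
    )


# ---------------------------------------------------------------------------
# Multispecies coalescent gene trees
# ---------------------------------------------------------------------------

def simulate_gene_trees_msc(
    species_tree: Tree,
    n_loci: int,
    seed: Union[int, np.random.Generator],
) -> list[Tree]:
    """Gene trees under the multispecies coalescent, one haploid lineage per
    species, species-tree branch lengths in coalescent units.

    Within a branch, each lineage pair coalesces at exponential(1) rate on
    the coalescent-unit time scale; lineages surviving a branch are handed
    to the parent population. Node ages accumulate along the species tree
    (treated as ultrametric in coalescent units).
    """
    if not species_tree.rooted:
        raise TreeError("MSC simulation needs a rooted species tree")
    rng = _rng(seed)
    age: dict[int, float] = {}
    for node in species_tree.postorder():
        if node.is_tip:
            age[id(node)] = 0.0
        else:
            age[id(node)] = max(
                age[id(c)] + (c.length or 0.0) for c in node.children
            )
    out: list[Tree] = []
    for _ in range(n_loci):
        gage: dict[int, float] = {}
        pools: dict[int, list[Node]] = {}
        for node in species_tree.postorder():
            if node.is_tip:
                leaf = Node(node.label)
                gage[id(leaf)] = age[id(node)]
                pool = [leaf]
            else:
                pool = []
                for c in node.children:
                    pool.extend(pools.pop(id(c)))
            start = age[id(node)]
            duration = (
                np.inf if node.parent is None else (node.length or 0.0)
            )
            elapsed = 0.0
            while len(pool) > 1:
                k = len(pool)
                wait = rng.exponential(2.0 / (k * (k - 1)))
                if elapsed + wait > duration:
                    break
                elapsed += wait
                i, j = sorted(rng.choice(k, size=2, replace=False))
                parent = Node()
                gage[id(parent)] = start + elapsed
                for child in (pool[i], pool[j]):
                    parent.add_child(child)
                    child.length = gage[id(parent)] - gage[id(child)]
                pool = [p for idx, p in enumerate(pool) if idx not in (i, j)]
                pool.append(parent)
            pools[id(node)] = pool
        root = pools[id(species_tree.root)][0]
        out.append(Tree(root, rooted=True))
    return out


# ---------------------------------------------------------------------------
# Binary trait evolution
# ---------------------------------------------------------------------------

@dataclass
class TraitSimulation:
    """Tip states, true internal states (keyed by descendant tip set), and
    the realized number of state changes on each branch."""

    tip_states: dict
    node_states: dict
    branch_changes: dict


def _clade_key(node: Node, below: dict) -> frozenset:
    return below[id(node)]


def simulate_binary_trait(
    tree: Tree,
    q01: float,
    q10: float,
    seed: Union[int, np.random.Generator],
) -> TraitSimulation:
    """Evolve a 0/1 trait by event sampling (Gillespie) along each branch.

    The root state is drawn from the stationary distribution
    (q10, q01)/(q01+q10); internal-node states and per-branch change counts
    are returned for recovery scoring.
    """
    if q01 <= 0 or q10 <= 0:
        raise ValueError("trait rates must be positive")
    if not tree.rooted:
        raise TreeError("trait simulation needs a rooted tree")
    rng = _rng(seed)
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children)
            )
    pi1 = q01 / (q01 + q10)
    states: dict[int, int] = {
        id(tree.root): int(rng.random() < pi1)
    }
    tip_states, node_states, branch_changes = {}, {}, {}
    node_states[below[id(tree.root)]] = states[id(tree.root)]
    for node in tree.preorder():
        if node.parent is None:
            continue
        if node.length is None:
            raise TreeError(f"missing branch length above {node.label!r}")
        s = states[id(node.parent)]
        t, changes = 0.0, 0
        while True:
            rate = q01 if s == 0 else q10
            t += rng.exponential(1.0 / rate)
            if t > node.length:
                break
            s = 1 - s
            changes += 1
        states[id(node)] = s
        branch_changes[below[id(node)]] = changes
        if node.is_tip:
            tip_states[node.label] = s
        else:
            node_states[below[id(node)]] = s
    return TraitSimulation(tip_states, node_states, branch_changes)


# ---------------------------------------------------------------------------
# Backbone fixtures: the three placement hypotheses and FcLM groups
# ---------------------------------------------------------------------------

#: One exemplar per subfamily/family; the four-cluster group assignment.
BACKBONE_GROUPS: dict[str, tuple[str, ...]] = {
    "group1": ("Chrysomyinae", "Phumosiinae"),
    "group2a": ("Ameniinae", "Helicoboscinae", "Rhinophoridae"),
    "group2b": ("Rhiniidae", "Bengaliinae"),
    "group3": ("Luciliinae", "Calliphorinae", "Toxotarsinae"),
    "outgroup": ("Outgroup",),
}


@dataclass(frozen=True)
class BackboneFixture:
    hypothesis: str
    tree: Tree
    groups: dict


def backbone_fixture(
    hypothesis: str,
    internal_length: float = 0.05,
    terminal_length: float = 0.2,
) -> BackboneFixture:
    """The subfamily-level backbone for one placement hypothesis.

    T1: Chrysomyinae+Phumosiinae (group 1) sister to all remaining
    calliphorids; T2: Chrysomyinae joins group 3 (Luciliinae +
    Calliphorinae s.l.); T3: Chrysomyinae joins group 2b (Rhiniidae +
    Bengaliinae). The three agree everywhere else.
    """
    t, i = terminal_length, internal_length
    g2a = f"(Ameniinae:{t},(Helicoboscinae:{t},Rhinophoridae:{t}):{i}):{i}"
    g2b = f"(Rhiniidae:{t},Bengaliinae:{t}):{i}"
    g3 = f"(Luciliinae:{t},(Calliphorinae:{t},Toxotarsinae:{t}):{i}):{i}"
    if hypothesis == "T1":
        ingroup = (
            f"((Chrysomyinae:{t},Phumosiinae:{t}):{i},"
            f"({g2a},({g2b},{g3}):{i}):{i}):{i}"
        )
    elif hypothesis == "T2":
        ingroup = (
            f"(Phumosiinae:{t},({g2a},({g2b},"
            f"(Chrysomyinae:{t},{g3}):{i}):{i}):{i}):{i}"
        )
    elif hypothesis == "T3":
        ingroup = (
            f"(Phumosiinae:{t},({g2a},((Chrysomyinae:{t},{g2b}):{i},"
            f"{g3}):{i}):{i}):{i}"
        )
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}; expected T1/T2/T3")
    tree = parse_newick(f"(Outgroup:{t},{ingroup});")
    tree.rooted = True
    return BackboneFixture(hypothesis, tree, dict(BACKBONE_GROUPS))
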