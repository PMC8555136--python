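"""Quartet-score species-tree estimation from gene trees.

The quartet agreement score counts, over gene trees and taxon quadruples,
the induced four-taxon subtrees that match a candidate species tree — the
criterion maximized by summary coalescent methods. At the subfamily-
exemplar scale used here (≤ 9 taxa) the optimum is found by exhaustive
enumeration of all (2n−5)!! unrooted topologies rather than a heuristic.

Gene trees may be rooted or unrooted and may miss taxa (they then simply
contribute fewer quadruples); polytomies contribute no resolved quartets.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .trees import Tree, enumerate_unrooted_topologies, splits, write_newick

__all__ = [
    "induced_quartet",
    "quartet_agreement_score",
    "exact_quartet_species_tree",
    "gene_tree_bootstrap_support",
]

log = logging.getLogger(__name__)


def induced_quartet(
    tree_splits: "set[frozenset]", quad: Sequence[str]
) -> Optional[int]:
    """Resolution of a sorted quadruple: index of the partner of the first
    taxon (0 → second, 1 → third, 2 → fourth), or None if unresolved."""
    q = sorted(quad)
    qset = set(q)
    for s in tree_splits:
        inside = qset & s
        if len(inside) == 2:
            if q[0] in inside:
                partner = (inside - {q[0]}).pop()
            else:
                partner = (qset - inside - {q[0]}).pop()
            return q.index(partner) - 1
    return None


def _quartet_resolutions(tree: Tree) -> dict:
    """Mapping quadruple (frozenset) → resolution index for one tree."""
    tsplits = splits(tree)
    taxa = sorted(tree.taxon_set())
    out = {}
    for quad in itertools.combinations(taxa, 4):
        res = induced_quartet(tsplits, quad)
        if res is not None:
            out[frozenset(quad)] = res
    return out


def quartet_agreement_score(
    species_tree: Tree, gene_trees: Sequence[Tree]
) -> int:
    """Total number of gene-tree quartets agreeing with the species tree."""
    sp_taxa = species_tree.taxon_set()
    sp_res = _quartet_resolutions(species_tree)
    score = 0
    for gt in gene_trees:
        gt_taxa = gt.taxon_set()
        extra = gt_taxa - sp_taxa
        if extra:
            raise ValueError(
                f"gene-tree taxa not in species tree: {sorted(extra)}"
            )
        if len(gt_taxa) < 4:
            log.info("gene tree with < 4 tips contributes no quartets")
            continue
        for quad, res in _quartet_resolutions(gt).items():
            if sp_res.get(quad) == res:
                score += 1
    return score


def _gene_quartet_counts(gene_trees: Sequence[Tree]) -> dict:
    counts: dict = defaultdict(lambda: np.zeros(3, dtype=np.int64))
    for gt in gene_trees:
        if len(gt.taxon_set()) < 4:
            log.info("gene tree with < 4 tips contributes no quartets")
            continue
        for quad, res in _quartet_resolutions(gt).items():
            counts[quad][res] += 1
    return counts


def exact_quartet_species_tree(
    gene_trees: Sequence[Tree], taxa: Iterable[str]
) -> tuple[list, int]:
    """Argmax of the quartet agreement score over every unrooted binary
    topology on ``taxa`` (4–9 taxa); all co-optimal trees are returned."""
    taxa = sorted(set(taxa))
    if not 4 <= len(taxa) <= 9:
        raise ValueError(
            f"exact search supported for 4..9 taxa, got {len(taxa)}"
        )
    for gt in gene_trees:
        extra = gt.taxon_set() - set(taxa)
        if extra:
            raise ValueError(
                f"gene-tree taxa outside the taxon set: {sorted(extra)}"
            )
    counts = _gene_quartet_counts(gene_trees)
    best_trees: list = []
    best_score = -1
    for cand in enumerate_unrooted_topologies(taxa):
        cand_res = _quartet_resolutions(cand)
        score = sum(
            int(counts[quad][res])
            for quad, res in cand_res.items()
            if quad in counts
        )
        if score > best_score:
            best_trees, best_score = [cand], score
        elif score == best_score:
            best_trees.append(cand)
    return best_trees, int(best_score)


def _canonical(tree: Tree) -> str:
    return repr(sorted(tuple(sorted(s)) for s in splits(tree)))


def gene_tree_bootstrap_support(
    replicate_sets: Sequence[Sequence[Tree]],
    taxa: Iterable[str],
    main_tree: Optional[Tree] = None,
) -> dict:
    """Split support for the main quartet species-tree estimate.

    Each replicate set is one bootstrap collection of gene trees; the exact
    search runs per set and a split counts as recovered when every
    co-optimal tree of that set contains it. Without an explicit
    ``main_tree`` the pooled gene trees define the main estimate (first
    co-optimal tree in a canonical order).
    """
    taxa = sorted(set(taxa))
    if main_tree is None:
        pooled = [t for s in replicate_sets for t in s]
        optima, _ = exact_quartet_species_tree(pooled, taxa)
        main_tree = min(optima, key=_canonical)
    target = splits(main_tree)
    hits = {s: 0 for s in target}
    for rep in replicate_sets:
        optima, _ = exact_quartet_species_tree(rep, taxa)
        common = set.intersection(*(splits(t) for t in optima))
        for s in target:
            if s in common:
                hits[s] += 1
    n = len(replicate_sets)
    return {s: 100.0 * h / n for s, h in hits.items()}
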