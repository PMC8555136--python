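"""Fitch maximum parsimony with NNI search and jackknife support.

Intended for Dayhoff-recoded amino-acid matrices (gaps as missing data)
but works over any alphabet: ambiguity sets are used directly as tip state
sets, so all-missing sites cost nothing. The search is plain multi-start
hill climbing over nearest-neighbor interchanges; support comes from
site-deletion jackknife resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .alignment import Alignment
from .trees import Node, Tree, nni_neighbors, splits, unroot

__all__ = [
    "fitch_score",
    "parsimony_search_nni",
    "random_topology",
    "parsimony_best_tree",
    "jackknife_support",
    "annotate_support",
]

log = logging.getLogger(__name__)


def _binary_rooted_view(tree: Tree) -> Tree:
    """Root an unrooted binary tree on its anchor's first edge."""
    t = tree.copy()
    if len(t.root.children) <= 2:
        return t
    first = t.root.children[0]
    t.root.remove_child(first)
    new_root = Node()
    new_root.add_child(first)
    new_root.add_child(t.root)
    return Tree(new_root, rooted=True)


def _state_masks(aln: Alignment) -> np.ndarray:
    """Bitmask of compatible states per character code."""
    cm = aln.alphabet.code_matrix.astype(np.int64)
    return cm @ (1 << np.arange(cm.shape[1], dtype=np.int64))


def _fitch_changes(tree: Tree, aln: Alignment, patterns, counts) -> int:
    lut = _state_masks(aln)
    view = _binary_rooted_view(tree)
    row = {lab: i for i, lab in enumerate(aln.labels)}
    masks: dict[int, np.ndarray] = {}
    changes = np.zeros(patterns.shape[1], dtype=np.int64)
    for node in view.postorder():
        if node.is_tip:
            masks[id(node)] = lut[patterns[row[node.label]]]
        else:
            acc = None
            for child in node.children:
                m = masks.pop(id(child))
                if acc is None:
                    acc = m
                    continue
                inter = acc & m
                empty = inter == 0
                changes += empty
                acc = np.where(empty, acc | m, inter)
            masks[id(node)] = acc
    return int(changes @ counts)


def fitch_score(tree: Tree, aln: Alignment) -> int:
    """Minimum number of state changes over all sites (Fitch counting)."""
    missing = tree.taxon_set() - set(aln.labels)
    if missing:
        raise ValueError(f"taxa in tree but not alignment: {sorted(missing)}")
    patterns, counts = np.unique(aln.codes, axis=1, return_counts=True)
    sub = Alignment(aln.labels, patterns, aln.alphabet)
    return _fitch_changes(tree, sub, patterns, counts)


def random_topology(
    taxa: Sequence[str], rng: np.random.Generator
) -> Tree:
    """A uniformly grown unrooted binary topology (random edge insertion)."""
    labels = list(taxa)
    rng.shuffle(labels)
    root = Node()
    for lab in labels[:3]:
        root.add_child(Node(lab))
    tree = Tree(root)
    for lab in labels[3:]:
        edges = tree.edges()
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(Node(lab))
        tree = Tree(tree.root)
    return tree


def parsimony_search_nni(
    aln: Alignment,
    start: Tree,
    seed: Union[int, np.random.Generator] = 0,
) -> Tree:
    """Hill-climb over NNI moves until no move lowers the Fitch score.

    Among equally best improving moves, one is chosen at random (seeded).
    The accepted-move score trajectory is strictly decreasing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    current = unroot(start)
    current_score = fitch_score(current, aln)
    while True:
        neighbors = nni_neighbors(current)
        scores = np.array([fitch_score(t, aln) for t in neighbors])
        if len(scores) == 0 or scores.min() >= current_score:
            return current
        best = np.flatnonzero(scores == scores.min())
        pick = best[rng.integers(len(best))]
        current, current_score = neighbors[pick], int(scores.min())


def parsimony_best_tree(
    aln: Alignment,
    seed: int = 0,
    n_starts: int = 10,
) -> tuple[Tree, int]:
    """Multi-start NNI search; returns the best tree and its score."""
    rng = np.random.default_rng(seed)
    best_tree, best_score = None, None
    for _ in range(n_starts):
        start = random_topology(aln.labels, rng)
        tree = parsimony_search_nni(aln, start, rng)
        score = fitch_score(tree, aln)
        if best_score is None or score < best_score:
            best_tree, best_score = tree, score
    return best_tree, best_score


def jackknife_support(
    aln: Alignment,
    deletion: float = 0.36,
    replicates: int = 1000,
    seed: int = 0,
    best_tree: Optional[Tree] = None,
    n_starts: int = 10,
) -> dict:
    """Split support from site-deletion jackknifing.

    Each replicate deletes every site independently with probability
    ``deletion``, reruns the NNI search from a seeded random start, and the
    support of each split of the best full-data tree is the percentage of
    replicate trees containing it. All-deleted replicates are redrawn.
    """
    if not 0.0 < deletion < 1.0:
        raise ValueError("deletion fraction must be in (0, 1)")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    if best_tree is None:
        best_tree, _ = parsimony_best_tree(aln, seed=seed, n_starts=n_starts)
    target_splits = splits(best_tree)
    hits = {s: 0 for s in target_splits}
    done = 0
    while done < replicates:
        keep = rng.random(aln.n_sites) >= deletion
        if not keep.any():
            log.warning("jackknife replicate deleted every site; redrawn")
            continue
        sub = aln.subset_sites(np.flatnonzero(keep))
        start = random_topology(aln.labels, rng)
        result = parsimony_search_nni(sub, start, rng)
        rep_splits = splits(result)
        for s in target_splits:
            if s in rep_splits:
                hits[s] += 1
        done += 1
    return {s: 100.0 * h / replicates for s, h in hits.items()}


def annotate_support(tree: Tree, support: dict) -> Tree:
    """Attach split support percentages to the matching internal nodes."""
    t = tree.copy()
    taxa = t.taxon_set()
    anchor = min(taxa)
    below: dict[int, frozenset] = {}
    for node in t.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.label])
            continue
        clade = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = clade
        if node.parent is None:
            continue
        side = taxa - clade if anchor in clade else clade
        if side in support:
            node.support = support[side]
    return t
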