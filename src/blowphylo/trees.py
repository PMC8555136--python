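"""Phylogenetic tree structure, Newick I/O, and topology operations.

Trees are stored as node-linked structures. Unrooted trees carry a
designated trifurcating (or higher-degree) root node; rooted trees a
bifurcating root. Branch lengths are in expected substitutions per site
unless a caller supplies another scale (e.g. coalescent units).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "CladeConstraint",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "splits",
    "rf_distance",
    "restrict_to_taxa",
    "enumerate_unrooted_topologies",
    "satisfies_constraints",
    "patristic_distance",
    "nni_neighbors",
    "splits_table",
]


class TreeError(ValueError):
    """Invalid tree structure or operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class Node:
    """A tree node with optional label, branch length and support."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None):
        self.label: Optional[str] = label
        self.length: Optional[float] = length
        self.support: Optional[float] = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.label!r}, len={self.length})"


class Tree:
    """A phylogeny; ``rooted`` distinguishes a bifurcating root from the
    arbitrary trifurcating anchor node of an unrooted tree."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self.validate()

    # -- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def taxon_set(self) -> frozenset[str]:
        return frozenset(self.tip_labels())

    def edges(self) -> list[Node]:
        """Every non-root node, each standing for the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    # -- bookkeeping ---------------------------------------------------
    def validate(self) -> None:
        labels = [n.label for n in self.postorder() if n.is_tip]
        if any(not lab for lab in labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for n in self.postorder():
            if n.length is not None:
                if not (n.length == n.length and abs(n.length) != float("inf")):
                    raise TreeError(f"non-finite branch length at {n.label!r}")
                if n.length < 0:
                    raise TreeError(f"negative branch length at {n.label!r}")

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root), rooted=self.rooted)

    def __len__(self) -> int:
        return len(self.tips())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({write_newick(self)})"


@dataclass(frozen=True)
class CladeConstraint:
    """A set of tip labels required to form a clade (split) of the tree."""

    taxa: frozenset[str]

    def __init__(self, taxa: Iterable[str]):
        object.__setattr__(self, "taxa", frozenset(taxa))
        if len(self.taxa) < 2:
            raise TreeError("a clade constraint needs at least two taxa")


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; writing is direct serialization)
# ---------------------------------------------------------------------------

def _from_dendropy(dnode: dendropy.Node) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
    else:
        node = Node(label=dnode.label, length=dnode.edge.length)
        if dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                pass
        for child in dnode.child_nodes():
            node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Numeric internal-node labels are additionally stored as ``support``;
    bracketed comments are ignored; quoted labels are supported. A tree
    whose root has two children is treated as rooted, except for the
    degenerate two-tip tree which is unrooted by construction.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick input")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"Newick string must end in ';' (character offset {len(stripped)})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "col_num", None)
        loc = f" near character offset {offset}" if offset is not None else ""
        raise NewickParseError(f"malformed Newick{loc}: {exc}") from None
    root = _from_dendropy(dtree.seed_node)
    root.length = None
    n_tips = sum(1 for n in _iter_nodes(root) if not n.children)
    rooted = len(root.children) == 2 and n_tips > 2
    if dtree.is_rooted is True:
        rooted = True
    return Tree(root, rooted=rooted)


def _iter_nodes(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(node.children)


def _needs_quoting(label: str) -> bool:
    return any(c in label for c in " \t()[]:;,'")


def _format_label(label: Optional[str]) -> str:
    if label is None:
        return ""
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, include_support: bool = True) -> str:
    """Serialize a tree to Newick, preserving lengths and labels."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            out = _format_label(node.label)
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = node.label
            if label is None and include_support and node.support is not None:
                label = format(node.support, "g")
            out = f"({inner}){_format_label(label)}"
        if node.length is not None and node.parent is not None:
            out += f":{node.length:.10g}"
        return out

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Splits and topology comparison
# ---------------------------------------------------------------------------

def splits(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial splits of the unrooted topology.

    Each split is represented by the tip set on the side *not* containing
    the lexicographically smallest tip, giving a canonical orientation.
    """
    all_taxa = tree.taxon_set()
    anchor = min(all_taxa)
    out: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.label])
        else:
            clade = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = clade
            if node.parent is None:
                continue
            side = all_taxa - clade if anchor in clade else clade
            if 2 <= len(side) <= len(all_taxa) - 2:
                out.add(side)
    return out


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree."""
    if t1.taxon_set() != t2.taxon_set():
        raise TreeError(
            "tip sets differ: "
            f"{sorted(t1.taxon_set() ^ t2.taxon_set())} not shared"
        )
    return len(splits(t1) ^ splits(t2))


def satisfies_constraints(
    tree: Tree, constraints: Sequence[CladeConstraint]
) -> bool:
    """True iff every constraint set is a clade on some rooting (a split)."""
    taxa = tree.taxon_set()
    tsplits = None
    for con in constraints:
        extra = con.taxa - taxa
        if extra:
            raise TreeError(f"constraint taxa not in tree: {sorted(extra)}")
        if len(con.taxa) <= 1 or len(con.taxa) >= len(taxa) - 1:
            continue  # trivial splits hold on every tree
        if tsplits is None:
            tsplits = splits(tree)
        anchor = min(taxa)
        side = taxa - con.taxa if anchor in con.taxa else con.taxa
        if side not in tsplits:
            return False
    return True


def patristic_distance(tree: Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between tips ``a`` and ``b``."""
    nodes = {n.label: n for n in tree.tips()}
    try:
        na, nb = nodes[a], nodes[b]
    except KeyError as exc:
        raise TreeError(f"unknown tip label {exc.args[0]!r}") from None

    def ancestors(n: Node) -> list[Node]:
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    anc_a = ancestors(na)
    anc_b = set(map(id, ancestors(nb)))
    mrca = next(n for n in anc_a if id(n) in anc_b)
    dist = 0.0
    for start in (na, nb):
        n = start
        while n is not mrca:
            dist += n.length or 0.0
            n = n.parent
    return dist


# ---------------------------------------------------------------------------
# Topology manipulation
# ---------------------------------------------------------------------------

def restrict_to_taxa(tree: Tree, keep: Iterable[str]) -> Tree:
    """Induced subtree on ``keep``; suppressed nodes sum branch lengths."""
    keep = set(keep)
    unknown = keep - tree.taxon_set()
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least two taxa to keep")
    new = tree.copy()

    def prune(node: Node) -> Optional[Node]:
        if node.is_tip:
            return node if node.label in keep else None
        kept = []
        for child in node.children:
            res = prune(child)
            if res is not None:
                kept.append(res)
        if not kept:
            return None
        if len(kept) == 1:
            # suppress this degree-2 node, summing lengths onto the child
            child = kept[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            child.parent = None
            return child
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    root = prune(new.root)
    if root is None:  # unreachable given |keep| >= 2
        raise TreeError("pruning removed every taxon")
    root.parent = None
    root.length = None
    rooted = tree.rooted and len(root.children) == 2
    if not rooted and len(root.children) == 2 and len(keep) > 2:
        root = _collapse_root_bifurcation(root)
    return Tree(root, rooted=rooted)


def _collapse_root_bifurcation(root: Node) -> Node:
    """Merge the two root-adjacent edges of an unrooted tree into one."""
    x, y = root.children
    if x.is_tip and not y.is_tip:
        x, y = y, x
    x.parent = None
    y.length = (y.length or 0.0) + (x.length or 0.0)
    x.add_child(y)
    x.length = None
    return x


def enumerate_unrooted_topologies(taxa: Iterable[str]) -> list[Tree]:
    """All (2n−5)!! distinct unrooted binary topologies on ``taxa``.

    Guarded to 4 ≤ n ≤ 9; branch lengths are left unset.
    """
    labels = sorted(set(taxa))
    n = len(labels)
    if not 4 <= n <= 9:
        raise TreeError(f"enumeration supported for 4..9 taxa, got {n}")

    def base() -> Tree:
        root = Node()
        for lab in labels[:3]:
            root.add_child(Node(lab))
        return Tree(root)

    trees = [base()]
    for lab in labels[3:]:
        nxt: list[Tree] = []
        for t in trees:
            for edge_idx in range(len(t.edges())):
                t2 = t.copy()
                target = t2.edges()[edge_idx]
                parent = target.parent
                mid = Node()
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(Node(lab))
                nxt.append(Tree(t2.root))
        trees = nxt
    return trees


def nni_neighbors(tree: Tree) -> list[Tree]:
    """All nearest-neighbor-interchange neighbors of an unrooted binary tree.

    Two neighbors per internal edge, built by swapping a child of the edge's
    lower node with a sibling subtree.
    """
    out: list[Tree] = []
    edge_list = [
        (i, n)
        for i, n in enumerate(tree.edges())
        if not n.is_tip and n.parent is not None
    ]
    for idx, _ in edge_list:
        for which_child in (0, 1):
            t2 = tree.copy()
            v = t2.edges()[idx]
            p = v.parent
            sibling = next(c for c in p.children if c is not v)
            a = v.children[which_child]
            # swap `a` and `sibling`
            p.children[p.children.index(sibling)] = a
            v.children[which_child] = sibling
            a.parent, sibling.parent = p, v
            out.append(Tree(t2.root, rooted=t2.rooted))
    return out


def unroot(tree: Tree) -> Tree:
    """Unrooted view: a bifurcating root is collapsed into its neighbor."""
    t = tree.copy()
    if len(t.root.children) == 2 and len(t) > 2:
        root = _collapse_root_bifurcation(t.root)
        return Tree(root, rooted=False)
    t.rooted = False
    return t


def reroot_at_tip_neighbor(tree: Tree, tip_label: str) -> Tree:
    """Re-anchor an unrooted tree at the internal node adjacent to a tip.

    Used for canonical hashing (anchor at the lexicographically smallest
    tip's neighbor) and for likelihood re-rooting invariance checks.
    """
    t = tree.copy()
    try:
        tip = next(n for n in t.tips() if n.label == tip_label)
    except StopIteration:
        raise TreeError(f"unknown tip label {tip_label!r}") from None
    new_root = tip.parent
    if new_root is None:
        raise TreeError("cannot reroot a single-node tree")
    path = []
    n = new_root
    while n is not None:
        path.append(n)
        n = n.parent
    orig_lengths = [n.length for n in path]
    for (child, parent), orig in zip(zip(path, path[1:]), orig_lengths):
        parent.children.remove(child)
        child.add_child(parent)
        parent.length = orig  # reversed edge keeps its original length
    path[0].length = None
    path[0].parent = None
    old_root = path[-1]
    if len(old_root.children) == 1 and not old_root.is_tip:
        # the old bifurcating anchor becomes degree-2: suppress it
        sole = old_root.children[0]
        grand = old_root.parent
        sole.length = (sole.length or 0.0) + (old_root.length or 0.0)
        grand.children[grand.children.index(old_root)] = sole
        sole.parent = grand
    return Tree(path[0], rooted=False)


def splits_table(tree: Tree) -> "list[tuple[str, str]]":
    """Bipartitions as (side, complement) label strings for TSV export."""
    taxa = tree.taxon_set()
    rows = []
    for s in sorted(splits(tree), key=lambda s: (len(s), sorted(s))):
        rows.append(("|".join(sorted(s)), "|".join(sorted(taxa - s))))
    return rows
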