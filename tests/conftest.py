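"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the implementation paths they check:
likelihoods by exhaustive enumeration over internal-node states, Fitch
scores by minimum over all internal assignments, quartet scores by
explicit four-taxon restriction.
"""

import itertools

import numpy as np
import pytest

import blowphylo as bp


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_site_logliks(tree, aln, model):
    """Exhaustive sum over internal-node state assignments and categories."""
    rates, weights = model.category_rates_weights
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_tip]
    n = model.alphabet.n_states
    cm = model.alphabet.code_matrix
    out = []
    pmats = {
        (id(nd), c): model.transition_matrices(np.asarray(nd.length * r))
        for nd in nodes
        if nd.parent is not None
        for c, r in enumerate(rates)
    }
    for site in range(aln.n_sites):
        lik = 0.0
        for c, w in enumerate(weights):
            site_lik = 0.0
            for assign in itertools.product(range(n), repeat=len(internal)):
                amap = {id(nd): s for nd, s in zip(internal, assign)}
                pr = model.frequencies[amap[id(tree.root)]]
                for nd in nodes:
                    if nd.parent is None:
                        continue
                    ps = amap[id(nd.parent)]
                    P = pmats[(id(nd), c)]
                    if nd.is_tip:
                        pr *= float(P[ps] @ cm[aln.row(nd.label)[site]])
                    else:
                        pr *= float(P[ps, amap[id(nd)]])
                site_lik += pr
            lik += w * site_lik
        out.append(np.log(lik))
    return np.array(out)


def brute_force_fitch(tree, aln):
    """Minimum changes over all internal-node state assignments."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_tip]
    nstates = aln.alphabet.n_states
    cm = aln.alphabet.code_matrix.astype(bool)
    total = 0
    for site in range(aln.n_sites):
        best = None
        tipsets = {
            id(nd): set(np.flatnonzero(cm[aln.row(nd.label)[site]]))
            for nd in nodes
            if nd.is_tip
        }
        for assign in itertools.product(range(nstates), repeat=len(internal)):
            amap = {id(nd): s for nd, s in zip(internal, assign)}
            changes = 0
            for nd in nodes:
                if nd.parent is None:
                    continue
                ps = amap[id(nd.parent)]
                if nd.is_tip:
                    if ps not in tipsets[id(nd)]:
                        changes += 1
                elif amap[id(nd)] != ps:
                    changes += 1
            if best is None or changes < best:
                best = changes
        total += best
    return total


def brute_force_quartet_score(species_tree, gene_trees):
    """Quartet agreement by explicit restriction to every quadruple."""
    score = 0
    sp_taxa = sorted(species_tree.taxon_set())
    for gt in gene_trees:
        taxa = sorted(gt.taxon_set())
        if len(taxa) < 4:
            continue
        for quad in itertools.combinations(taxa, 4):
            sub_g = bp.restrict_to_taxa(gt, quad)
            sub_s = bp.restrict_to_taxa(species_tree, quad)
            sg, ss = bp.splits(sub_g), bp.splits(sub_s)
            if sg and sg == ss:
                score += 1
    return score


def brute_force_marginal_asr(tree, trait, q01, q10):
    """Per-node P(state 1) by summing over all joint internal assignments."""
    from blowphylo.models import binary_model

    model = binary_model(q01, q10)
    pi = model.frequencies
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_tip]
    pmats = {
        id(nd): model.transition_matrices(np.asarray(nd.length))
        for nd in nodes
        if nd.parent is not None
    }
    tip_vec = {}
    for nd in nodes:
        if nd.is_tip:
            s = trait[nd.label]
            tip_vec[id(nd)] = (
                np.ones(2) if s is None else np.eye(2)[s]
            )
    marg = {id(nd): np.zeros(2) for nd in nodes}
    total = 0.0
    tips = [n for n in nodes if n.is_tip]
    tip_state_sets = [
        [0, 1] if trait[t.label] is None else [trait[t.label]] for t in tips
    ]
    for tip_assign in itertools.product(*tip_state_sets):
        tmap = dict(zip([id(t) for t in tips], tip_assign))
        for assign in itertools.product((0, 1), repeat=len(internal)):
            amap = {id(nd): s for nd, s in zip(internal, assign)}
            amap.update(tmap)
            pr = pi[amap[id(tree.root)]]
            for nd in nodes:
                if nd.parent is None:
                    continue
                pr *= pmats[id(nd)][amap[id(nd.parent)], amap[id(nd)]]
            total += pr
            for nd in nodes:
                marg[id(nd)][amap[id(nd)]] += pr
    below = {}
    for nd in nodes:
        if nd.is_tip:
            below[id(nd)] = frozenset([nd.label])
        else:
            below[id(nd)] = frozenset().union(*(below[id(c)] for c in nd.children))
    return {below[id(nd)]: marg[id(nd)][1] / total for nd in nodes}, total


def split_set(tree):
    return bp.splits(tree)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def backbone_t1():
    return bp.backbone_fixture("T1")


@pytest.fixture(scope="session")
def four_taxon_tree():
    return bp.parse_newick("((A:0.2,B:0.15):0.1,(C:0.3,D:0.25):0.05);")


def random_branched_tree(taxa, rng, lo=0.02, hi=0.4):
    """A random topology with random branch lengths."""
    from blowphylo.parsimony import random_topology

    t = random_topology(list(taxa), rng)
    for n in t.postorder():
        if n.parent is not None:
            n.length = float(rng.uniform(lo, hi))
    return t


def random_rooted_tree(taxa, rng, lo=0.02, hi=0.4):
    """A random rooted binary tree (root splits the first anchor edge)."""
    from blowphylo.trees import Node

    t = random_branched_tree(taxa, rng, lo, hi)
    first = t.root.children[0]
    t.root.remove_child(first)
    new_root = Node()
    half = (first.length or 0.0) / 2
    first.length = half
    t.root.length = half
    new_root.add_child(first)
    new_root.add_child(t.root)
    return bp.Tree(new_root, rooted=True)
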