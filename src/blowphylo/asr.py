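"""Ancestral-state reconstruction of a binary trait (metallic coloration).

A two-state Markov model (Mk2) with gain rate q01 and loss rate q10 drives
three reconstructions on a fixed rooted tree:

* :func:`fit_mk2` — maximum-likelihood rates by bounded optimization of
  the pruning likelihood, root at the stationary frequencies;
* :func:`marginal_asr` — exact per-node marginal probabilities by the
  up–down (inside–outside) algorithm;
* :func:`bbm_asr` — Bayesian binary MCMC: Metropolis–Hastings over the
  rates with independent exponential priors, node probabilities averaged
  over the retained posterior samples;
* :func:`count_origins` — gains and losses implied by assigning each node
  its preferred state.

Unknown tip states (``?``) are treated as fully ambiguous. Probabilities
are keyed by each node's descendant tip set, which is stable across tree
copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .models import binary_model
from .trees import Node, Tree, TreeError

__all__ = [
    "BinaryTrait",
    "AsrResult",
    "fit_mk2",
    "marginal_asr",
    "bbm_asr",
    "count_origins",
    "read_trait_tsv",
    "write_trait_tsv",
]

_RATE_LO, _RATE_HI = 1e-6, 1e3


class BinaryTrait(dict):
    """Taxon → state map; 0 = absent, 1 = present, None = unknown."""

    def __init__(self, states: Mapping[str, Optional[int]]):
        super().__init__()
        for k, v in states.items():
            if v not in (0, 1, None):
                raise ValueError(f"state for {k!r} must be 0, 1 or None")
            self[k] = v

    @property
    def observed(self) -> dict:
        return {k: v for k, v in self.items() if v is not None}

    def require_polymorphic(self) -> None:
        vals = set(self.observed.values())
        if vals != {0, 1}:
            raise ValueError(
                "trait is monomorphic among observed tips; rate estimation "
                "is undefined (the reconstruction is trivially the observed "
                "state everywhere)"
            )


def read_trait_tsv(path: Union[str, Path]) -> BinaryTrait:
    states = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        taxon, value = line.split("\t")
        states[taxon] = None if value == "?" else int(value)
    return BinaryTrait(states)


def write_trait_tsv(trait: BinaryTrait, path: Union[str, Path]) -> None:
    lines = [
        f"{k}\t{'?' if v is None else v}" for k, v in sorted(trait.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pruning machinery (2 states, exact, single or pooled characters)
# ---------------------------------------------------------------------------

def _tip_vector(state: Optional[int]) -> np.ndarray:
    if state is None:
        return np.ones(2)
    v = np.zeros(2)
    v[state] = 1.0
    return v


def _check_inputs(tree: Tree, traits: Sequence[BinaryTrait]) -> None:
    if not tree.rooted:
        raise TreeError("ancestral reconstruction needs a rooted tree")
    tips = tree.taxon_set()
    for trait in traits:
        missing = tips - set(trait)
        if missing:
            raise ValueError(f"trait missing taxa: {sorted(missing)}")
    for n in tree.postorder():
        if n.parent is not None and n.length is None:
            raise TreeError(f"missing branch length above {n.label!r}")


def _pmats(tree: Tree, q01: float, q10: float) -> dict:
    model = binary_model(q01, q10)
    out = {}
    for n in tree.postorder():
        if n.parent is not None:
            out[id(n)] = model.transition_matrices(np.asarray(n.length))
    return out


def _root_prior(q01: float, q10: float, root_prior: str) -> np.ndarray:
    if root_prior == "stationary":
        return np.array([q10, q01]) / (q01 + q10)
    if root_prior == "flat":
        return np.array([0.5, 0.5])
    raise ValueError("root_prior must be 'stationary' or 'flat'")


def _down_pass(tree: Tree, trait: BinaryTrait, pmats: dict):
    """Inside partials and log scale per node for one character."""
    D: dict[int, np.ndarray] = {}
    logsc: dict[int, float] = {}
    for n in tree.postorder():
        if n.is_tip:
            D[id(n)] = _tip_vector(trait[n.label])
            logsc[id(n)] = 0.0
        else:
            v = np.ones(2)
            sc = 0.0
            for c in n.children:
                v = v * (pmats[id(c)] @ D[id(c)])
                sc += logsc[id(c)]
            mx = v.max()
            if mx > 0:
                v = v / mx
                sc += math.log(mx)
            D[id(n)] = v
            logsc[id(n)] = sc
    return D, logsc


def _loglik(tree: Tree, traits: Sequence[BinaryTrait], q01, q10,
            root_prior: str = "stationary") -> float:
    pmats = _pmats(tree, q01, q10)
    pi = _root_prior(q01, q10, root_prior)
    total = 0.0
    for trait in traits:
        D, logsc = _down_pass(tree, trait, pmats)
        lik = float(pi @ D[id(tree.root)])
        total += (math.log(lik) if lik > 0 else -math.inf) + logsc[id(tree.root)]
    return total


def _as_trait_list(trait) -> list:
    if isinstance(trait, BinaryTrait):
        return [trait]
    return list(trait)


def fit_mk2(
    tree: Tree,
    trait,
    equal_rates: bool = False,
    root_prior: str = "stationary",
) -> tuple[float, float, float]:
    """ML gain/loss rates for one trait or a pool of independent traits.

    Returns (q01, q10, lnL). Rates are bounded to [1e−6, 1e3]; with
    ``equal_rates`` a single symmetric rate is fitted.
    """
    traits = _as_trait_list(trait)
    _check_inputs(tree, traits)
    for t in traits:
        t.require_polymorphic() if len(traits) == 1 else None
    if len(traits) > 1:
        observed = set()
        for t in traits:
            observed |= set(t.observed.values())
        if observed != {0, 1}:
            raise ValueError("pooled traits are monomorphic")

    if equal_rates:
        def nll(x):
            q = math.exp(x[0])
            return -_loglik(tree, traits, q, q, root_prior)
        res = minimize(
            nll, [math.log(0.1)], method="L-BFGS-B",
            bounds=[(math.log(_RATE_LO), math.log(_RATE_HI))],
        )
        q = math.exp(res.x[0])
        return q, q, -float(res.fun)

    def nll(x):
        return -_loglik(tree, traits, math.exp(x[0]), math.exp(x[1]), root_prior)

    res = minimize(
        nll, [math.log(0.1), math.log(0.1)], method="L-BFGS-B",
        bounds=[(math.log(_RATE_LO), math.log(_RATE_HI))] * 2,
    )
    q01, q10 = map(math.exp, res.x)
    return float(q01), float(q10), -float(res.fun)


# ---------------------------------------------------------------------------
# Marginal reconstruction
# ---------------------------------------------------------------------------

@dataclass
class AsrResult:
    """Per-node P(state 1), keyed by descendant tip set; includes tips."""

    node_prob: dict
    method: str
    q01: float
    q10: float
    extras: dict = field(default_factory=dict)

    def prob(self, clade: Iterable[str]) -> float:
        return self.node_prob[frozenset(clade)]


def _clades(tree: Tree) -> dict:
    below = {}
    for n in tree.postorder():
        if n.is_tip:
            below[id(n)] = frozenset([n.label])
        else:
            below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
    return below


def marginal_asr(
    tree: Tree,
    trait: BinaryTrait,
    q01: float,
    q10: float,
    root_prior: str = "stationary",
) -> AsrResult:
    """Exact marginal state probabilities at every node (up–down pass)."""
    if q01 <= 0 or q10 <= 0:
        raise ValueError("rates must be positive")
    _check_inputs(tree, [trait])
    pmats = _pmats(tree, q01, q10)
    pi = _root_prior(q01, q10, root_prior)
    D, _ = _down_pass(tree, trait, pmats)
    below = _clades(tree)
    # outside partials: U[v][j] = P(rest of data | state j at v)
    U: dict[int, np.ndarray] = {id(tree.root): pi.copy()}
    for n in tree.preorder():
        for child in n.children:
            out = U[id(n)].copy()
            for sib in n.children:
                if sib is not child:
                    out = out * (pmats[id(sib)] @ D[id(sib)])
            U[id(child)] = pmats[id(child)].T @ out
    probs = {}
    for n in tree.postorder():
        joint = U[id(n)] * D[id(n)]
        total = joint.sum()
        probs[below[id(n)]] = float(joint[1] / total) if total > 0 else 0.5
    return AsrResult(probs, "ML marginal", q01, q10)


# ---------------------------------------------------------------------------
# Bayesian binary MCMC
# ---------------------------------------------------------------------------

def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1))
    acf = acf / acf[0]
    tau = 1.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)


def bbm_asr(
    tree: Tree,
    trait: BinaryTrait,
    prior_mean: float = 1.0,
    generations: int = 10000,
    burnin: int = 2000,
    thin: int = 10,
    seed: int = 0,
    proposal_sd: float = 0.3,
    root_prior: str = "stationary",
) -> AsrResult:
    """Bayesian binary MCMC ancestral reconstruction.

    Metropolis–Hastings over (q01, q10) with independent exponential
    priors of the given mean and Gaussian proposals on the log scale; node
    probabilities are the posterior mean of the marginal reconstruction
    over retained samples. Acceptance rate and per-rate effective sample
    sizes land in ``extras`` with a warning flag when acceptance falls
    outside [0.05, 0.8].
    """
    if generations <= burnin:
        raise ValueError("generations must exceed burnin")
    _check_inputs(tree, [trait])
    rng = np.random.default_rng(seed)
    theta = np.log([0.1, 0.1])

    def logpost(th: np.ndarray) -> float:
        q01, q10 = np.exp(th)
        # exponential(prior_mean) prior plus the log-scale Jacobian
        return (
            _loglik(tree, [trait], q01, q10, root_prior)
            - (q01 + q10) / prior_mean
            + th.sum()
        )

    cur = logpost(theta)
    samples, accepted = [], 0
    prob_sum: Optional[dict] = None
    n_kept = 0
    for g in range(1, generations + 1):
        prop = theta + rng.normal(0.0, proposal_sd, size=2)
        lp = logpost(prop)
        if math.log(rng.random()) < lp - cur:
            theta, cur = prop, lp
            accepted += 1
        if g > burnin and (g - burnin) % thin == 0:
            q01, q10 = np.exp(theta)
            samples.append((q01, q10))
            res = marginal_asr(tree, trait, q01, q10, root_prior)
            if prob_sum is None:
                prob_sum = dict.fromkeys(res.node_prob, 0.0)
            for k, v in res.node_prob.items():
                prob_sum[k] += v
            n_kept += 1
    samples = np.array(samples)
    probs = {k: v / n_kept for k, v in prob_sum.items()}
    acc_rate = accepted / generations
    extras = {
        "rate_samples": samples,
        "acceptance_rate": acc_rate,
        "ess_q01": _ess(samples[:, 0]),
        "ess_q10": _ess(samples[:, 1]),
        "warning": (
            "acceptance rate outside [0.05, 0.8]"
            if not 0.05 <= acc_rate <= 0.8
            else ""
        ),
    }
    post_mean = samples.mean(axis=0)
    return AsrResult(
        probs, "Bayesian posterior mean",
        float(post_mean[0]), float(post_mean[1]), extras,
    )


# ---------------------------------------------------------------------------
# Origin counting
# ---------------------------------------------------------------------------

def count_origins(
    tree: Tree, asr: AsrResult, threshold: float = 0.5
) -> tuple[int, int, dict]:
    """Gains (0→1 edges) and losses (1→0) under the preferred-state map.

    Each node takes state 1 when P(1) > ``threshold``, state 0 when
    P(1) < 1 − ``threshold``; undecided nodes inherit the parent's state
    (an undecided root takes 0).
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1]")
    below = _clades(tree)
    assignment: dict = {}
    for n in tree.preorder():
        p1 = asr.node_prob[below[id(n)]]
        if p1 > threshold:
            state = 1
        elif p1 < 1.0 - threshold:
            state = 0
        else:
            state = assignment[below[id(n.parent)]] if n.parent is not None else 0
        assignment[below[id(n)]] = state
    gains = losses = 0
    for n in tree.preorder():
        if n.parent is None:
            continue
        parent_state = assignment[below[id(n.parent)]]
        child_state = assignment[below[id(n)]]
        if parent_state == 0 and child_state == 1:
            gains += 1
        elif parent_state == 1 and child_state == 0:
            losses += 1
    return gains, losses, assignment
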