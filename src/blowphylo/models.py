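"""Reversible CTMC substitution models with discrete-gamma rate variation.

A model bundles an alphabet, symmetric exchangeabilities s_ij, equilibrium
frequencies π, an optional discrete-gamma shape (k equal-probability
categories, category rate = within-bin mean) and an optional proportion of
invariant sites. The generated rate matrix Q_ij = s_ij π_j satisfies
detailed balance and, unless ``normalize=False`` (trait models in absolute
rate units), is scaled so one unit of branch length equals one expected
substitution per site at stationarity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

import numpy as np
from scipy.stats import gamma as gamma_dist

from ._lg_data import LG_EXCH_LOWER, LG_FREQS, LG_ORDER
from .alphabet import AA, BINARY, DAYHOFF6, DNA, DAYHOFF_GROUPS, Alphabet
from .alignment import Alignment

__all__ = [
    "SubstitutionModel",
    "build_rate_matrix",
    "transition_probabilities",
    "discrete_gamma_rates",
    "jc",
    "gtr",
    "poisson_aa",
    "lg",
    "dayhoff6_model",
    "binary_model",
    "dayhoff6_recode",
]


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability bins of Gamma(shape, mean 1)."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), shape, scale=1.0 / shape)
    # E[X; X in bin] / P(bin) via the incomplete-gamma identity
    upper_cdf = gamma_dist.cdf(edges, shape + 1, scale=1.0 / shape)
    rates = k * np.diff(upper_cdf)
    return rates / (rates.mean())


@dataclass(eq=False)
class SubstitutionModel:
    alphabet: Alphabet
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: Optional[float] = None
    n_categories: int = 4
    p_invariant: float = 0.0
    normalize: bool = True

    def __post_init__(self):
        n = self.alphabet.n_states
        ex = np.asarray(self.exchangeabilities, dtype=float)
        fr = np.asarray(self.frequencies, dtype=float)
        if ex.shape != (n, n):
            raise ValueError(f"exchangeabilities must be {n}x{n}")
        if not np.allclose(ex, ex.T):
            raise ValueError("exchangeabilities must be symmetric")
        if (ex[~np.eye(n, dtype=bool)] < 0).any():
            raise ValueError("exchangeabilities must be non-negative")
        if ex[~np.eye(n, dtype=bool)].max(initial=0.0) <= 0:
            raise ValueError("at least one exchangeability must be positive")
        if fr.shape != (n,):
            raise ValueError(f"frequencies must have length {n}")
        if (fr <= 0).any():
            raise ValueError("zero or negative equilibrium frequency")
        if not np.isclose(fr.sum(), 1.0, atol=1e-8):
            raise ValueError("frequencies must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("p_invariant must be in [0, 1)")
        self.exchangeabilities = ex
        self.frequencies = fr / fr.sum()

    # -- rate matrix and spectral cache --------------------------------
    @cached_property
    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self)

    @cached_property
    def _spectral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetric-form eigendecomposition of the reversible Q."""
        pi = self.frequencies
        d = np.sqrt(pi)
        sym = self.rate_matrix * (d[:, None] / d[None, :])
        sym = (sym + sym.T) / 2.0
        w, v = np.linalg.eigh(sym)
        left = v.T * d[None, :]        # rows: v^T diag(sqrt pi)
        right = (v.T / d[None, :]).T   # diag(1/sqrt pi) v
        return w, right, left

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) = exp(Qt) for an array of times; shape (*t.shape, n, n)."""
        t = np.asarray(t, dtype=float)
        if (t < 0).any():
            raise ValueError("branch length must be non-negative")
        w, right, left = self._spectral
        expwt = np.exp(np.multiply.outer(t, w))
        p = np.einsum("...k,ik,kj->...ij", expwt, right, left)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=-1, keepdims=True)
        return p

    # -- among-site rate variation -------------------------------------
    @cached_property
    def category_rates_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) including an invariant class when p_inv > 0;
        weighted mean rate is exactly 1."""
        if self.gamma_shape is None:
            rates = np.ones(1)
            weights = np.ones(1)
        else:
            rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)
            weights = np.full(self.n_categories, 1.0 / self.n_categories)
        p = self.p_invariant
        if p > 0:
            rates = np.concatenate([[0.0], rates / (1.0 - p)])
            weights = np.concatenate([[p], weights * (1.0 - p)])
        return rates, weights

    def replace(self, **kw) -> "SubstitutionModel":
        return dataclasses.replace(self, **kw)


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Q_ij = s_ij π_j, diagonal = −row sums, mean rate 1 if normalized."""
    pi = model.frequencies
    q = model.exchangeabilities * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if model.normalize:
        mu = -(pi * np.diag(q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        q = q / mu
    return q


def transition_probabilities(model: SubstitutionModel, t: float) -> np.ndarray:
    """Stochastic matrix exp(Qt) for a single branch length ``t`` >= 0."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    return model.transition_matrices(np.asarray(t))


# ---------------------------------------------------------------------------
# Shipped model families
# ---------------------------------------------------------------------------

def _equal_exchange(n: int) -> np.ndarray:
    ex = np.ones((n, n))
    np.fill_diagonal(ex, 0.0)
    return ex


def jc(gamma_shape: Optional[float] = None, n_categories: int = 4,
       p_invariant: float = 0.0) -> SubstitutionModel:
    """Jukes–Cantor: equal exchangeabilities, uniform base frequencies."""
    return SubstitutionModel(
        DNA, _equal_exchange(4), np.full(4, 0.25),
        gamma_shape=gamma_shape, n_categories=n_categories,
        p_invariant=p_invariant,
    )


def gtr(exchangeabilities, frequencies, gamma_shape: Optional[float] = None,
        n_categories: int = 4, p_invariant: float = 0.0) -> SubstitutionModel:
    """General time-reversible nucleotide model."""
    return SubstitutionModel(
        DNA, np.asarray(exchangeabilities, float), np.asarray(frequencies, float),
        gamma_shape=gamma_shape, n_categories=n_categories,
        p_invariant=p_invariant,
    )


def poisson_aa(gamma_shape: Optional[float] = None,
               n_categories: int = 4) -> SubstitutionModel:
    """Poisson amino-acid model: equal exchangeabilities, uniform π."""
    return SubstitutionModel(
        AA, _equal_exchange(20), np.full(20, 0.05),
        gamma_shape=gamma_shape, n_categories=n_categories,
    )


def lg(gamma_shape: Optional[float] = None, n_categories: int = 4,
       frequencies=None) -> SubstitutionModel:
    """The empirical LG amino-acid replacement model."""
    assert LG_ORDER == "".join(AA.states)
    n = 20
    ex = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            ex[i, j] = ex[j, i] = LG_EXCH_LOWER[k]
            k += 1
    fr = np.asarray(LG_FREQS if frequencies is None else frequencies, float)
    return SubstitutionModel(
        AA, ex, fr, gamma_shape=gamma_shape, n_categories=n_categories
    )


def dayhoff6_model(frequencies=None, gamma_shape: Optional[float] = None,
                   n_categories: int = 4) -> SubstitutionModel:
    """Equal-exchangeability 6-state model for Dayhoff-recoded matrices."""
    fr = np.full(6, 1 / 6) if frequencies is None else np.asarray(frequencies)
    return SubstitutionModel(
        DAYHOFF6, _equal_exchange(6), fr,
        gamma_shape=gamma_shape, n_categories=n_categories,
    )


def binary_model(q01: float, q10: float,
                 gamma_shape: Optional[float] = None,
                 n_categories: int = 1) -> SubstitutionModel:
    """Two-state trait model with gain rate q01 and loss rate q10.

    Rates are in absolute units (no mean-rate normalization), so branch
    lengths multiply the given rates directly. Stationary frequencies are
    (q10, q01)/(q01 + q10).
    """
    if q01 <= 0 or q10 <= 0:
        raise ValueError("trait rates must be positive")
    tot = q01 + q10
    freqs = np.array([q10 / tot, q01 / tot])
    # s * pi_1 = q01 and s * pi_0 = q10  =>  s = q01 + q10
    ex = np.array([[0.0, tot], [tot, 0.0]])
    return SubstitutionModel(
        BINARY, ex, freqs, gamma_shape=gamma_shape,
        n_categories=n_categories, normalize=False,
    )


# ---------------------------------------------------------------------------
# Dayhoff six-group recoding
# ---------------------------------------------------------------------------

def dayhoff6_recode(aln: Alignment) -> Alignment:
    """Collapse a 20-state amino-acid alignment onto the six Dayhoff groups
    {AGPST, DENQ, HKR, ILMV, FWY, C}; every ambiguity or missing symbol
    becomes full six-state ambiguity."""
    if aln.alphabet.name != "aa":
        raise ValueError("Dayhoff recoding requires an amino-acid alignment")
    src, dst = AA, DAYHOFF6
    lut = np.empty(len(src.symbols), dtype=np.int16)
    full_amb = dst.code_of["X"]
    lut[:] = full_amb
    for gi, group in enumerate(DAYHOFF_GROUPS):
        for aa_sym in group:
            lut[src.code_of[aa_sym]] = gi
    codes = lut[aln.codes]
    return Alignment(list(aln.labels), codes, dst)
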