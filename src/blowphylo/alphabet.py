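"""Character alphabets with ambiguity maps.

An :class:`Alphabet` knows its ordered fundamental states plus a mapping
from ambiguity symbols (gaps, ``N``/``X``, IUPAC degeneracies, ``?``) to the
subset of states each is compatible with. Sequences are stored as integer
codes; codes ``>= n_states`` index rows of :attr:`Alphabet.code_matrix`,
the 0/1 compatibility matrix used directly as tip partial likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["Alphabet", "DNA", "AA", "DAYHOFF6", "BINARY", "DAYHOFF_GROUPS"]


@dataclass(frozen=True)
class Alphabet:
    name: str
    states: tuple[str, ...]
    ambiguity: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.states) < 2:
            raise ValueError("alphabet needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state symbols")
        for sym, subset in self.ambiguity.items():
            if not subset:
                raise ValueError(f"empty ambiguity subset for {sym!r}")
            if not set(subset) <= set(self.states):
                raise ValueError(f"ambiguity {sym!r} maps outside the alphabet")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @cached_property
    def symbols(self) -> tuple[str, ...]:
        """All recognized symbols: fundamental states then ambiguity codes."""
        return self.states + tuple(self.ambiguity)

    @cached_property
    def code_of(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    @cached_property
    def code_matrix(self) -> np.ndarray:
        """(n_codes, n_states) 0/1 state-compatibility matrix."""
        m = np.zeros((len(self.symbols), self.n_states))
        for i, s in enumerate(self.states):
            m[i, i] = 1.0
        for sym, subset in self.ambiguity.items():
            row = self.code_of[sym]
            for st in subset:
                m[row, self.states.index(st)] = 1.0
        return m

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.array(
                [self.code_of[c.upper()] for c in seq], dtype=np.int16
            )
        except KeyError as exc:
            raise ValueError(
                f"symbol {exc.args[0]!r} not in alphabet {self.name}"
            ) from None

    def decode(self, codes: np.ndarray) -> str:
        return "".join(self.symbols[c] for c in codes)

    def is_certain(self, codes: np.ndarray) -> np.ndarray:
        """Boolean mask of fully specified (unambiguous) codes."""
        return np.asarray(codes) < self.n_states

    def is_fully_ambiguous(self, codes: np.ndarray) -> np.ndarray:
        full = self.code_matrix.sum(axis=1) == self.n_states
        return full[np.asarray(codes)]


def _dna() -> Alphabet:
    states = tuple("ACGT")
    iupac = {
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    }
    amb = {k: tuple(v) for k, v in iupac.items()}
    for sym in ("N", "-", "?"):
        amb[sym] = states
    return Alphabet("dna", states, amb)


def _aa() -> Alphabet:
    states = tuple("ARNDCQEGHILKMFPSTWYV")
    amb = {
        "B": ("N", "D"),
        "Z": ("Q", "E"),
        "J": ("I", "L"),
    }
    for sym in ("X", "-", "?", "*"):
        amb[sym] = states
    return Alphabet("aa", states, amb)


#: The six classical Dayhoff groups, in the order used throughout.
DAYHOFF_GROUPS: tuple[str, ...] = ("AGPST", "DENQ", "HKR", "ILMV", "FWY", "C")


def _dayhoff6() -> Alphabet:
    states = tuple("123456")
    amb = {sym: states for sym in ("X", "-", "?")}
    return Alphabet("dayhoff6", states, amb)


def _binary() -> Alphabet:
    return Alphabet("binary", ("0", "1"), {"?": ("0", "1"), "-": ("0", "1")})


DNA = _dna()
AA = _aa()
DAYHOFF6 = _dayhoff6()
BINARY = _binary()
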