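"""Alignments, partition maps, and sequence-format I/O.

Alignments are rectangular taxa × sites matrices of integer character
codes over an :class:`~blowphylo.alphabet.Alphabet`. FASTA and relaxed
PHYLIP reading/writing is delegated to Biopython; the RAxML-style
partition dialect (``MODEL, name = start-end`` with 1-based inclusive
coordinates) is converted to 0-based half-open intervals at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA, BINARY, DAYHOFF6, DNA, Alphabet

__all__ = [
    "Alignment",
    "Partition",
    "PartitionMap",
    "read_fasta",
    "write_fasta",
    "read_phylip",
    "write_phylip",
    "read_partitions",
    "write_partitions",
]


class Alignment:
    """A taxa × sites character matrix with an alphabet."""

    def __init__(
        self,
        labels: Sequence[str],
        codes: np.ndarray,
        alphabet: Alphabet,
    ):
        codes = np.asarray(codes, dtype=np.int16)
        if codes.ndim != 2 or codes.shape[0] != len(labels):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate taxon labels")
        if codes.size and (codes.min() < 0 or codes.max() >= len(alphabet.symbols)):
            raise ValueError("character code outside alphabet")
        self.labels = list(labels)
        self.codes = codes
        self.alphabet = alphabet
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @classmethod
    def from_sequences(
        cls, pairs: "Iterable[tuple[str, str]]", alphabet: Alphabet
    ) -> "Alignment":
        labels, rows = [], []
        for label, seq in pairs:
            labels.append(label)
            rows.append(alphabet.encode(seq))
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        return cls(labels, np.array(rows, dtype=np.int16), alphabet)

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, label: str) -> str:
        return self.alphabet.decode(self.codes[self._index[label]])

    def row(self, label: str) -> np.ndarray:
        return self.codes[self._index[label]]

    def subset_taxa(self, keep: Sequence[str]) -> "Alignment":
        idx = [self._index[k] for k in keep]
        return Alignment(list(keep), self.codes[idx].copy(), self.alphabet)

    def subset_sites(self, cols: np.ndarray) -> "Alignment":
        return Alignment(self.labels, self.codes[:, cols].copy(), self.alphabet)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.labels == other.labels
            and self.alphabet.name == other.alphabet.name
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_taxa} taxa x {self.n_sites} sites, {self.alphabet.name})"


@dataclass(frozen=True)
class Partition:
    """One gene: a 0-based half-open column interval, optional model name."""

    name: str
    start: int
    end: int
    model: Optional[str] = None

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad interval for {self.name}: [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class PartitionMap:
    """Ordered, disjoint gene intervals covering an alignment exactly."""

    def __init__(self, parts: Sequence[Partition]):
        names = [p.name for p in parts]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in partition map")
        prev_end = None
        for p in parts:
            if prev_end is not None and p.start != prev_end:
                raise ValueError(
                    f"partitions not contiguous at {p.name}: start {p.start} != {prev_end}"
                )
            prev_end = p.end
        self.parts = list(parts)

    def __iter__(self):
        return iter(self.parts)

    def __len__(self):
        return len(self.parts)

    def __getitem__(self, key: Union[int, str]) -> Partition:
        if isinstance(key, str):
            for p in self.parts:
                if p.name == key:
                    return p
            raise KeyError(key)
        return self.parts[key]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parts]

    @property
    def total_sites(self) -> int:
        return self.parts[-1].end if self.parts else 0

    def validate_against(self, aln: Alignment) -> None:
        if self.total_sites != aln.n_sites or (self.parts and self.parts[0].start != 0):
            raise ValueError(
                f"partition map covers [0,{self.total_sites}) but alignment has "
                f"{aln.n_sites} sites"
            )

    def gene_columns(self, name: str) -> np.ndarray:
        p = self[name]
        return np.arange(p.start, p.end)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_ALPHABETS = {a.name: a for a in (DNA, AA, DAYHOFF6, BINARY)}


def _records_to_alignment(records, alphabet: Alphabet) -> Alignment:
    return Alignment.from_sequences(
        ((r.id, str(r.seq)) for r in records), alphabet
    )


def read_fasta(path: Union[str, Path], alphabet: Alphabet) -> Alignment:
    return _records_to_alignment(SeqIO.parse(str(path), "fasta"), alphabet)


def write_fasta(aln: Alignment, path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(lab)), id=lab, description="")
        for lab in aln.labels
    ]
    SeqIO.write(records, str(path), "fasta")


def read_phylip(path: Union[str, Path], alphabet: Alphabet) -> Alignment:
    return _records_to_alignment(
        SeqIO.parse(str(path), "phylip-relaxed"), alphabet
    )


def write_phylip(aln: Alignment, path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(lab)), id=lab, description="")
        for lab in aln.labels
    ]
    SeqIO.write(records, str(path), "phylip-relaxed")


def read_partitions(path: Union[str, Path]) -> PartitionMap:
    """Read RAxML-style partition lines ``MODEL, name = start-end``."""
    parts = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            model_part, rest = line.split(",", 1)
            name, interval = rest.split("=", 1)
            lo, hi = interval.strip().split("-")
            parts.append(
                Partition(
                    name=name.strip(),
                    start=int(lo) - 1,  # 1-based inclusive -> 0-based half-open
                    end=int(hi),
                    model=model_part.strip() or None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"bad partition line {lineno}: {raw!r}") from exc
    return PartitionMap(parts)


def write_partitions(parts: PartitionMap, path: Union[str, Path]) -> None:
    lines = [
        f"{p.model or 'AUTO'}, {p.name} = {p.start + 1}-{p.end}" for p in parts
    ]
    Path(path).write_text("\n".join(lines) + "\n")
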