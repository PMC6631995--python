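"""Core genomic containers and sequence statistics.

Coordinate conventions used throughout the package:

* all internal coordinates are 0-based, half-open ``[start, end)``;
* the only 1-based surface is VCF input (converted on read);
* repeat masking is carried exclusively by sequence case — lowercase
  bases are repeat-masked, and analysis windows touching them (or ``N``)
  are skipped by the k-mer and PSSM machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

_ALPHABET = set("ACGTNacgtn")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class UndefinedStatisticError(ValueError):
    """Raised when a requested statistic has an empty denominator."""


def revcomp(seq: str) -> str:
    """Reverse complement preserving case (lowercase travels with its base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


class Genome:
    """Ordered collection of named nucleotide sequences.

    Lowercase letters mark repeat-masked bases; the alphabet is restricted
    to ``ACGTN`` in either case.
    """

    def __init__(self, records: Iterable[Tuple[str, str]]):
        self._records: Dict[str, str] = {}
        for name, seq in records:
            if name in self._records:
                raise ValueError(f"duplicate record name {name!r}")
            if len(seq) == 0:
                raise ValueError(f"record {name!r} has length 0")
            bad = set(seq) - _ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"record {name!r} holds non-alphabet character "
                    f"{seq[pos]!r} at position {pos}"
                )
            self._records[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __getitem__(self, name: str) -> str:
        return self._records[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def names(self) -> List[str]:
        return list(self._records)

    def length(self, name: str) -> int:
        return len(self._records[name])

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval``; minus-strand intervals are reverse
        complemented so the result always reads 5'→3' on the requested
        strand."""
        seq = self._records[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds sequence length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        return revcomp(sub) if interval.strand == "-" else sub

    def items(self) -> Iterable[Tuple[str, str]]:
        return self._records.items()


@dataclass
class SignalTrack:
    """A sparse nonnegative coverage track (e.g. one histone mark).

    ``data`` holds non-overlapping intervals with columns
    ``chrom, start, end, value``; within one track intervals never overlap.
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "value"]
        if list(self.data.columns)[:4] != required:
            raise ValueError(f"track data must have columns {required}")
        if (self.data["value"] < 0).any():
            raise ValueError(f"track {self.name!r} holds negative coverage")
        self.data = (
            self.data.sort_values(["chrom", "start"]).reset_index(drop=True)
        )
        for chrom, grp in self.data.groupby("chrom", sort=False):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError(
                    f"track {self.name!r} holds overlapping intervals on {chrom}"
                )

    def peaks(self, quantile: float = 0.5) -> List[GenomicInterval]:
        """Intervals whose value reaches the given quantile of all values."""
        if self.data.empty:
            return []
        cut = float(self.data["value"].quantile(quantile))
        sel = self.data[self.data["value"] >= cut]
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sel.itertuples()
        ]


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide substitution at a 0-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-base substitutions are supported")
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")

    def check_against(self, genome: Genome) -> None:
        base = genome[self.chrom][self.pos]
        if base.upper() != self.ref.upper():
            raise ValueError(
                f"REF {self.ref} disagrees with genome base {base} at "
                f"{self.chrom}:{self.pos} (0-based)"
            )


def seq_stats(seq: str) -> Tuple[float, float]:
    """GC fraction and repeat (lowercase) fraction of a sequence.

    GC is computed case-insensitively over ``A/C/G/T`` only; ``N`` bases
    are excluded from the denominator.  Repeat fraction is the share of
    lowercase letters.  An all-``N`` sequence has no defined GC and raises
    :class:`UndefinedStatisticError`.
    """
    if not seq:
        raise ValueError("seq_stats of empty sequence")
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    denom = gc + at
    if denom == 0:
        raise UndefinedStatisticError("GC undefined: sequence is all N")
    repeat = sum(1 for c in seq if c.islower()) / len(seq)
    return gc / denom, repeat


# ---------------------------------------------------------------------------
# integer encoding shared by the k-mer and PSSM scanners

_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
# lowercase (repeat-masked) and N stay -1: windows touching them are skipped


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to int codes A=0 C=1 G=2 T=3; masked/N bases = -1."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def total_interval_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)
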