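"""GC/repeat/length-matched control sequences for enhancer sets.

For each enhancer, candidate windows of identical length are drawn
uniformly from the genome and accepted when their GC content and repeat
content match the enhancer within strict tolerances (defaults 0.005 and
0.01) and they overlap neither any enhancer nor a previously accepted
control.  When the search budget is exhausted the deficit is filled by
reshuffling the enhancer sequence itself (a mononucleotide permutation,
case travelling with its letter, so both matched statistics are preserved
exactly); such controls are flagged ``shuffled``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Genome, GenomicInterval, seq_stats

SAMPLED = "sampled"
SHUFFLED = "shuffled"


@dataclass
class ControlRecord:
    """One control for one enhancer."""

    enhancer_id: str
    origin: str                       # "sampled" or "shuffled"
    seq: str
    interval: Optional[GenomicInterval]   # None for shuffled controls
    d_gc: float
    d_repeat: float


@dataclass
class ControlSet:
    records: List[ControlRecord] = field(default_factory=list)

    def for_enhancer(self, enhancer_id: str) -> List[ControlRecord]:
        return [r for r in self.records if r.enhancer_id == enhancer_id]

    @property
    def sequences(self) -> List[str]:
        return [r.seq for r in self.records]

    def sampled_fraction(self) -> float:
        if not self.records:
            return float("nan")
        return sum(r.origin == SAMPLED for r in self.records) / len(self.records)


def shuffle_fallback(seq: str, seed: int) -> str:
    """Uniform random permutation of the sequence's letters (case-linked)."""
    if not seq:
        raise ValueError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq))
    rng.shuffle(letters)
    return "".join(letters)


class MatchedControlSampler:
    """Draws matched controls from a genome with O(1) per-candidate cost.

    Prefix sums of GC, AT and lowercase indicators are precomputed per
    chromosome so candidate window statistics need no sequence slicing.
    """

    def __init__(self, genome: Genome,
                 exclusions: Sequence[GenomicInterval] = ()):
        self.genome = genome
        self._gc: Dict[str, np.ndarray] = {}
        self._acgt: Dict[str, np.ndarray] = {}
        self._rep: Dict[str, np.ndarray] = {}
        self._blocked: Dict[str, np.ndarray] = {}
        for name, seq in genome.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            up = np.where((arr >= 97), arr - 32, arr)   # uppercase view
            is_gc = (up == ord("G")) | (up == ord("C"))
            is_at = (up == ord("A")) | (up == ord("T"))
            is_rep = arr >= 97
            self._gc[name] = np.concatenate(([0], np.cumsum(is_gc)))
            self._acgt[name] = np.concatenate(([0], np.cumsum(is_gc | is_at)))
            self._rep[name] = np.concatenate(([0], np.cumsum(is_rep)))
            self._blocked[name] = np.zeros(len(seq), dtype=bool)
        for iv in exclusions:
            self._blocked[iv.chrom][iv.start:iv.end] = True
        self._chroms = genome.names
        self._lengths = np.array([genome.length(c) for c in self._chroms])

    def _window_stats(self, chrom: str, start: int, end: int
                      ) -> Tuple[float, float]:
        gc = self._gc[chrom][end] - self._gc[chrom][start]
        acgt = self._acgt[chrom][end] - self._acgt[chrom][start]
        rep = self._rep[chrom][end] - self._rep[chrom][start]
        if acgt == 0:
            return float("nan"), rep / (end - start)
        return gc / acgt, rep / (end - start)

    def block(self, interval: GenomicInterval) -> None:
        self._blocked[interval.chrom][interval.start:interval.end] = True

    def sample_matched_controls(
        self,
        enhancer: GenomicInterval,
        n: int = 5,
        max_dgc: float = 0.005,
        max_drepeat: float = 0.01,
        seed: int = 0,
        max_tries: int = 10_000,
    ) -> List[ControlRecord]:
        """Up to ``n`` genome-sampled controls for one enhancer; the deficit
        is filled by :func:`shuffle_fallback` and flagged ``shuffled``.

        Accepted controls are blocked so controls never overlap each other
        (or, via the constructor exclusions, any enhancer).
        """
        length = len(enhancer)
        if all(genome_len < length for genome_len in self._lengths):
            raise ValueError(
                f"genome shorter than enhancer of length {length}"
            )
        enh_seq = self.genome.fetch(
            GenomicInterval(enhancer.chrom, enhancer.start, enhancer.end)
        )
        enh_gc, enh_rep = seq_stats(enh_seq)
        rng = np.random.default_rng(seed)
        eligible = [i for i, L in enumerate(self._lengths) if L >= length]
        weights = self._lengths[eligible] - length + 1
        weights = weights / weights.sum()
        out: List[ControlRecord] = []
        accepted: List[GenomicInterval] = []
        tries = 0
        while len(out) < n and tries < max_tries:
            tries += 1
            ci = eligible[rng.choice(len(eligible), p=weights)]
            chrom = self._chroms[ci]
            start = int(rng.integers(0, self._lengths[ci] - length + 1))
            end = start + length
            if self._blocked[chrom][start:end].any():
                continue
            gc, rep = self._window_stats(chrom, start, end)
            if np.isnan(gc):
                continue
            if abs(gc - enh_gc) <= max_dgc and abs(rep - enh_rep) <= max_drepeat:
                iv = GenomicInterval(chrom, start, end,
                                     id=f"{enhancer.id or 'enh'}_ctrl{len(out)}")
                out.append(ControlRecord(
                    enhancer_id=enhancer.id or "", origin=SAMPLED,
                    seq=self.genome.fetch(iv), interval=iv,
                    d_gc=abs(gc - enh_gc), d_repeat=abs(rep - enh_rep),
                ))
                accepted.append(iv)
                self.block(iv)
        while len(out) < n:
            shuf = shuffle_fallback(enh_seq, int(rng.integers(0, 2**31)))
            out.append(ControlRecord(
                enhancer_id=enhancer.id or "", origin=SHUFFLED,
                seq=shuf, interval=None, d_gc=0.0, d_repeat=0.0,
            ))
        return out


def sample_control_set(
    genome: Genome,
    enhancers: Sequence[GenomicInterval],
    n: int = 5,
    max_dgc: float = 0.005,
    max_drepeat: float = 0.01,
    seed: int = 0,
    max_tries: int = 10_000,
) -> ControlSet:
    """Matched controls for every enhancer (exclusions = all enhancers)."""
    sampler = MatchedControlSampler(genome, exclusions=enhancers)
    rng = np.random.default_rng(seed)
    cs = ControlSet()
    for enh in enhancers:
        recs = sampler.sample_matched_controls(
            enh, n=n, max_dgc=max_dgc, max_drepeat=max_drepeat,
            seed=int(rng.integers(0, 2**31)), max_tries=max_tries,
        )
        cs.records.extend(recs)
    return cs
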