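"""Canonical k-mer vocabularies built by Fisher enrichment.

A vocabulary partitions all canonical k-mers (a k-mer and its reverse
complement share one count) into three classes relative to a matched
control set:

* ``top`` — significantly enriched in enhancers (one-sided Fisher test,
  Bonferroni-corrected p <= alpha, default 1e-3) with enhancer window
  density above control density; these carry a log2 enrichment weight;
* ``background`` — clearly unenriched (raw p > alpha); weight 0;
* ``neutral`` — everything in between; weight 0.

K-mers never observed in either set have raw p = 1 and are background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import Genome, GenomicInterval, SignalTrack, encode_sequence, revcomp

TOP = "top"
BACKGROUND = "background"
NEUTRAL = "neutral"

_CANON_TRANS = str.maketrans("ACGT", "TGCA")


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    up = kmer.upper()
    if set(up) - set("ACGT"):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    rc = up.translate(_CANON_TRANS)[::-1]
    return up if up <= rc else rc


def count_distinct_canonical(k: int) -> int:
    """Number of reverse-complement equivalence classes of k-mers.

    For even k there are 4**(k/2) self-reverse-complementary words, each
    its own class; odd-length words are never palindromic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    palindromes = 4 ** (k // 2) if k % 2 == 0 else 0
    return (4**k + palindromes) // 2


def _window_codes(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement integer codes of every valid window.

    Returns (canonical_codes, valid_mask) over all ``len - k + 1`` windows;
    windows touching masked (-1) bases are invalid.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    valid = (win >= 0).all(axis=1)
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = (np.where(win < 0, 0, win) * pw).sum(axis=1)
    rev = ((3 - np.where(win < 0, 0, win)) * pw[::-1]).sum(axis=1)
    return np.minimum(fwd, rev), valid


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_occurrences(seqs: Iterable[str], k: int) -> Tuple[Dict[int, int], int]:
    """Count every valid length-k window under its canonical integer code.

    Windows containing ``N`` or lowercase (repeat-masked) bases are skipped.
    Returns ``(counts, total_valid_windows)``.
    """
    counts: Dict[int, int] = {}
    total = 0
    for seq in seqs:
        codes = encode_sequence(seq)
        can, valid = _window_codes(codes, k)
        can = can[valid]
        total += len(can)
        if len(can):
            uniq, cnt = np.unique(can, return_counts=True)
            for u, c in zip(uniq.tolist(), cnt.tolist()):
                counts[u] = counts.get(u, 0) + c
    return counts, total


@dataclass
class KmerVocabulary:
    """Per-(k, track) partition of canonical k-mers with enrichment weights.

    Only observed k-mers are stored explicitly; absent k-mers are
    ``background`` with weight 0.
    """

    k: int
    track: str
    enh_total: int
    ctrl_total: int
    enh_counts: Dict[int, int]
    ctrl_counts: Dict[int, int]
    p_raw: Dict[int, float]
    classes: Dict[int, str]
    weights: Dict[int, float]

    def canonical_code(self, kmer: str) -> int:
        can = canonical(kmer)
        code = 0
        for c in can:
            code = code * 4 + "ACGT".index(c)
        return code

    def class_of(self, kmer: str) -> str:
        return self.classes.get(self.canonical_code(kmer), BACKGROUND)

    def class_of_code(self, code: int) -> str:
        return self.classes.get(code, BACKGROUND)

    def weight_of_code(self, code: int) -> float:
        return self.weights.get(code, 0.0)

    @property
    def n_top(self) -> int:
        return sum(1 for c in self.classes.values() if c == TOP)

    def class_sizes(self) -> Dict[str, int]:
        """Class sizes over the full canonical universe (absent = background)."""
        sizes = {TOP: 0, BACKGROUND: 0, NEUTRAL: 0}
        for c in self.classes.values():
            sizes[c] += 1
        sizes[BACKGROUND] += count_distinct_canonical(self.k) - len(self.classes)
        return sizes

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                decode_kmer(code, self.k),
                self.k,
                self.track,
                self.enh_counts.get(code, 0),
                self.ctrl_counts.get(code, 0),
                self.p_raw[code],
                self.classes[code],
                self.weights.get(code, 0.0),
            )
            for code in sorted(self.classes)
        ]
        return pd.DataFrame(
            rows,
            columns=["kmer", "k", "track", "enh_count", "ctrl_count",
                     "p_raw", "class", "weight"],
        )


def classify_kmers(
    enh_counts: Dict[int, int],
    ctrl_counts: Dict[int, int],
    k: int,
    enh_total: int,
    ctrl_total: int,
    alpha: float = 1e-3,
    track: str = "pooled",
) -> KmerVocabulary:
    """Partition canonical k-mers into top / background / neutral.

    For each k-mer the 2x2 table is [this k-mer vs all other k-mer windows]
    x [enhancers vs controls]; the one-sided (enrichment) Fisher exact
    p-value equals the hypergeometric upper tail.  ``top`` requires the
    Bonferroni-corrected p (factor = number of canonical k-mers) <= alpha
    AND enhancer window density above control density; ``background`` is
    raw p > alpha; the rest are ``neutral``.
    """
    if enh_total <= 0 or ctrl_total <= 0:
        raise ValueError("empty k-mer universe: no valid windows counted")
    codes = sorted(set(enh_counts) | set(ctrl_counts))
    a = np.array([enh_counts.get(c, 0) for c in codes], dtype=np.int64)
    c_ = np.array([ctrl_counts.get(c, 0) for c in codes], dtype=np.int64)
    M = enh_total + ctrl_total
    # P(X >= a) with X ~ Hypergeom(M, a+c, enh_total)
    p = hypergeom.sf(a - 1, M, a + c_, enh_total)
    p = np.clip(p, 0.0, 1.0)
    bonf = count_distinct_canonical(k)
    enh_density = a / enh_total
    ctrl_density = c_ / ctrl_total
    eps = 1.0 / M
    classes: Dict[int, str] = {}
    weights: Dict[int, float] = {}
    p_raw: Dict[int, float] = {}
    for i, code in enumerate(codes):
        pi = float(p[i])
        p_raw[code] = pi
        if pi * bonf <= alpha and enh_density[i] > ctrl_density[i]:
            classes[code] = TOP
            weights[code] = float(
                np.log2((enh_density[i] + eps) / (ctrl_density[i] + eps))
            )
        elif pi > alpha:
            classes[code] = BACKGROUND
        else:
            classes[code] = NEUTRAL
    return KmerVocabulary(
        k=k, track=track, enh_total=enh_total, ctrl_total=ctrl_total,
        enh_counts=dict(enh_counts), ctrl_counts=dict(ctrl_counts),
        p_raw=p_raw, classes=classes, weights=weights,
    )


def kmer_weight(vocab: KmerVocabulary, kmer: str) -> float:
    """Log2 enrichment weight of a k-mer; 0 for background and neutral."""
    return vocab.weights.get(vocab.canonical_code(kmer), 0.0)


def build_vocabulary(
    enh_seqs: Sequence[str],
    ctrl_seqs: Sequence[str],
    k: int,
    alpha: float = 1e-3,
    track: str = "pooled",
) -> KmerVocabulary:
    enh_counts, enh_total = kmer_occurrences(enh_seqs, k)
    ctrl_counts, ctrl_total = kmer_occurrences(ctrl_seqs, k)
    return classify_kmers(
        enh_counts, ctrl_counts, k, enh_total, ctrl_total, alpha=alpha,
        track=track,
    )


def _subsequences_overlapping(
    genome: Genome,
    intervals: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
) -> List[str]:
    """Sub-sequences of ``intervals`` clipped to peak overlaps."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for v in by_chrom.values():
        v.sort()
    out: List[str] = []
    for iv in intervals:
        for ps, pe in by_chrom.get(iv.chrom, []):
            s, e = max(iv.start, ps), min(iv.end, pe)
            if s < e:
                out.append(genome[iv.chrom][s:e])
    return out


def build_vocabularies(
    genome: Genome,
    enhancers: Sequence[GenomicInterval],
    control_seqs: Sequence[str],
    tracks: Sequence[SignalTrack],
    k_sizes: Sequence[int] = (4, 6, 8, 10, 12),
    alpha: float = 1e-3,
    peak_quantile: float = 0.5,
) -> Dict[Tuple[int, str], KmerVocabulary]:
    """One vocabulary per (k, track) plus a pooled vocabulary per k.

    Per-track vocabularies are learned from the enhancer sub-sequences
    overlapping that track's peaks (intervals above ``peak_quantile`` of
    track values); the pooled vocabulary uses the full enhancer sequences.
    Controls are shared across tracks.
    """
    vocabs: Dict[Tuple[int, str], KmerVocabulary] = {}
    enh_seqs = [genome.fetch(iv) for iv in enhancers]
    for k in k_sizes:
        vocabs[(k, "pooled")] = build_vocabulary(
            enh_seqs, control_seqs, k, alpha=alpha, track="pooled"
        )
    for tr in tracks:
        peaks = tr.peaks(peak_quantile)
        sub = _subsequences_overlapping(genome, enhancers, peaks)
        if not sub:
            sub = enh_seqs
        for k in k_sizes:
            vocabs[(k, tr.name)] = build_vocabulary(
                sub, control_seqs, k, alpha=alpha, track=tr.name
            )
    return vocabs


def vocabularies_to_frame(
    vocabs: Dict[Tuple[int, str], KmerVocabulary]
) -> pd.DataFrame:
    return pd.concat([v.to_frame() for v in vocabs.values()],
                     ignore_index=True)
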