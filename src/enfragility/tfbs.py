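"""PSSM scanning with FPR calibration, TFBS enrichment, cluster typing
and deMP position profiles along motifs.

Thresholds are calibrated so that scanning a neutral background sequence
yields about a target density of hits (default 5 per 10 kb, both strands
pooled).  Scanning skips any window touching an ``N`` or a lowercase
(repeat-masked) base.  Enrichment of a TF's sites in an enhancer set over
a control set normalizes hit counts by non-repetitive sequence length:

    enrichment = (n_enh / L_enh) / (n_ctrl / L_ctrl)

with a 0.5 continuity guard on the control count only when it is zero.
A homotypic cluster is >= 3 sites of one TF spanning <= 1 kb; a
heterotypic cluster is >= 3 sites of >= 3 distinct TFs spanning <= 1 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (Genome, GenomicInterval, UndefinedStatisticError,
                   encode_sequence)

HOMOTYPIC = "homotypic"
HETEROTYPIC = "heterotypic"


@dataclass
class PSSM:
    """Log-odds position-specific scoring matrix against a uniform
    background, with an optional calibrated hit threshold."""

    tf: str
    matrix: np.ndarray               # width x 4, log2-odds over A,C,G,T
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PSSM matrix must be width x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PSSM width must be >= 4")
        if not np.isfinite(self.matrix).all():
            raise ValueError("PSSM entries must be finite")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_probabilities(cls, tf: str, probs: np.ndarray,
                           pseudo: float = 1e-3) -> "PSSM":
        probs = np.asarray(probs, dtype=float)
        probs = (probs + pseudo) / (probs + pseudo).sum(axis=1, keepdims=True)
        return cls(tf, np.log2(probs / 0.25))

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


@dataclass(frozen=True)
class TFBSHit:
    tf: str
    interval: GenomicInterval
    strand: str
    score: float


@dataclass
class TFBSCluster:
    members: List[TFBSHit]
    type: str

    @property
    def span(self) -> int:
        return (max(h.interval.end for h in self.members)
                - min(h.interval.start for h in self.members))

    @property
    def tfs(self) -> set:
        return {h.tf for h in self.members}


def _window_scores(codes: np.ndarray, matrix: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Scores of all plus-strand windows and a validity mask."""
    w = matrix.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win < 0, 0, win)
    scores = matrix[np.arange(w)[None, :], safe].sum(axis=1)
    return scores, valid


def _revcomp_matrix(matrix: np.ndarray) -> np.ndarray:
    return matrix[::-1, ::-1]


def scan_scores(seq: str, pssm: PSSM) -> Tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
    """Per-start plus- and minus-strand scores plus validity mask."""
    codes = encode_sequence(seq)
    plus, valid = _window_scores(codes, pssm.matrix)
    minus, _ = _window_scores(codes, _revcomp_matrix(pssm.matrix))
    return plus, minus, valid


def calibrate_pssm_threshold(
    pssm: PSSM,
    background_seq: str,
    target_rate: float = 5.0,
    per_bp: int = 10_000,
) -> float:
    """Smallest score whose both-strand hit density on the background is
    at most ``target_rate`` hits per ``per_bp`` bases."""
    if len(background_seq) < 100_000:
        import warnings
        warnings.warn("background shorter than 100 kb: calibration is coarse",
                      stacklevel=2)
    plus, minus, valid = scan_scores(background_seq, pssm)
    scores = np.concatenate([plus[valid], minus[valid]])
    if scores.size == 0:
        raise ValueError("background has no valid windows")
    L = len(background_seq)
    max_hits = target_rate * L / per_bp
    uniq, counts = np.unique(scores, return_counts=True)
    # hits at threshold uniq[i] = count of scores >= uniq[i]
    ge_counts = counts[::-1].cumsum()[::-1]
    ok = np.flatnonzero(ge_counts <= max_hits)
    if ok.size == 0:
        raise ValueError(
            f"cannot attain {target_rate} hits per {per_bp} bp for PSSM "
            f"{pssm.tf!r}: score ties are degenerate"
        )
    return float(uniq[ok[0]])


def scan_pssm(
    seq: str, pssm: PSSM, chrom: str = "chr1", offset: int = 0
) -> List[TFBSHit]:
    """Both-strand hits with score >= the calibrated threshold; windows
    touching N/lowercase are skipped; overlapping hits are not merged."""
    if pssm.threshold is None:
        raise ValueError(f"PSSM {pssm.tf!r} has no calibrated threshold")
    plus, minus, valid = scan_scores(seq, pssm)
    hits: List[TFBSHit] = []
    w = pssm.width
    plus_idx = np.flatnonzero(valid & (plus >= pssm.threshold))
    minus_idx = np.flatnonzero(valid & (minus >= pssm.threshold))
    for i in plus_idx:
        s = offset + int(i)
        hits.append(TFBSHit(
            pssm.tf, GenomicInterval(chrom, s, s + w), "+", float(plus[i])))
    for i in minus_idx:
        s = offset + int(i)
        hits.append(TFBSHit(
            pssm.tf, GenomicInterval(chrom, s, s + w), "-", float(minus[i])))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def tfbs_enrichment(
    n_hits_enh: int, n_hits_ctrl: int,
    nonrep_len_enh: int, nonrep_len_ctrl: int,
) -> float:
    """Density-normalized fold enrichment of a TF's sites in enhancers
    over controls (0.5 continuity guard when the control count is zero)."""
    if nonrep_len_enh <= 0 or nonrep_len_ctrl <= 0:
        raise ValueError("zero non-repetitive length")
    ctrl = n_hits_ctrl if n_hits_ctrl > 0 else 0.5
    return (n_hits_enh / nonrep_len_enh) / (ctrl / nonrep_len_ctrl)


def fraction_sites_with_demp(
    hits: Sequence[TFBSHit], demps: Iterable[int]
) -> float:
    """Fraction of hits whose interval holds >= 1 deMP (counted once per
    hit regardless of deMP multiplicity)."""
    if not hits:
        return 0.0
    dset = sorted(set(demps))
    arr = np.asarray(dset, dtype=int)
    n = 0
    for h in hits:
        lo = np.searchsorted(arr, h.interval.start, side="left")
        if lo < len(arr) and arr[lo] < h.interval.end:
            n += 1
    return n / len(hits)


def find_clusters(
    hits: Sequence[TFBSHit], min_sites: int = 3, max_span: int = 1000
) -> List[TFBSCluster]:
    """Homotypic and heterotypic TFBS clusters within one enhancer.

    Homotypic: maximal windows of >= ``min_sites`` same-TF hits spanning
    <= ``max_span``.  Heterotypic: maximal windows of hits from >=
    ``min_sites`` distinct TFs spanning <= ``max_span`` (so a homotypic
    window is never also typed heterotypic).
    """
    clusters: List[TFBSCluster] = []
    shits = sorted(hits, key=lambda h: (h.interval.start, h.interval.end,
                                        h.tf, h.strand))

    def _maximal_windows(group: List[TFBSHit]) -> List[List[TFBSHit]]:
        wins: List[Tuple[int, int]] = []
        j = 0
        for i in range(len(group)):
            j = max(j, i)
            while (j + 1 < len(group)
                   and max(h.interval.end for h in group[i:j + 2])
                   - group[i].interval.start <= max_span):
                j += 1
            if (j - i + 1 >= min_sites
                    and max(h.interval.end for h in group[i:j + 1])
                    - group[i].interval.start <= max_span):
                if not wins or wins[-1][1] < j:
                    wins.append((i, j))
        return [group[a:b + 1] for a, b in wins]

    by_tf: Dict[str, List[TFBSHit]] = {}
    for h in shits:
        by_tf.setdefault(h.tf, []).append(h)
    for tf, group in sorted(by_tf.items()):
        for members in _maximal_windows(group):
            clusters.append(TFBSCluster(members, HOMOTYPIC))
    for members in _maximal_windows(shits):
        if len({h.tf for h in members}) >= min_sites:
            clusters.append(TFBSCluster(members, HETEROTYPIC))
    return clusters


def cluster_flags(clusters: Sequence[TFBSCluster]) -> Tuple[bool, bool]:
    """(has_homotypic, has_heterotypic) for one enhancer."""
    return (any(c.type == HOMOTYPIC for c in clusters),
            any(c.type == HETEROTYPIC for c in clusters))


def htc_fraction(tf: str, hits: Sequence[TFBSHit],
                 clusters: Sequence[TFBSCluster]) -> float:
    """Fraction of a TF's hits belonging to >= 1 of its homotypic clusters."""
    tf_hits = [h for h in hits if h.tf == tf]
    if not tf_hits:
        raise UndefinedStatisticError(f"TF {tf!r} has zero hits")
    in_cluster = set()
    for c in clusters:
        if c.type == HOMOTYPIC and c.members[0].tf == tf:
            in_cluster.update(c.members)   # hits are frozen/hashable
    return sum(1 for h in tf_hits if h in in_cluster) / len(tf_hits)


def demp_motif_profile(
    hits: Sequence[TFBSHit], demps: Iterable[int], pssm_width: int
) -> np.ndarray:
    """Counts of deMPs per motif position (minus-strand hits mirrored)."""
    profile = np.zeros(pssm_width, dtype=int)
    dset = sorted(set(demps))
    for h in hits:
        for p in dset:
            if h.interval.start <= p < h.interval.end:
                off = p - h.interval.start
                if h.strand == "-":
                    off = pssm_width - 1 - off
                profile[off] += 1
    return profile


def nonrepetitive_length(genome: Genome,
                         intervals: Sequence[GenomicInterval]) -> int:
    """Total uppercase (non-repeat) bases over the intervals."""
    total = 0
    for iv in intervals:
        seq = genome[iv.chrom][iv.start:iv.end]
        total += sum(1 for c in seq if not c.islower())
    return total
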