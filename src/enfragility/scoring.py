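"""Deactivating-mutation (deM) scoring with an exactly decomposable score.

A candidate deactivating mutation is a substitution that flips at least
one covering 8-mer from the ``top`` vocabulary class to ``background``.
Each candidate is described, for every k-mer size k in {4,6,8,10,12} and
every chromatin signal track j, by two signatures:

* ``Delta_kj`` — the disruptive effect on the cognate motif: the largest
  drop in top-k-mer weight over the k windows covering the variant,
  floored at 0;
* ``S_kj`` — the binding capability of the neighbourhood: the summed
  weight of top-k-mer windows fully inside +-``flank_window`` bp of the
  variant that do not cover the variant itself.

A linear maximum-margin classifier over these features yields a margin
that partitions exactly into a motif-disruption term WS(Delta), a
neighbourhood term WS(S) and an intercept; the reported score is the
logistic map of the margin.  The deM threshold is calibrated as the
empirical (1 - FPR) quantile of negative-control scores (FPR 0.01 by
default); a position where at least one of the three possible
substitutions is a deM is a deMP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .core import Genome, GenomicInterval, VariantRecord, encode_sequence
from .kmers import BACKGROUND, TOP, KmerVocabulary, _window_codes

_BASES = "ACGT"


@dataclass(frozen=True)
class FeatureSchema:
    """Feature layout: (Delta, S) per k-mer size per signal track."""

    tracks: Tuple[str, ...]
    k_sizes: Tuple[int, ...] = (4, 6, 8, 10, 12)
    flank_window: int = 100

    @property
    def n_features(self) -> int:
        return len(self.k_sizes) * 2 * len(self.tracks)

    def index(self, track: str, k: int, signature: str) -> int:
        t = self.tracks.index(track)
        ki = self.k_sizes.index(k)
        s = {"delta": 0, "s": 1}[signature]
        return (t * len(self.k_sizes) + ki) * 2 + s

    def labels(self) -> List[Tuple[str, int, str]]:
        return [
            (tr, k, sig)
            for tr in self.tracks
            for k in self.k_sizes
            for sig in ("delta", "s")
        ]

    @property
    def delta_mask(self) -> np.ndarray:
        return np.array([sig == "delta" for _, _, sig in self.labels()])


@dataclass
class WeightSet:
    """Linear weights over a :class:`FeatureSchema` plus an intercept."""

    schema: FeatureSchema
    weights: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.schema.n_features,):
            raise ValueError(
                f"weight vector length {self.weights.shape} does not match "
                f"schema ({self.schema.n_features} features)"
            )

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("k\ttrack\tsignature\tweight\n")
            for (tr, k, sig), w in zip(self.schema.labels(), self.weights):
                fh.write(f"{k}\t{tr}\t{sig}\t{float(w)!r}\n")
            fh.write(f"0\t.\tintercept\t{float(self.intercept)!r}\n")

    @classmethod
    def load_tsv(cls, path, flank_window: int = 100) -> "WeightSet":
        rows = []
        intercept = 0.0
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                k, tr, sig, w = line.rstrip("\n").split("\t")
                if sig == "intercept":
                    intercept = float(w)
                else:
                    rows.append((int(k), tr, sig, float(w)))
        tracks = tuple(dict.fromkeys(tr for _, tr, _, _ in rows))
        ks = tuple(sorted({k for k, _, _, _ in rows}))
        schema = FeatureSchema(tracks=tracks, k_sizes=ks,
                               flank_window=flank_window)
        vec = np.zeros(schema.n_features)
        for k, tr, sig, w in rows:
            vec[schema.index(tr, k, sig)] = w
        return cls(schema, vec, intercept)


@dataclass
class ScoreDecomposition:
    """A variant's margin split into WS(Delta) + WS(S) + intercept."""

    ws_delta: float
    ws_s: float
    intercept: float

    @property
    def margin(self) -> float:
        return self.ws_delta + self.ws_s + self.intercept

    @property
    def score(self) -> float:
        return float(expit(self.margin))


@dataclass
class DeMCall:
    variant: VariantRecord
    decomposition: ScoreDecomposition
    is_dem: bool


# ---------------------------------------------------------------------------
# reference (windows-loop) feature implementations


def _local_pos(seq_len: int, offset: int, variant: VariantRecord) -> int:
    pos = variant.pos - offset
    if not (0 <= pos < seq_len):
        raise ValueError("variant outside the provided sequence")
    return pos


def _alt_codes(codes: np.ndarray, pos: int, alt: str) -> np.ndarray:
    out = codes.copy()
    out[pos] = _BASES.index(alt.upper())
    return out


def delta_feature(
    seq: str, variant: VariantRecord, vocab: KmerVocabulary,
    offset: int = 0,
) -> float:
    """Max over covering windows of (ref-window weight − alt-window weight),
    floored at 0; windows touching masked bases are skipped."""
    k = vocab.k
    pos = _local_pos(len(seq), offset, variant)
    ref_codes = encode_sequence(seq)
    alt_codes = _alt_codes(ref_codes, pos, variant.alt)
    ref_can, ref_valid = _window_codes(ref_codes, k)
    alt_can, alt_valid = _window_codes(alt_codes, k)
    best = 0.0
    for i in range(max(0, pos - k + 1), min(len(ref_can), pos + 1)):
        if not (ref_valid[i] and alt_valid[i]):
            continue
        d = vocab.weight_of_code(int(ref_can[i])) - vocab.weight_of_code(
            int(alt_can[i]))
        best = max(best, d)
    return best


def s_feature(
    seq: str, variant: VariantRecord, vocab: KmerVocabulary,
    flank_window: int = 100, offset: int = 0,
) -> float:
    """Summed weight of top windows fully inside ±flank_window of the
    variant that do not cover the variant position."""
    k = vocab.k
    pos = _local_pos(len(seq), offset, variant)
    can, valid = _window_codes(encode_sequence(seq), k)
    total = 0.0
    lo = max(0, pos - flank_window)
    hi = min(len(can) - 1, pos + flank_window - k + 1)
    for i in range(lo, hi + 1):
        if not valid[i]:
            continue
        if i <= pos <= i + k - 1:
            continue
        total += vocab.weight_of_code(int(can[i]))
    return total


def extract_features(
    variant: VariantRecord,
    seq: str,
    vocabularies: Dict[Tuple[int, str], KmerVocabulary],
    schema: FeatureSchema,
    offset: int = 0,
) -> np.ndarray:
    """Reference feature extractor (loop over windows); the fast path in
    :class:`EnhancerScorer` must agree with this exactly."""
    fv = np.zeros(schema.n_features)
    for tr in schema.tracks:
        for k in schema.k_sizes:
            if (k, tr) not in vocabularies:
                raise KeyError(f"missing vocabulary for (k={k}, track={tr!r})")
            vocab = vocabularies[(k, tr)]
            fv[schema.index(tr, k, "delta")] = delta_feature(
                seq, variant, vocab, offset=offset)
            fv[schema.index(tr, k, "s")] = s_feature(
                seq, variant, vocab, schema.flank_window, offset=offset)
    return fv


# ---------------------------------------------------------------------------
# fast per-enhancer scorer


class EnhancerScorer:
    """Precomputes window codes and top-weight prefix sums for one sequence
    so candidate enumeration and feature extraction are O(k) per variant."""

    def __init__(
        self,
        seq: str,
        vocabularies: Dict[Tuple[int, str], KmerVocabulary],
        schema: FeatureSchema,
        chrom: str = "chr1",
        offset: int = 0,
    ):
        self.seq = seq
        self.chrom = chrom
        self.offset = offset
        self.schema = schema
        self.vocabs = vocabularies
        self.codes = encode_sequence(seq)
        L = len(seq)
        self._fwd: Dict[int, np.ndarray] = {}
        self._rev: Dict[int, np.ndarray] = {}
        self._valid: Dict[int, np.ndarray] = {}
        self._wt: Dict[Tuple[int, str], np.ndarray] = {}
        self._prefix: Dict[Tuple[int, str], np.ndarray] = {}
        ks = sorted(set(schema.k_sizes) | {8})
        for k in ks:
            n = max(L - k + 1, 0)
            if n == 0:
                self._fwd[k] = np.empty(0, dtype=np.int64)
                self._rev[k] = np.empty(0, dtype=np.int64)
                self._valid[k] = np.empty(0, dtype=bool)
                continue
            win = np.lib.stride_tricks.sliding_window_view(
                self.codes, k).astype(np.int64)
            valid = (win >= 0).all(axis=1)
            safe = np.where(win < 0, 0, win)
            pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
            self._fwd[k] = (safe * pw).sum(axis=1)
            self._rev[k] = ((3 - safe) * pw[::-1]).sum(axis=1)
            self._valid[k] = valid
        for (k, tr), vocab in vocabularies.items():
            if k not in self._fwd:
                continue
            can = np.minimum(self._fwd[k], self._rev[k])
            wt = np.array(
                [vocab.weights.get(int(c), 0.0) for c in can], dtype=float
            )
            wt[~self._valid[k]] = 0.0
            self._wt[(k, tr)] = wt
            self._prefix[(k, tr)] = np.concatenate(([0.0], np.cumsum(wt)))

    # -- candidates ---------------------------------------------------------

    def candidate_substitutions(
        self, vocab_k8: KmerVocabulary
    ) -> List[VariantRecord]:
        """All substitutions flipping at least one covering 8-mer from top
        to background (windows with masked bases skipped)."""
        k = 8
        fwd, rev, valid = self._fwd[k], self._rev[k], self._valid[k]
        can = np.minimum(fwd, rev)
        classes = vocab_k8.classes
        top_windows = np.array(
            [valid[i] and classes.get(int(can[i])) == TOP
             for i in range(len(can))], dtype=bool,
        )
        out: List[VariantRecord] = []
        top_idx = np.flatnonzero(top_windows)
        cand_positions: Dict[int, set] = {}
        pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for i in top_idx:
            for off in range(k):
                pos = i + off
                ref_code = int(self.codes[pos])
                for alt_code in range(4):
                    if alt_code == ref_code:
                        continue
                    altfwd = int(fwd[i]) + (alt_code - ref_code) * int(pw[off])
                    altrev = int(rev[i]) + (ref_code - alt_code) * int(
                        pw[k - 1 - off])
                    alt_can = min(altfwd, altrev)
                    # absent codes default to background
                    if classes.get(alt_can, BACKGROUND) == BACKGROUND:
                        cand_positions.setdefault(pos, set()).add(alt_code)
        for pos in sorted(cand_positions):
            ref = _BASES[int(self.codes[pos])]
            for alt_code in sorted(cand_positions[pos]):
                out.append(VariantRecord(
                    self.chrom, self.offset + pos, ref, _BASES[alt_code]))
        return out

    # -- features -----------------------------------------------------------

    def _delta_fast(self, pos: int, alt_code: int, k: int, tr: str) -> float:
        fwd, rev, valid = self._fwd[k], self._rev[k], self._valid[k]
        vocab = self.vocabs[(k, tr)]
        wt = self._wt[(k, tr)]
        ref_code = int(self.codes[pos])
        best = 0.0
        lo = max(0, pos - k + 1)
        hi = min(len(fwd) - 1, pos)
        for i in range(lo, hi + 1):
            if not valid[i]:
                continue
            off = pos - i
            p_hi = 4 ** (k - 1 - off)
            p_lo = 4 ** off
            altfwd = int(fwd[i]) + (alt_code - ref_code) * p_hi
            altrev = int(rev[i]) + (ref_code - alt_code) * p_lo
            d = wt[i] - vocab.weights.get(min(altfwd, altrev), 0.0)
            if d > best:
                best = d
        return best

    def _s_fast(self, pos: int, k: int, tr: str) -> float:
        W = self.schema.flank_window
        pre = self._prefix[(k, tr)]
        nwin = len(pre) - 1
        if nwin == 0:
            return 0.0
        lo = max(0, pos - W)
        hi = min(nwin - 1, pos + W - k + 1)
        if hi < lo:
            return 0.0
        total = pre[hi + 1] - pre[lo]
        c = max(lo, pos - k + 1)
        d = min(hi, pos)
        if d >= c:
            total -= pre[d + 1] - pre[c]
        return float(total)

    def features(self, variant: VariantRecord) -> np.ndarray:
        pos = _local_pos(len(self.seq), self.offset, variant)
        alt_code = _BASES.index(variant.alt.upper())
        fv = np.zeros(self.schema.n_features)
        for tr in self.schema.tracks:
            for k in self.schema.k_sizes:
                fv[self.schema.index(tr, k, "delta")] = self._delta_fast(
                    pos, alt_code, k, tr)
                fv[self.schema.index(tr, k, "s")] = self._s_fast(pos, k, tr)
        return fv

    def feature_matrix(self, variants: Sequence[VariantRecord]) -> np.ndarray:
        if not variants:
            return np.zeros((0, self.schema.n_features))
        return np.vstack([self.features(v) for v in variants])


def candidate_dems(
    seq: str,
    vocab_k8: KmerVocabulary,
    chrom: str = "chr1",
    offset: int = 0,
) -> List[VariantRecord]:
    """Substitutions changing at least one covering top 8-mer into a
    background 8-mer (the IGR-style candidate filter)."""
    schema = FeatureSchema(tracks=(), k_sizes=(8,))
    scorer = EnhancerScorer(seq, {}, schema, chrom=chrom, offset=offset)
    return scorer.candidate_substitutions(vocab_k8)


# ---------------------------------------------------------------------------
# fitting, scoring, calibration


def score_and_decompose(fv: np.ndarray, weights: WeightSet
                        ) -> ScoreDecomposition:
    fv = np.asarray(fv, dtype=float)
    if fv.shape != weights.weights.shape:
        raise ValueError(
            f"feature vector length {fv.shape} does not match weight layout "
            f"{weights.weights.shape}"
        )
    dmask = weights.schema.delta_mask
    ws_delta = float(fv[dmask] @ weights.weights[dmask])
    ws_s = float(fv[~dmask] @ weights.weights[~dmask])
    return ScoreDecomposition(ws_delta, ws_s, weights.intercept)


def fit_weights(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    schema: FeatureSchema,
    folds: int = 5,
    seed: int = 0,
    c_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
) -> Tuple[WeightSet, Dict]:
    """Fit a linear maximum-margin classifier with 5-fold CV model choice.

    The regularization strength is chosen by mean out-of-fold ROC AUC over
    ``c_grid``; the final SVM is refit on all data, and a logistic
    (Platt-style) probability map is fitted on the pooled held-out margins
    and folded into the weight vector, so the reported score is exactly the
    logistic of the (rescaled) margin and the WS(Delta)+WS(S)+b
    decomposition is preserved.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    cv_auc = {}
    oof_margin = {c: np.zeros(len(y)) for c in c_grid}
    for c in c_grid:
        aucs = []
        for tr_idx, te_idx in splits:
            clf = LinearSVC(C=c, max_iter=20_000, tol=1e-5)
            clf.fit(X[tr_idx], y[tr_idx])
            m = clf.decision_function(X[te_idx])
            oof_margin[c][te_idx] = m
            aucs.append(roc_auc_score(y[te_idx], m))
        cv_auc[c] = float(np.mean(aucs))
    best_c = max(c_grid, key=lambda c: (cv_auc[c], -c))
    clf = LinearSVC(C=best_c, max_iter=20_000, tol=1e-5)
    clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    # Platt map on held-out margins; fold the (positive) slope into the
    # weights so score == logistic(margin) still holds exactly.
    platt = LogisticRegression(C=1e6, max_iter=10_000)
    platt.fit(oof_margin[best_c].reshape(-1, 1), y)
    a = float(platt.coef_[0, 0])
    c0 = float(platt.intercept_[0])
    if a > 0:
        w = a * w
        b = a * b + c0
    report = {
        "cv_auc": cv_auc,
        "best_c": best_c,
        "oof_auc": float(roc_auc_score(y, oof_margin[best_c])),
        "platt": (a, c0),
    }
    return WeightSet(schema, w, b), report


def calibrate_fpr_threshold(
    negative_scores: Sequence[float], fpr: float = 0.01
) -> float:
    """Smallest score t such that the fraction of negatives >= t is <= fpr.

    With ``fpr=1.0`` this is the minimum score.  When no observed score
    satisfies the bound (tiny samples or heavy ties at the maximum) the
    threshold is placed just above the maximum.
    """
    scores = np.asarray(list(negative_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot calibrate a threshold from zero scores")
    if scores.size < 1.0 / fpr:
        warnings.warn(
            f"only {scores.size} negative scores for FPR {fpr}: calibration "
            "is coarse", stacklevel=2,
        )
    n = scores.size
    uniq, counts = np.unique(scores, return_counts=True)
    ge_counts = counts[::-1].cumsum()[::-1]   # scores >= uniq[i]
    ok = np.flatnonzero(ge_counts / n <= fpr)
    if ok.size == 0:
        return float(np.nextafter(scores.max(), np.inf))
    return float(uniq[ok[0]])


def call_demps(
    scorer: EnhancerScorer,
    vocab_k8: KmerVocabulary,
    weights: WeightSet,
    threshold: float,
) -> Tuple[List[int], List[DeMCall]]:
    """Score every candidate substitution of one enhancer and return the
    deMP positions (genomic) plus all calls.

    A position is a deMP iff at least one of its scored substitutions has
    score >= threshold (ties count as deMs).
    """
    candidates = scorer.candidate_substitutions(vocab_k8)
    calls: List[DeMCall] = []
    demps = set()
    for v in candidates:
        fv = scorer.features(v)
        dec = score_and_decompose(fv, weights)
        is_dem = dec.score >= threshold
        calls.append(DeMCall(v, dec, is_dem))
        if is_dem:
            demps.add(v.pos)
    return sorted(demps), calls
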