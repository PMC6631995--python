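"""deM scoring: candidates, Delta/S features, fitting, decomposition and
FPR calibration."""

import numpy as np
import pytest
from scipy.special import expit

from enfragility import (FeatureSchema, ScoreDecomposition, VariantRecord,
                         WeightSet, calibrate_fpr_threshold, call_demps,
                         candidate_dems, delta_feature, extract_features,
                         fit_weights, s_feature, score_and_decompose)
from enfragility.kmers import (BACKGROUND, NEUTRAL, TOP, KmerVocabulary,
                               build_vocabulary, canonical)
from enfragility.scoring import EnhancerScorer


def make_vocab(k, top_weights=None, neutral=(), track="pooled"):
    """Hand-built vocabulary: dict of kmer-string -> weight for top class."""
    top_weights = top_weights or {}
    classes, weights = {}, {}

    def code(kmer):
        c = 0
        for ch in canonical(kmer):
            c = c * 4 + "ACGT".index(ch)
        return c

    for kmer, w in top_weights.items():
        classes[code(kmer)] = TOP
        weights[code(kmer)] = w
    for kmer in neutral:
        classes[code(kmer)] = NEUTRAL
    return KmerVocabulary(k=k, track=track, enh_total=1, ctrl_total=1,
                          enh_counts={}, ctrl_counts={}, p_raw={},
                          classes=classes, weights=weights)


class TestCandidates:
    def test_single_top_kmer_yields_its_disrupting_substitutions(self):
        seq = "T" * 10 + "ACGTTGCA" + "T" * 10
        vocab = make_vocab(8, {"ACGTTGCA": 2.0})
        cands = candidate_dems(seq, vocab)
        assert cands  # the planted word can be broken
        for v in cands:
            assert 10 <= v.pos < 18

    def test_all_background_sequence_has_no_candidates(self):
        seq = "ACGT" * 10
        vocab = make_vocab(8)   # everything background
        assert candidate_dems(seq, vocab) == []

    def test_matches_window_by_window_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        counts = {}
        # promote a handful of observed 8-mers to top, one to neutral
        words = [seq[i:i + 8] for i in range(0, 40, 7)]
        vocab = make_vocab(8, {w: 1.0 for w in words[:4]},
                           neutral=[words[4]])
        cands = set((v.pos, v.alt) for v in candidate_dems(seq, vocab))
        oracle = set()
        for pos in range(len(seq)):
            for alt in "ACGT":
                if alt == seq[pos]:
                    continue
                for i in range(max(0, pos - 7), min(len(seq) - 7, pos + 1)):
                    ref_w = seq[i:i + 8]
                    alt_w = ref_w[:pos - i] + alt + ref_w[pos - i + 1:]
                    if (vocab.class_of(ref_w) == TOP
                            and vocab.class_of(alt_w) == BACKGROUND):
                        oracle.add((pos, alt))
                        break
        assert cands == oracle

    def test_candidate_count_bounded(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50))
        vocab = build_vocabulary([seq], [seq[::-1]], 8)
        assert len(candidate_dems(seq, vocab)) <= 3 * len(seq)


class TestDeltaFeature:
    def test_no_top_window_gives_zero(self):
        vocab = make_vocab(4)
        v = VariantRecord("chr1", 5, "A", "C")
        assert delta_feature("AAAAAAAAAA", v, vocab) == 0.0

    def test_top_to_background_drop_equals_weight(self):
        seq = "TTTTACGGTTTT"
        vocab = make_vocab(4, {"ACGG": 1.5})
        # changing the G at position 6 breaks ACGG
        v = VariantRecord("chr1", 6, "G", "A")
        assert delta_feature(seq, v, vocab) == pytest.approx(1.5)

    def test_fast_path_matches_reference(self, rng):
        seq = "".join(rng.choice(list("ACGTa"), p=[.24, .24, .24, .24, .04],
                                 size=120))
        words = {}
        for i in range(0, 100, 5):
            w = seq[i:i + 6].upper()
            if all(c in "ACGT" for c in w) and len(w) == 6:
                words[w] = float(rng.uniform(0.5, 3))
        vocab = make_vocab(6, words)
        vocabs = {(6, "t"): vocab}
        schema = FeatureSchema(tracks=("t",), k_sizes=(6,), flank_window=30)
        scorer = EnhancerScorer(seq, vocabs, schema)
        for _ in range(50):
            pos = int(rng.integers(0, len(seq)))
            if seq[pos].islower():
                continue
            alt = rng.choice([b for b in "ACGT" if b != seq[pos].upper()])
            v = VariantRecord("chr1", pos, seq[pos].upper(), str(alt))
            fv = scorer.features(v)
            assert fv[0] == pytest.approx(
                delta_feature(seq, v, vocab), abs=1e-12)
            assert fv[1] == pytest.approx(
                s_feature(seq, v, vocab, 30), abs=1e-9)


class TestSFeature:
    def test_empty_flank_gives_zero(self):
        vocab = make_vocab(4)
        v = VariantRecord("chr1", 10, "A", "C")
        assert s_feature("A" * 21, v, vocab) == 0.0

    def test_two_non_covering_windows_sum(self):
        #      0123456789012345678901
        seq = "ACGGTTTTTTATTTTTTTTGCAT"
        vocab = make_vocab(4, {"ACGG": 1.0, "GCAT": 2.0})
        v = VariantRecord("chr1", 10, "A", "C")
        assert s_feature(seq, v, vocab, flank_window=100) == pytest.approx(3.0)

    def test_window_covering_variant_excluded(self):
        seq = "TTTTACGGTTTT"
        vocab = make_vocab(4, {"ACGG": 1.5})
        v = VariantRecord("chr1", 6, "G", "A")   # inside the only top window
        assert s_feature(seq, v, vocab, flank_window=100) == 0.0


class TestExtractFeatures:
    @pytest.mark.parametrize("n_tracks,expected", [(1, 10), (8, 80)])
    def test_feature_count(self, n_tracks, expected, rng):
        tracks = tuple(f"t{i}" for i in range(n_tracks))
        schema = FeatureSchema(tracks=tracks)
        assert schema.n_features == expected
        seq = "".join(rng.choice(list("ACGT"), size=40))
        vocabs = {(k, t): make_vocab(k, track=t)
                  for k in schema.k_sizes for t in tracks}
        v = VariantRecord("chr1", 20, seq[20], "A" if seq[20] != "A" else "C")
        fv = extract_features(v, seq, vocabs, schema)
        assert fv.shape == (expected,)

    def test_missing_vocabulary_named(self):
        schema = FeatureSchema(tracks=("t",), k_sizes=(4,))
        v = VariantRecord("chr1", 2, "G", "A")
        with pytest.raises(KeyError, match="k=4.*'t'"):
            extract_features(v, "AAGAA", {}, schema)


class TestDecomposition:
    def test_zero_weights_score_half(self):
        schema = FeatureSchema(tracks=("t",))
        w = WeightSet(schema, np.zeros(10), 0.0)
        d = score_and_decompose(np.random.default_rng(0).normal(size=10), w)
        assert d.margin == 0.0
        assert d.score == 0.5

    def test_delta_only_weights(self):
        schema = FeatureSchema(tracks=("t",))
        vec = schema.delta_mask.astype(float)
        w = WeightSet(schema, vec, 0.0)
        fv = np.arange(10, dtype=float)
        d = score_and_decompose(fv, w)
        assert d.ws_s == 0.0
        assert d.ws_delta == pytest.approx(fv[schema.delta_mask].sum())

    def test_additivity_against_dot_product_oracle(self, rng):
        """WS(Delta) + WS(S) + b equals the direct dot product to 1e-9."""
        schema = FeatureSchema(tracks=("a", "b"))
        n = schema.n_features
        for _ in range(200):
            wvec = rng.normal(size=n)
            b = float(rng.normal())
            fv = rng.normal(size=n)
            w = WeightSet(schema, wvec, b)
            d = score_and_decompose(fv, w)
            assert abs(d.margin - (fv @ wvec + b)) < 1e-9
            assert abs(d.margin - (d.ws_delta + d.ws_s + d.intercept)) < 1e-9
            assert d.score == pytest.approx(expit(fv @ wvec + b))

    def test_layout_mismatch_rejected(self):
        schema = FeatureSchema(tracks=("t",))
        w = WeightSet(schema, np.zeros(10), 0.0)
        with pytest.raises(ValueError):
            score_and_decompose(np.zeros(8), w)

    def test_weightset_tsv_round_trip(self, tmp_path, rng):
        schema = FeatureSchema(tracks=("H3K27ac", "DNase"))
        w = WeightSet(schema, rng.normal(size=schema.n_features),
                      float(rng.normal()))
        w.save_tsv(tmp_path / "w.tsv")
        back = WeightSet.load_tsv(tmp_path / "w.tsv")
        assert np.array_equal(back.weights, w.weights)
        assert back.intercept == w.intercept
        assert back.schema.tracks == schema.tracks


class TestFitWeights:
    def _toy(self, rng, n=200, sep=3.0):
        schema = FeatureSchema(tracks=("t",), k_sizes=(4,))
        X = rng.normal(size=(n, schema.n_features))
        y = (rng.random(n) < 0.5).astype(int)
        X[y == 1, 0] += sep
        return schema, X, y

    def test_separable_toy_perfect_training_accuracy(self, rng):
        schema, X, y = self._toy(rng, sep=30.0)
        w, rep = fit_weights(X, y, schema, seed=0)
        scores = X @ w.weights + w.intercept
        assert (((scores > 0).astype(int)) == y).mean() == 1.0

    def test_permuted_labels_have_chance_auc(self, rng):
        schema, X, y = self._toy(rng, n=500, sep=3.0)
        y_perm = rng.permutation(y)
        _, rep = fit_weights(X, y_perm, schema, seed=0)
        assert 0.4 <= rep["oof_auc"] <= 0.6

    def test_deterministic_under_seed(self, rng):
        schema, X, y = self._toy(rng)
        w1, _ = fit_weights(X, y, schema, seed=5)
        w2, _ = fit_weights(X, y, schema, seed=5)
        assert np.array_equal(w1.weights, w2.weights)
        assert w1.intercept == w2.intercept

    def test_single_class_rejected(self, rng):
        schema, X, y = self._toy(rng)
        with pytest.raises(ValueError):
            fit_weights(X, np.zeros_like(y), schema, seed=0)


class TestFprCalibration:
    def test_order_statistic_example(self):
        """Scores 1..100 at FPR 0.01: exactly one negative at/above."""
        scores = np.arange(1, 101, dtype=float)
        t = calibrate_fpr_threshold(scores, 0.01)
        assert np.count_nonzero(scores >= t) == 1

    def test_fpr_one_returns_minimum(self):
        assert calibrate_fpr_threshold([3.0, 1.0, 2.0], 1.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_fpr_threshold([], 0.01)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="calibration is coarse"):
            calibrate_fpr_threshold([0.1, 0.2, 0.3], 0.01)

    def test_held_out_rate_close_to_design_bound(self):
        """Threshold from 10k negatives keeps fresh-negative FPR <= 0.013."""
        rng = np.random.default_rng(77)
        train = rng.normal(size=10_000)
        t = calibrate_fpr_threshold(train, 0.01)
        held_out = rng.normal(size=10_000)
        assert np.mean(held_out >= t) <= 0.013


class TestCallDemps:
    def test_qualifying_position_is_demp(self, rng):
        seq = "T" * 20 + "ACGTTGCA" + "T" * 20
        vocab = make_vocab(8, {"ACGTTGCA": 2.0})
        schema = FeatureSchema(tracks=("t",), k_sizes=(8,))
        vocabs = {(8, "t"): vocab}
        scorer = EnhancerScorer(seq, vocabs, schema)
        # weights that reward Delta strongly
        vec = schema.delta_mask.astype(float) * 5.0
        w = WeightSet(schema, vec, -1.0)
        demps, calls = call_demps(scorer, vocab, w, threshold=0.6)
        assert demps   # disrupting the planted word scores above threshold
        assert all(20 <= p < 28 for p in demps)
        assert len(demps) <= len(seq)
        for c in calls:
            assert c.is_dem == (c.decomposition.score >= 0.6)

    def test_unreachable_threshold_gives_no_demps(self, rng):
        seq = "T" * 20 + "ACGTTGCA" + "T" * 20
        vocab = make_vocab(8, {"ACGTTGCA": 2.0})
        schema = FeatureSchema(tracks=("t",), k_sizes=(8,))
        scorer = EnhancerScorer(seq, {(8, "t"): vocab}, schema)
        w = WeightSet(schema, np.zeros(2), 0.0)
        demps, calls = call_demps(scorer, vocab, w, threshold=0.9)
        assert demps == []
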