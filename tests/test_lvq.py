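import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumorpipe import lvq
from tumorpipe.errors import (
    ConfigurationError,
    SchemaError,
    UndefinedSimilarityError,
)
from tumorpipe.synthetic import make_cluster_dataset

unit_vectors = st.lists(
    st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=12
)


class TestMaxMinSimilarity:
    @pytest.mark.parametrize(
        "x,w,expected",
        [
            ([0.3, 0.7, 1.0], [0.3, 0.7, 1.0], 1.0),
            ([1.0, 0.0], [0.0, 1.0], 0.0),
            ([0.5, 0.5], [1.0, 1.0], 0.5),
        ],
    )
    def test_hand_values(self, x, w, expected):
        assert lvq.maxmin_similarity(np.array(x), np.array(w)) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(unit_vectors, st.randoms(use_true_random=False))
    def test_axioms(self, xs, rnd):
        x = np.array(xs)
        w = np.array([rnd.random() for _ in xs])
        if x.max() == 0 and w.max() == 0:
            return
        s = lvq.maxmin_similarity(x, w)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(lvq.maxmin_similarity(w, x))  # symmetry
        if x.max() > 0:
            assert lvq.maxmin_similarity(x, x) == 1.0
        # identity of indiscernibles: S = 1 only at equality
        if not np.allclose(x, w) and s == 1.0:
            raise AssertionError("similarity 1 for unequal vectors")

    def test_error_cases(self):
        with pytest.raises(UndefinedSimilarityError):
            lvq.maxmin_similarity(np.zeros(3), np.zeros(3))
        with pytest.raises(SchemaError):
            lvq.maxmin_similarity(np.zeros(3), np.zeros(4))


def toy_codebook():
    return lvq.Codebook(
        classes=("A", "B"),
        clusters={"A": np.array([[0.9, 0.9]]), "B": np.array([[0.1, 0.1]])},
        d=2,
    )


class TestClassify:
    def test_exact_reference_match(self):
        cb = toy_codebook()
        res = lvq.classify(np.array([0.1, 0.1]), cb)
        assert res.label == "B" and res.similarity == 1.0

    def test_hand_computed_similarities(self):
        cb = toy_codebook()
        res = lvq.classify(np.array([0.8, 0.8]), cb)
        assert res.label == "A"
        assert res.per_class["A"] == pytest.approx(1.6 / 1.8)
        assert res.per_class["B"] == pytest.approx(0.2 / 1.6)

    def test_tie_goes_to_first_class(self):
        cb = lvq.Codebook(
            classes=("first", "second"),
            clusters={
                "first": np.array([[0.4, 0.4]]),
                "second": np.array([[0.4, 0.4]]),
            },
            d=2,
        )
        assert lvq.classify(np.array([0.2, 0.6]), cb).label == "first"

    def test_empty_codebook_rejected(self):
        with pytest.raises(ConfigurationError):
            lvq.Codebook(classes=(), clusters={}, d=2)


class TestTrain:
    def setup_method(self):
        self.X, self.y = make_cluster_dataset(3, 6, 100, separation=5.0, seed=77)

    def test_zero_epochs_returns_initialization(self):
        cfg = lvq.TrainConfig(seed=1, epochs=0)
        cb = lvq.train(self.X, self.y, cfg)
        # every reference is one of the training vectors, stratified by class
        for cls in cb.classes:
            class_rows = self.X[self.y == cls]
            for ref in cb.clusters[cls]:
                assert any(np.allclose(ref, row) for row in class_rows)

    def test_single_class_dataset(self):
        X = np.random.default_rng(0).uniform(0.2, 0.8, (20, 4))
        y = np.repeat("only", 20)
        cb = lvq.train(X, y, lvq.TrainConfig(seed=3, epochs=5))
        assert lvq.classify(np.full(4, 0.5), cb).label == "only"

    def test_training_is_deterministic(self):
        cfg = lvq.TrainConfig(seed=42, epochs=10)
        cb1 = lvq.train(self.X, self.y, cfg)
        cb2 = lvq.train(self.X, self.y, cfg)
        for cls in cb1.classes:
            assert np.array_equal(cb1.clusters[cls], cb2.clusters[cls])

    def test_separated_clusters_recovered(self):
        n = self.X.shape[0]
        rng = np.random.default_rng(5)
        perm = rng.permutation(n)
        cut = int(0.7 * n)
        tr, te = perm[:cut], perm[cut:]
        cb = lvq.train(self.X[tr], self.y[tr], lvq.TrainConfig(seed=11))
        preds = [lvq.classify(x, cb).label for x in self.X[te]]
        acc = np.mean(np.asarray(preds) == self.y[te])
        assert acc >= 0.95

    def test_loss_history_recorded(self):
        history = []
        lvq.train(self.X, self.y, lvq.TrainConfig(seed=2, epochs=5), history=history)
        assert len(history) == 5
        assert all(0.0 <= loss <= 1.0 for loss in history)


class TestQuantization:
    def test_one_bit_reconstruction_points(self):
        w = np.linspace(0, 1, 33)
        q = lvq.quantize_weights(w, 1)
        assert set(np.round(q, 6)) <= {0.25, 0.75}

    def test_sixteen_bit_error_bound(self):
        w = np.random.default_rng(0).uniform(0, 1, 1000)
        q = lvq.quantize_weights(w, 16)
        assert np.max(np.abs(q - w)) <= 2**-16

    def test_reconstruction_level_is_fixed_point(self):
        levels = (np.arange(8) + 0.5) / 8
        assert np.array_equal(lvq.quantize_weights(levels, 3), levels)

    def test_noise_power_monotone_in_beta(self):
        w = np.random.default_rng(1).uniform(0, 1, 20000)
        powers = [np.mean((lvq.quantize_weights(w, b) - w) ** 2) for b in range(1, 12)]
        assert all(p2 <= p1 for p1, p2 in zip(powers, powers[1:]))

    def test_codebook_quantization_report(self):
        cb = toy_codebook()
        qcb, report = lvq.quantize_codebook(cb, lvq.QuantizationSpec(beta=8))
        assert qcb.beta == 8
        assert report.noise_power[0] >= 0
        refs, _ = qcb.stacked()
        assert refs.min() >= 0 and refs.max() <= 1

    def test_invalid_beta(self):
        with pytest.raises(ConfigurationError):
            lvq.QuantizationSpec(beta=0)


class TestSqnr:
    def test_constant_offset_closed_form(self):
        w = np.array([1.0, -1.0, 1.0, -1.0])  # unit mean square
        q = w + 0.1
        assert lvq.measure_sqnr(w, q) == pytest.approx(10 * np.log10(1 / 0.01))

    def test_scale_invariance(self):
        w = np.random.default_rng(2).uniform(0.1, 1, 100)
        q = lvq.quantize_weights(w, 4)
        assert lvq.measure_sqnr(2 * w, 2 * q) == pytest.approx(lvq.measure_sqnr(w, q))

    def test_zero_noise_reports_infinity(self):
        w = np.array([0.3, 0.6])
        assert lvq.measure_sqnr(w, w.copy()) == np.inf

    def test_six_db_per_bit_law(self):
        w = np.random.default_rng(3).uniform(0, 1, 100_000)
        report = lvq.sqnr_vs_beta(w, range(2, 11))
        assert 5.5 <= report.kappa <= 6.5
        # 4 extra bits ~ 24 dB
        s4 = lvq.measure_sqnr(w, lvq.quantize_weights(w, 4))
        s8 = lvq.measure_sqnr(w, lvq.quantize_weights(w, 8))
        assert s8 - s4 == pytest.approx(24.0, abs=1.5)

    def test_label_stability_under_8bit_quantization(self):
        X, y = make_cluster_dataset(3, 6, 60, separation=5.0, seed=21)
        cb = lvq.train(X, y, lvq.TrainConfig(seed=9, epochs=20))
        qcb, _ = lvq.quantize_codebook(cb, lvq.QuantizationSpec(beta=8))
        keep = np.mean(
            [lvq.classify(x, cb).label == lvq.classify(x, qcb).label for x in X]
        )
        assert keep >= 0.95
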