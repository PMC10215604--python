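"""Feature-extraction model: architecture audit, training, cache population."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from galslo.cache import FeatureCache
from galslo.fem import (TrainConfig, build_fem, extract_features,
                        inverse_frequency_weights, populate_cache,
                        pre_gap_length, train_fem)
from galslo.preprocess import EcgRecord


def _burst_dataset(n_per_class=150, seed=0):
    """Two classes of 1 s single-lead segments differing by a 25 Hz burst."""
    rng = np.random.default_rng(seed)
    t = np.arange(1000) / 1000
    burst = 3.0 * np.sin(2 * np.pi * 25 * t) * np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)
    XA = rng.normal(0, 1, (n_per_class, 1000))
    XB = rng.normal(0, 1, (n_per_class, 1000)) + burst
    X = np.vstack([XA, XB])
    y = np.array(["quiet"] * n_per_class + ["burst"] * n_per_class, dtype=object)
    return X, y


REDUCED = 1 / 8  # desk-scale width factor; identical topology and code paths


class TestArchitecture:
    @pytest.mark.parametrize("T_L", range(1, 10))
    def test_audit_every_length(self, T_L):
        spec = build_fem(T_L, 5)
        assert spec.input_len == 1000 * T_L
        assert spec.n_conv_layers == 13
        widths = spec.stage_widths
        assert all(a <= b for a, b in zip(widths, widths[1:]))
        assert widths[0] == 64 and widths[-1] == 512
        assert spec.feature_width == 512
        assert pre_gap_length(spec.input_len) == max(1, spec.input_len // 8192)

    def test_head_configuration(self):
        assert build_fem(3, 5).head_activation == "softmax"
        two = build_fem(1, 2)
        assert two.head_activation == "sigmoid" and two.n_classes == 2

    def test_reduced_widths(self):
        spec = build_fem(1, 2, width_scale=REDUCED)
        assert spec.stage_widths == (8, 8, 16, 32, 64, 64)
        assert spec.feature_width == 64

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_fem(0, 5)
        with pytest.raises(ValueError):
            build_fem(3, 3)


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self):
        X, y = _burst_dataset()
        spec = build_fem(1, 2, width_scale=REDUCED)
        model = train_fem(spec, X, y, TrainConfig(epochs=10, seed=0))
        return model, X, y

    def test_learns_planted_burst(self, trained):
        model, X, y = trained
        assert (model.predict(X) == y).mean() >= 0.95
        assert model.loss_history[-1] < model.loss_history[0]

    def test_shuffled_labels_give_chance_accuracy(self):
        X, y = _burst_dataset(n_per_class=40, seed=1)
        rng = np.random.default_rng(2)
        y_shuf = y.copy()
        rng.shuffle(y_shuf)
        spec = build_fem(1, 2, width_scale=REDUCED)
        model = train_fem(spec, X[:60], y_shuf[:60], TrainConfig(epochs=4, seed=0))
        held_acc = (model.predict(X[60:]) == y_shuf[60:]).mean()
        assert abs(held_acc - 0.5) <= 0.15

    def test_seeded_determinism(self):
        X, y = _burst_dataset(n_per_class=20, seed=3)
        spec = build_fem(1, 2, width_scale=REDUCED)
        cfg = TrainConfig(epochs=2, seed=7)
        m1 = train_fem(spec, X, y, cfg)
        m2 = train_fem(spec, X, y, cfg)
        assert abs(m1.loss_history[-1] - m2.loss_history[-1]) < 1e-6

    def test_error_cases(self):
        X, y = _burst_dataset(n_per_class=10)
        spec = build_fem(1, 2, width_scale=REDUCED)
        with pytest.raises(ValueError, match="two classes"):
            train_fem(spec, X[:10], y[:10], TrainConfig(epochs=1))
        with pytest.raises(ValueError, match="segments"):
            train_fem(spec, X[:, :500], y, TrainConfig(epochs=1))

    def test_feature_extraction_contracts(self, trained):
        model, X, y = trained
        feats = extract_features(model, X[:7])
        assert feats.shape == (7, 64)
        twice = extract_features(model, np.vstack([X[:1], X[:1]]))
        assert np.array_equal(twice[0], twice[1])
        # planted structure is linearly separable in feature space
        F = extract_features(model, X)
        clf = LogisticRegression(max_iter=1000).fit(F, y.astype(str))
        assert clf.score(F, y.astype(str)) >= 0.9


def test_inverse_frequency_weights_normalised():
    w = inverse_frequency_weights(np.array([0, 0, 0, 1]), 2)
    assert w.mean() == pytest.approx(1.0)
    assert w[1] > w[0]
    with pytest.raises(ValueError):
        inverse_frequency_weights(np.array([0, 0]), 2)


class TestPopulateCache:
    @staticmethod
    def _records(n_per_class=4, seconds=6.0, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for label, shift in (("HC", 0.0), ("MI", 1.5)):
            for p in range(n_per_class):
                sig = rng.normal(0, 1, (12, int(seconds * 1000)))
                sig[1] += shift  # lead II offset; removed by z-score but harmless
                recs.append(EcgRecord(patient_id=f"{label}{p}",
                                      record_id=f"{label}{p}r", signals=sig,
                                      fs=1000.0, label=label))
        return recs

    def test_entry_counting_and_roundtrip(self, tmp_path):
        recs = self._records()
        cfg = TrainConfig(epochs=1, seed=0)
        cache = populate_cache(recs, "mi", lengths=(1, 2), leads=(1, 2), cfg=cfg,
                               width_scale=1 / 16, split_fraction=0.5,
                               max_segments_per_record=3)
        assert len(cache) == 8  # 2 leads x 2 lengths x 2 splits
        path = tmp_path / "cache.h5"
        cache.save(path)
        loaded = FeatureCache.load(path)
        for key in cache.keys():
            a, _, _ = cache.get(*key)
            b, _, _ = loaded.get(*key)
            assert np.array_equal(a, b)

    def test_patient_overlap_rejected(self):
        recs = self._records()
        with pytest.raises(ValueError, match="both splits"):
            populate_cache(recs, "mi", (1,), (1,), TrainConfig(epochs=1),
                           width_scale=1 / 16, split=(recs, recs))

    def test_cache_alignment_invariants(self):
        recs = self._records(seed=1)
        cache = populate_cache(recs, "mi", (1,), (1, 2), TrainConfig(epochs=1),
                               width_scale=1 / 16, split_fraction=0.5,
                               max_segments_per_record=2)
        X, labels, patients = cache.block(1, (1, 2), "train")
        assert X.shape[1] == 2 and len(labels) == len(patients) == X.shape[0]
        assert cache.patient_ids("train").isdisjoint(cache.patient_ids("test"))
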