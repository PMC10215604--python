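"""Lead attention module and classification heads."""

import numpy as np
import pytest

from galslo import nn
from galslo.lam import (FeatureBlock, LamMlpClassifier, LamNetwork, LamSpec,
                        MlpClassifier, MlpNetwork, apply_lam, lead_weights)

from conftest import numerical_gradient


def _gaussian_block(n=120, n_leads=3, width=24, sep=3.0, noise_leads=(),
                    seed=0, n_test=0):
    """Two-class blocks with informative leads separated by ``sep`` sd.

    Train and test samples share the same class-separation directions.
    Returns (X, y) or (X, y, X_test, y_test) when ``n_test`` is given.
    """
    rng = np.random.default_rng(seed)
    total = n + n_test
    y = np.array((["A", "B"] * ((total + 1) // 2))[:total], dtype=object)
    X = rng.normal(size=(total, n_leads, width))
    shift = np.where(y == "B", sep / 2, -sep / 2)
    for lead in range(n_leads):
        if lead in noise_leads:
            continue
        direction = rng.normal(size=width)
        direction /= np.linalg.norm(direction)
        X[:, lead, :] += shift[:, None] * direction[None, :]
    if not n_test:
        return X, y
    return X[:n], y[:n], X[n:], y[n:]


class TestLeadWeights:
    def test_softmax_normalisation(self):
        rng = np.random.default_rng(0)
        net = LamNetwork(LamSpec(n_leads=4, width=16, n_classes=2), rng)
        X = rng.normal(size=(9, 4, 16))
        w = net.lead_weights(X)
        assert w.shape == (9, 4)
        assert np.all(w >= 0)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_single_lead_weight_is_one(self):
        rng = np.random.default_rng(1)
        net = LamNetwork(LamSpec(n_leads=1, width=8, n_classes=2), rng)
        X = rng.normal(size=(5, 1, 8))
        assert np.allclose(net.lead_weights(X), 1.0)
        block = FeatureBlock(X, (2,))
        assert np.allclose(apply_lam(block, net), 2.0 * X)

    def test_zero_block_maps_to_zero(self):
        rng = np.random.default_rng(2)
        net = LamNetwork(LamSpec(n_leads=3, width=8, n_classes=2), rng)
        block = FeatureBlock(np.zeros((4, 3, 8)), (1, 2, 3))
        assert np.allclose(apply_lam(block, net), 0.0)

    def test_uniform_weights_scale_rows_by_1_25(self):
        rng = np.random.default_rng(3)
        net = LamNetwork(LamSpec(n_leads=4, width=8, n_classes=2), rng)
        # zeroed FC makes the softmax uniform: w_i = 0.25
        net.fc_w.w.value[...] = 0.0
        net.fc_w.b.value[...] = 0.0
        X = rng.normal(size=(6, 4, 8))
        out = apply_lam(FeatureBlock(X, (1, 2, 3, 4)), net)
        assert np.allclose(out, 1.25 * X, atol=1e-12)

    def test_lead_permutation_symmetry(self):
        rng = np.random.default_rng(4)
        spec = LamSpec(n_leads=3, width=10, n_classes=2, conv_filters=4)
        net = LamNetwork(spec, rng)
        X = rng.normal(size=(5, 3, 10))
        w = net.lead_weights(X)
        perm = [2, 0, 1]
        # permute lead rows and the FC blocks/rows correspondingly
        net2 = LamNetwork(spec, np.random.default_rng(4))
        W = net.fc_w.w.value.reshape(3, 3, spec.conv_filters)
        net2.fc_w.w.value[...] = W[perm][:, perm].reshape(3, -1)
        net2.fc_w.b.value[...] = net.fc_w.b.value[perm]
        net2.conv.w.value[...] = net.conv.w.value
        net2.conv.b.value[...] = net.conv.b.value
        w2 = net2.lead_weights(X[:, perm, :])
        assert np.allclose(w2, w[:, perm], atol=1e-10)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        net = LamNetwork(LamSpec(n_leads=3, width=8, n_classes=2), rng)
        with pytest.raises(ValueError, match="expected"):
            net.lead_weights(np.zeros((2, 4, 8)))


def test_lam_backward_matches_numerical_gradient():
    rng = np.random.default_rng(6)
    net = LamNetwork(LamSpec(n_leads=3, width=10, n_classes=2,
                             conv_filters=4, hidden=(8,)), rng)
    X = rng.normal(size=(5, 3, 10))
    y = np.array([0, 1, 0, 1, 1])

    def loss():
        l, _ = nn.softmax_cross_entropy(net.forward(X), y)
        return l

    for p in net.all_parameters():
        p.zero_grad()
    _, d = nn.softmax_cross_entropy(net.forward(X), y)
    dX = net.backward(d)
    for p in net.all_parameters():
        ng = numerical_gradient(loss, p.value)
        assert np.all(np.abs(p.grad - ng) <= 5e-4 + 1e-3 * np.abs(ng))
    ngX = numerical_gradient(loss, X)
    assert np.all(np.abs(dX - ngX) <= 5e-4 + 1e-3 * np.abs(ngX))


def test_zeroed_attention_reduces_to_pure_mlp():
    rng = np.random.default_rng(7)
    spec = LamSpec(n_leads=2, width=12, n_classes=2, hidden=(16,))
    lam = LamNetwork(spec, rng)
    mlp = MlpNetwork(spec, np.random.default_rng(99))
    # share MLP parameters, then force the attention weights to zero
    for p_lam, p_mlp in zip(lam.mlp.all_parameters(), mlp.all_parameters()):
        p_mlp.value[...] = p_lam.value
    lam.force_zero_weights = True
    X = rng.normal(size=(6, 2, 12))
    assert np.allclose(lam.forward(X), mlp.forward(X), atol=1e-12)


class TestClassifiers:
    def test_probabilities_sum_to_one_and_untrained_errors(self):
        X, y = _gaussian_block()
        clf = LamMlpClassifier(n_leads=3, width=24, n_classes=2,
                               hidden=(16,), epochs=5, seed=0)
        with pytest.raises(RuntimeError, match="not been trained"):
            clf.predict(X)
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_separable_features_classified_accurately(self):
        X, y, Xt, yt = _gaussian_block(n=160, n_test=80, sep=4.0, seed=1)
        clf = LamMlpClassifier(n_leads=3, width=24, n_classes=2,
                               hidden=(32,), epochs=25, seed=0)
        clf.fit(X, y)
        assert (clf.predict(Xt) == yt).mean() >= 0.95

    def test_fixed_seed_is_reproducible(self):
        X, y = _gaussian_block(n=60, seed=3)
        preds = []
        for _ in range(2):
            clf = MlpClassifier(n_leads=3, width=24, n_classes=2,
                                hidden=(16,), epochs=8, seed=5)
            clf.fit(X, y)
            preds.append(clf.predict(X))
        assert np.array_equal(preds[0], preds[1])

    def test_lam_at_least_matches_mlp_with_noise_lead(self):
        """With one pure-noise lead the attention head should not lose to
        the flat MLP (median over 5 seeds)."""
        from galslo.metrics import confusion, macro_report
        diffs = []
        for seed in range(5):
            X, y, Xt, yt = _gaussian_block(n=140, n_test=100, n_leads=3,
                                           sep=1.5, noise_leads=(2,), seed=seed)
            scores = {}
            for name, cls in (("lam", LamMlpClassifier), ("mlp", MlpClassifier)):
                clf = cls(n_leads=3, width=24, n_classes=2, hidden=(16,),
                          epochs=20, seed=seed)
                clf.fit(X, y)
                rep = macro_report(confusion(yt, clf.predict(Xt), ("A", "B")))
                scores[name] = rep.macro["F1"]
            diffs.append(scores["lam"] - scores["mlp"])
        assert np.median(diffs) >= 0.0

    def test_wrong_class_count_rejected(self):
        X, y = _gaussian_block(n=30)
        clf = LamMlpClassifier(n_leads=3, width=24, n_classes=5, epochs=1)
        with pytest.raises(ValueError, match="classes"):
            clf.fit(X, y)


def test_lead_weights_helper_and_block_validation():
    rng = np.random.default_rng(8)
    net = LamNetwork(LamSpec(n_leads=2, width=8, n_classes=2), rng)
    block = FeatureBlock(rng.normal(size=(3, 2, 8)), (2, 4))
    w = lead_weights(block, net)
    assert w.shape == (3, 2)
    with pytest.raises(ValueError):
        FeatureBlock(rng.normal(size=(3, 2, 8)), (2,))
    with pytest.raises(ValueError):
        FeatureBlock(rng.normal(size=(3, 8)), (2,))
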