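"""Lead-attention classification heads.

A classification block stacks the selected leads' GAP features as rows of an
``(n_leads, width)`` matrix per sample. The lead attention module (LAM)
produces one softmax weight per selected lead — a shared 1-D convolution
along the feature axis, global averaging, and a fully connected layer with
exactly ``n_leads`` units — and rescales each lead residually:

    out_i = f_i * w_i + f_i ,   w = softmax(FC(GAP(conv(f))))

so the weights are non-negative and sum to one on every forward pass. The
weighted (or, for the pure-MLP baseline, raw flattened) features feed a small
fully connected classifier. Forcing the weights to zero reduces the LAM
architecture exactly to the pure-MLP baseline, which is how the ablation is
controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "FeatureBlock",
    "LamSpec",
    "LamNetwork",
    "MlpNetwork",
    "HeadClassifier",
    "LamMlpClassifier",
    "MlpClassifier",
    "lead_weights",
    "apply_lam",
]


@dataclass
class FeatureBlock:
    """Per-sample stacked lead features: X has shape (n, n_leads, width)."""

    features: np.ndarray
    selected_leads: tuple[int, ...]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 3:
            raise ValueError("features must be (n, n_leads, width)")
        if self.features.shape[1] != len(self.selected_leads):
            raise ValueError("row count must match selected_leads")
        if len(self.selected_leads) < 1:
            raise ValueError("at least one lead required")


@dataclass(frozen=True)
class LamSpec:
    """LAM + MLP head hyperparameters."""

    n_leads: int
    width: int = 512
    n_classes: int = 2
    conv_filters: int = 16
    kernel: int = 3
    hidden: tuple[int, ...] = (128, 64)

    def __post_init__(self):
        if self.n_leads < 1:
            raise ValueError("n_leads must be >= 1")


class _Mlp(nn.Layer):
    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int,
                 rng: np.random.Generator):
        layers: list[nn.Layer] = []
        prev = n_in
        for h in hidden:
            layers += [nn.Dense(prev, h, rng=rng), nn.ReLU()]
            prev = h
        layers.append(nn.Dense(prev, n_out, rng=rng))
        self.seq = nn.Sequential(*layers)

    def children(self):
        return [self.seq]

    def forward(self, x):
        return self.seq.forward(x)

    def backward(self, grad):
        return self.seq.backward(grad)


class LamNetwork(nn.Layer):
    """Lead attention + MLP classifier over an (n, n_leads, width) block."""

    def __init__(self, spec: LamSpec, rng: np.random.Generator):
        self.spec = spec
        self.conv = nn.Conv1d(1, spec.conv_filters, spec.kernel, stride=1, rng=rng)
        self.gap = nn.GlobalAvgPool1d()
        self.fc_w = nn.Dense(spec.n_leads * spec.conv_filters, spec.n_leads, rng=rng)
        self.mlp = _Mlp(spec.n_leads * spec.width, spec.hidden, spec.n_classes, rng)
        self.force_zero_weights = False      # ablation switch: reduces to pure MLP
        self._cache = None

    def children(self):
        return [self.conv, self.gap, self.fc_w, self.mlp]

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != self.spec.n_leads or x.shape[2] != self.spec.width:
            raise ValueError(
                f"expected (n, {self.spec.n_leads}, {self.spec.width}) block, "
                f"got {x.shape}")
        return x

    def lead_weights(self, x: np.ndarray) -> np.ndarray:
        """Softmax lead weights, shape (n, n_leads); rows sum to 1."""
        x = self._check(x)
        n, L, F = x.shape
        a = self.conv.forward(x.reshape(n * L, 1, F))
        summary = self.gap.forward(a).reshape(n, L * self.spec.conv_filters)
        return nn.softmax(self.fc_w.forward(summary))

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._check(x)
        n, L, F = x.shape
        a = self.conv.forward(x.reshape(n * L, 1, F))
        summary = self.gap.forward(a).reshape(n, L * self.spec.conv_filters)
        logits_w = self.fc_w.forward(summary)
        w = np.zeros((n, L)) if self.force_zero_weights else nn.softmax(logits_w)
        out = x * (1.0 + w[:, :, None])
        self._cache = (x, w)
        return self.mlp.forward(out.reshape(n, L * F))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, w = self._cache
        n, L, F = x.shape
        d_out = self.mlp.backward(grad).reshape(n, L, F)
        dx = d_out * (1.0 + w[:, :, None])
        if not self.force_zero_weights:
            dw = (d_out * x).sum(axis=2)                     # (n, L)
            # softmax jacobian-vector product
            d_logits_w = w * (dw - (dw * w).sum(axis=1, keepdims=True))
            d_summary = self.fc_w.backward(d_logits_w)
            d_gap = d_summary.reshape(n * L, self.spec.conv_filters)
            dx += self.conv.backward(self.gap.backward(d_gap)).reshape(n, L, F)
        return dx


class MlpNetwork(nn.Layer):
    """Pure-MLP baseline: flatten the block and classify."""

    def __init__(self, spec: LamSpec, rng: np.random.Generator):
        self.spec = spec
        self.mlp = _Mlp(spec.n_leads * spec.width, spec.hidden, spec.n_classes, rng)

    def children(self):
        return [self.mlp]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        self._shape = x.shape
        return self.mlp.forward(x.reshape(x.shape[0], -1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.mlp.backward(grad).reshape(self._shape)


def lead_weights(block: FeatureBlock, network: LamNetwork) -> np.ndarray:
    """Per-sample softmax lead weights for a feature block."""
    return network.lead_weights(block.features)


def apply_lam(block: FeatureBlock, network: LamNetwork) -> np.ndarray:
    """Residually weighted features: row i becomes f_i * (1 + w_i)."""
    w = network.lead_weights(block.features)
    return block.features * (1.0 + w[:, :, None])


class HeadClassifier:
    """Trainable classification head over feature blocks.

    sklearn-flavoured API: ``fit(X, y)`` then ``predict`` /
    ``predict_proba``. Training is Adam on softmax cross-entropy (optionally
    class-weighted), with early stopping on a held-out tail of the shuffled
    training data. Deterministic given ``seed``.
    """

    network_cls = LamNetwork

    def __init__(self, n_leads: int, width: int = 512, n_classes: int = 2,
                 hidden: tuple[int, ...] = (128, 64), learning_rate: float = 0.001,
                 batch_size: int = 128, epochs: int = 30, patience: int = 5,
                 val_fraction: float = 0.15, class_weights: np.ndarray | None = None,
                 weighted: bool = False, seed: int = 0):
        self.spec = LamSpec(n_leads=n_leads, width=width, n_classes=n_classes,
                            hidden=hidden)
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.class_weights = class_weights
        self.weighted = weighted
        self.seed = seed
        self.network: nn.Layer | None = None
        self.classes_: tuple[str, ...] | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "HeadClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=object)
        self.classes_ = tuple(sorted(set(map(str, y))))
        if len(self.classes_) != self.spec.n_classes:
            raise ValueError(
                f"expected {self.spec.n_classes} classes, data has {len(self.classes_)}")
        yi = np.array([self.classes_.index(str(v)) for v in y])
        weights = None
        if self.weighted:
            weights = self.class_weights
            if weights is None:
                counts = np.bincount(yi, minlength=len(self.classes_)).astype(float)
                weights = counts.sum() / counts
                weights /= weights.mean()

        rng = np.random.default_rng(self.seed)
        net = self.network_cls(self.spec, rng)
        opt = nn.Adam(net.all_parameters(), lr=self.learning_rate)

        order = rng.permutation(len(X))
        n_val = max(1, int(self.val_fraction * len(X))) if len(X) > 10 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        best_val, best_state, stall = np.inf, None, 0
        net.set_training(True)
        for _ in range(self.epochs):
            perm = rng.permutation(train_idx)
            for start in range(0, len(perm), self.batch_size):
                batch = perm[start:start + self.batch_size]
                opt.zero_grad()
                logits = net.forward(X[batch])
                _, dlogits = nn.softmax_cross_entropy(logits, yi[batch], weights)
                net.backward(dlogits)
                opt.step()
            if n_val:
                net.set_training(False)
                val_loss, _ = nn.softmax_cross_entropy(
                    net.forward(X[val_idx]), yi[val_idx], weights)
                net.set_training(True)
                if val_loss < best_val - 1e-6:
                    best_val, stall = val_loss, 0
                    best_state = [p.value.copy() for p in net.all_parameters()]
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_state is not None:
            for p, v in zip(net.all_parameters(), best_state):
                p.value[...] = v
        net.set_training(False)
        self.network = net
        return self

    def _require_fitted(self) -> nn.Layer:
        if self.network is None:
            raise RuntimeError("classifier head has not been trained")
        return self.network

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        net = self._require_fitted()
        net.set_training(False)
        return nn.softmax(net.forward(np.asarray(X, dtype=np.float64)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(X).argmax(axis=1)
        assert self.classes_ is not None
        return np.array([self.classes_[i] for i in idx], dtype=object)


class LamMlpClassifier(HeadClassifier):
    """LAM-weighted MLP head (the default classifier)."""

    network_cls = LamNetwork

    def lead_weights(self, X: np.ndarray) -> np.ndarray:
        net = self._require_fitted()
        assert isinstance(net, LamNetwork)
        net.set_training(False)
        return net.lead_weights(np.asarray(X, dtype=np.float64))


class MlpClassifier(HeadClassifier):
    """Pure-MLP baseline head for the attention ablation."""

    network_cls = MlpNetwork
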