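"""Per-lead 1-D residual feature-extraction models (FEM).

One network per segment length (1-9 s at 1000 Hz): a 13-convolution residual
CNN — a 64-filter kernel-13 stem followed by a stride-2 max pool, then six
two-convolution residual stages of widths 64/64/128/256/512/512, each stage's
second convolution strided 2 and followed by a stride-2 average pool, with a
kernel-1 projection shortcut per stage. Global average pooling over the final
512 channels yields the per-segment feature vector; a fully connected head
(5-unit softmax for the arrhythmia task, 2-unit sigmoid for the binary MI
task) drives training. Features are the GAP output, extracted in inference
mode after training each lead separately at each length.

``width_scale`` shrinks every stage width proportionally (e.g. 1/8) for
desk-scale runs: identical topology and code paths, smaller matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .cache import FeatureCache
from .preprocess import EcgRecord, preprocess_record
from .synthetic import split_inter_patient

__all__ = [
    "FemSpec",
    "TrainConfig",
    "FemNetwork",
    "FemModel",
    "build_fem",
    "train_fem",
    "extract_features",
    "populate_cache",
    "inverse_frequency_weights",
    "pre_gap_length",
]

FULL_STAGE_WIDTHS = (64, 64, 128, 256, 512, 512)


@dataclass(frozen=True)
class FemSpec:
    """Architecture description for one segment length and task."""

    T_L: int
    n_classes: int
    input_len: int
    head_activation: str                     # 'softmax' or 'sigmoid'
    stage_widths: tuple[int, ...] = FULL_STAGE_WIDTHS
    stem_filters: int = 64
    stem_kernel: int = 13

    @property
    def n_conv_layers(self) -> int:
        # stem + two convolutions per stage (projection shortcuts not counted,
        # matching the stated 13-layer tally)
        return 1 + 2 * len(self.stage_widths)

    @property
    def feature_width(self) -> int:
        return self.stage_widths[-1]


@dataclass
class TrainConfig:
    """Optimisation settings: Adam at lr 0.001, batch 128, 40 epochs."""

    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 40
    loss: str = "ce"                         # 'ce' or 'weighted_ce'
    class_weights: np.ndarray | None = None  # derived from data when None
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def build_fem(T_L: int, n_classes: int, width_scale: float = 1.0) -> FemSpec:
    """Spec for segment length ``T_L`` seconds at 1000 Hz.

    ``n_classes`` selects the head: 5 -> softmax, 2 -> sigmoid over two
    units (argmax decides the class either way).
    """
    if T_L not in range(1, 10):
        raise ValueError(f"T_L must be in 1..9, got {T_L}")
    if n_classes not in (2, 5):
        raise ValueError(f"n_classes must be 2 or 5, got {n_classes}")
    widths = tuple(max(1, int(round(w * width_scale))) for w in FULL_STAGE_WIDTHS)
    stem = max(1, int(round(64 * width_scale)))
    return FemSpec(T_L=T_L, n_classes=n_classes, input_len=1000 * T_L,
                   head_activation="softmax" if n_classes == 5 else "sigmoid",
                   stage_widths=widths, stem_filters=stem)


def pre_gap_length(input_len: int) -> int:
    """Temporal length entering GAP under the stem/stage stride arithmetic."""
    length = input_len                       # stem conv, stride 1
    length = max(1, length // 2)             # max pool
    for _ in FULL_STAGE_WIDTHS:
        length = -(-length // 2)             # strided conv, same padding
        length = max(1, length // 2)         # average pool
    return length


class FemNetwork(nn.Layer):
    """Concrete network for a :class:`FemSpec`."""

    def __init__(self, spec: FemSpec, rng: np.random.Generator):
        self.spec = spec
        stem = [nn.Conv1d(1, spec.stem_filters, spec.stem_kernel, stride=1, rng=rng),
                nn.BatchNorm1d(spec.stem_filters), nn.ReLU(), nn.MaxPool1d()]
        stages = []
        c_in = spec.stem_filters
        for width in spec.stage_widths:
            stages.append(nn.ResidualBlock(c_in, width, kernel=3, rng=rng))
            stages.append(nn.AvgPool1d())
            c_in = width
        self.body = nn.Sequential(*stem, *stages)
        self.gap = nn.GlobalAvgPool1d()
        self.head = nn.Dense(spec.feature_width, spec.n_classes, rng=rng)

    def children(self) -> list[nn.Layer]:
        return [self.body, self.gap, self.head]

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        return self.gap.forward(self.body.forward(x))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.forward_features(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.body.backward(self.gap.backward(self.head.backward(grad)))


@dataclass
class FemModel:
    """A trained FEM: network, label mapping and the training trace."""

    network: FemNetwork
    classes: tuple[str, ...]
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def spec(self) -> FemSpec:
        return self.network.spec

    def predict_proba(self, segments: np.ndarray) -> np.ndarray:
        logits = _forward_eval(self.network, _as_batch(segments, self.spec),
                               lambda net, xb: net.forward(xb))
        if self.spec.head_activation == "softmax":
            return nn.softmax(logits)
        p = nn.sigmoid(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, segments: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(segments).argmax(axis=1)
        return np.array([self.classes[i] for i in idx], dtype=object)


def _as_batch(segments: np.ndarray, spec: FemSpec) -> np.ndarray:
    x = np.asarray(segments, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, None, :]
    if x.ndim != 3 or x.shape[1] != 1 or x.shape[2] != spec.input_len:
        raise ValueError(
            f"expected (n, {spec.input_len}) single-lead segments, got {x.shape}")
    return x


def _forward_eval(network: FemNetwork, x: np.ndarray, fn, chunk: int = 256
                  ) -> np.ndarray:
    network.set_training(False)
    outs = [fn(network, x[i:i + chunk]) for i in range(0, len(x), chunk)]
    return np.vstack(outs)


def inverse_frequency_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse class-frequency weights normalised to mean 1."""
    counts = np.bincount(y, minlength=n_classes).astype(float)
    if (counts == 0).any():
        raise ValueError("every class must be present to derive weights")
    w = counts.sum() / counts
    return w / w.mean()


def train_fem(spec: FemSpec, segments: np.ndarray, labels: np.ndarray,
              cfg: TrainConfig) -> FemModel:
    """Train one single-lead FEM; deterministic given ``cfg.seed``.

    ``segments`` is (n, input_len) raw rows; ``labels`` are class symbols.
    Raises on single-class input or shape mismatch.
    """
    x = _as_batch(segments, spec)
    labels = np.asarray(labels, dtype=object)
    classes = tuple(sorted(set(map(str, labels))))
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if len(classes) != spec.n_classes:
        raise ValueError(
            f"spec expects {spec.n_classes} classes, data has {len(classes)}")
    y = np.array([classes.index(str(v)) for v in labels])

    rng = np.random.default_rng(cfg.seed)
    network = FemNetwork(spec, rng)
    cfg = replace(cfg)
    if cfg.loss == "weighted_ce" and cfg.class_weights is None:
        cfg.class_weights = inverse_frequency_weights(y, spec.n_classes)
    weights = cfg.class_weights if cfg.loss == "weighted_ce" else None
    loss_fn = (nn.softmax_cross_entropy if spec.head_activation == "softmax"
               else nn.sigmoid_cross_entropy)

    opt = nn.Adam(network.all_parameters(), lr=cfg.learning_rate)
    history = []
    network.set_training(True)
    for _ in range(cfg.epochs):
        order = rng.permutation(len(x))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(x), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            logits = network.forward(x[batch])
            loss, dlogits = loss_fn(logits, y[batch], weights)
            network.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(batch)
            n_seen += len(batch)
        history.append(epoch_loss / n_seen)
    return FemModel(network=network, classes=classes, config=cfg,
                    loss_history=history)


def extract_features(model: FemModel, segments: np.ndarray) -> np.ndarray:
    """GAP features, one row per segment, input order preserved."""
    x = _as_batch(segments, model.spec)
    return _forward_eval(model.network, x,
                         lambda net, xb: net.forward_features(xb))


def populate_cache(records: list[EcgRecord], task: str,
                   lengths: tuple[int, ...], leads: tuple[int, ...],
                   cfg: TrainConfig, width_scale: float = 1.0,
                   split: tuple[list[EcgRecord], list[EcgRecord]] | None = None,
                   split_fraction: float = 0.8,
                   denoise: bool = True,
                   max_segments_per_record: int | None = None) -> FeatureCache:
    """Train one FEM per (lead, length) and cache train/test GAP features.

    ``split`` supplies explicit (train, test) record lists; otherwise an
    inter-patient split at ``split_fraction`` is derived from ``cfg.seed``.
    ``max_segments_per_record`` caps how many leading windows each record
    contributes (identical cap across leads keeps row alignment).
    """
    if split is None:
        train_recs, test_recs = split_inter_patient(records, split_fraction,
                                                    seed=cfg.seed)
    else:
        train_recs, test_recs = split
    if not train_recs or not test_recs:
        raise ValueError("both train and test splits must be non-empty")
    shared = {r.patient_id for r in train_recs} & {r.patient_id for r in test_recs}
    if shared:
        raise ValueError(f"patients in both splits: {sorted(shared)[:5]}")

    n_classes = len({r.label for r in records})
    cache: FeatureCache | None = None
    for T_L in lengths:
        spec = build_fem(T_L, n_classes, width_scale=width_scale)
        if cache is None:
            cache = FeatureCache(task, feature_width=spec.feature_width)
        cap = max_segments_per_record
        prepped = {split_name: [preprocess_record(r, T_L, denoise_signal=denoise)[:cap]
                                for r in recs]
                   for split_name, recs in (("train", train_recs),
                                            ("test", test_recs))}
        for lead in leads:
            data = {}
            for split_name in ("train", "test"):
                segs = [s for per_rec in prepped[split_name] for s in per_rec]
                if not segs:
                    raise ValueError(f"empty {split_name} split at T_L={T_L}")
                X = np.stack([s.lead_signals[lead - 1] for s in segs])
                labels = np.array([s.label for s in segs], dtype=object)
                patients = np.array([s.patient_id for s in segs], dtype=object)
                data[split_name] = (X, labels, patients)
            model = train_fem(spec, *data["train"][:2], cfg)
            for split_name in ("train", "test"):
                X, labels, patients = data[split_name]
                feats = extract_features(model, X)
                cache.add(lead, T_L, split_name, feats, labels, patients)
            cache.manifest[f"lead{lead}_T{T_L}"] = {
                "epochs": cfg.epochs, "lr": cfg.learning_rate,
                "batch_size": cfg.batch_size, "loss": cfg.loss,
                "seed": cfg.seed, "final_loss": model.loss_history[-1]}
    assert cache is not None
    return cache
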