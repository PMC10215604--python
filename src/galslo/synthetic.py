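"""Synthetic multi-lead pseudo-ECG and feature fixtures.

Two generators make the whole pipeline testable without any download:

* :func:`generate_records` emits raw 12-lead records at 1000 Hz with
  variable length, class-dependent beat rate (tachycardia-like classes beat
  fast, bradycardia-like slow), ectopic extra beats for premature-beat
  classes, per-lead amplitude morphology whose class differences are planted
  only on a configurable subset of leads, sinusoidal baseline wander, and
  white noise. Beats are Gaussian-bump QRS surrogates, not physiological
  waveforms: the fixture exercises selection and attention machinery, not
  cardiology realism.

* :func:`generate_feature_fixture` skips the signal level entirely and fills
  a :class:`~galslo.cache.FeatureCache` with class-conditional Gaussian
  feature vectors, separated only on informative leads. This is the
  substrate for GA-search tests where network training would only add noise.

Both are deterministic given their seed; patient identifiers group samples
for inter-patient splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cache import FeatureCache
from .preprocess import EcgRecord

__all__ = [
    "ClassEffect",
    "SynthConfig",
    "FeatureFixtureConfig",
    "generate_records",
    "generate_feature_fixture",
    "split_inter_patient",
    "arrhythmia_synth_config",
    "mi_synth_config",
]


@dataclass(frozen=True)
class ClassEffect:
    """Per-class waveform parameters.

    bpm: mean beat rate; ectopic_prob: probability that a beat is an ectopic
    extra bump (premature-beat surrogate); amp_delta: multiplicative
    amplitude change applied on informative leads only; invert: flip the bump
    polarity on informative leads (infarct-like morphology change).
    """

    bpm: float = 75.0
    ectopic_prob: float = 0.0
    amp_delta: float = 0.0
    invert: bool = False


# fixed per-lead base amplitude profile (mV) for the canonical 12 leads
_BASE_PROFILE = np.array([0.9, 1.1, 0.7, -0.8, 0.5, 0.9,
                          0.6, 1.0, 1.2, 1.3, 1.1, 0.9])


@dataclass(frozen=True)
class SynthConfig:
    """Raw-record generator settings.

    Defaults mirror the public-data conditions the pipeline targets:
    12 synchronized leads at 1000 Hz, record lengths drawn from 11-92 s,
    sinusoidal baseline wander (0.2 mV at 0.3 Hz) plus white noise
    (0.05 mV sd), and one record per patient.
    """

    classes: dict[str, ClassEffect] = field(default_factory=dict)
    n_patients_per_class: int = 10
    record_seconds: tuple[float, float] = (11.0, 92.0)
    fs: float = 1000.0
    informative_leads: tuple[int, ...] = (2, 4)  # 1-based gene indices
    baseline_amp: float = 0.2
    baseline_freq: float = 0.3
    white_sd: float = 0.05
    bump_width: float = 0.04  # Gaussian sd of the QRS surrogate, seconds
    seed: int = 0

    def __post_init__(self):
        if not self.informative_leads:
            raise ValueError("informative_leads must be non-empty")
        if any(not 1 <= v <= 12 for v in self.informative_leads):
            raise ValueError("informative_leads are 1-based indices in 1..12")


def arrhythmia_synth_config(**overrides) -> SynthConfig:
    """Five-class fixture shaped like the arrhythmia task (N/PAC/PVC/T/B)."""
    classes = {
        "N": ClassEffect(bpm=75),
        "PAC": ClassEffect(bpm=75, ectopic_prob=0.3, amp_delta=0.4),
        "PVC": ClassEffect(bpm=75, ectopic_prob=0.3, amp_delta=0.8, invert=True),
        "T": ClassEffect(bpm=120),
        "B": ClassEffect(bpm=50),
    }
    return SynthConfig(classes=classes, **overrides)


def mi_synth_config(effect: float = 1.0, **overrides) -> SynthConfig:
    """Binary fixture shaped like the MI task: morphology change on
    informative leads only, same beat rate in both classes."""
    classes = {
        "HC": ClassEffect(bpm=75),
        "MI": ClassEffect(bpm=75, amp_delta=effect, invert=True),
    }
    overrides.setdefault("record_seconds", (32.0, 120.0))
    return SynthConfig(classes=classes, **overrides)


def _render_record(rng: np.random.Generator, cfg: SynthConfig,
                   effect: ClassEffect) -> np.ndarray:
    duration = rng.uniform(*cfg.record_seconds)
    n = int(round(duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    period = 60.0 / effect.bpm
    beat_times = np.arange(0.3, duration - 0.3, period)
    beat_times = beat_times + rng.normal(0.0, 0.01, size=beat_times.size)

    # per-lead amplitude: base profile with informative-lead class delta
    profile = _BASE_PROFILE.copy()
    info = np.array(cfg.informative_leads) - 1
    profile[info] *= (1.0 + effect.amp_delta)
    if effect.invert:
        profile[info] *= -1.0

    signals = np.zeros((12, n))
    width = cfg.bump_width
    for bt in beat_times:
        lo = max(0, int((bt - 5 * width) * cfg.fs))
        hi = min(n, int((bt + 5 * width) * cfg.fs))
        bump = np.exp(-0.5 * ((t[lo:hi] - bt) / width) ** 2)
        signals[:, lo:hi] += profile[:, None] * bump
        if effect.ectopic_prob and rng.random() < effect.ectopic_prob:
            # premature extra bump shortly after the regular beat
            et = bt + period * rng.uniform(0.3, 0.5)
            elo = max(0, int((et - 5 * width) * cfg.fs))
            ehi = min(n, int((et + 5 * width) * cfg.fs))
            if ehi > elo:
                ebump = np.exp(-0.5 * ((t[elo:ehi] - et) / width) ** 2)
                eprof = profile * 0.6
                signals[:, elo:ehi] += eprof[:, None] * ebump

    phase = rng.uniform(0, 2 * np.pi, size=12)
    signals += cfg.baseline_amp * np.sin(
        2 * np.pi * cfg.baseline_freq * t[None, :] + phase[:, None])
    signals += rng.normal(0.0, cfg.white_sd, size=signals.shape)
    return signals


def generate_records(cfg: SynthConfig) -> list[EcgRecord]:
    """One record per synthetic patient, labels and patient ids attached."""
    if not cfg.classes:
        raise ValueError("SynthConfig.classes must not be empty")
    rng = np.random.default_rng(cfg.seed)
    records = []
    for label in sorted(cfg.classes):
        effect = cfg.classes[label]
        for p in range(cfg.n_patients_per_class):
            pid = f"{label}_p{p:03d}"
            records.append(EcgRecord(
                patient_id=pid, record_id=f"{pid}_r0",
                signals=_render_record(rng, cfg, effect),
                fs=cfg.fs, label=label))
    return records


def split_inter_patient(records: list[EcgRecord], fraction: float = 0.8,
                        seed: int = 0) -> tuple[list[EcgRecord], list[EcgRecord]]:
    """Patient-disjoint split: the given fraction of patients goes to train.

    Patients are shuffled within their (majority-)label group so that small
    fixtures keep every class represented on both sides.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[EcgRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    label_of = {pid: recs[0].label for pid, recs in by_patient.items()}
    groups: dict[str, list[str]] = {}
    for pid in sorted(by_patient):
        groups.setdefault(label_of[pid], []).append(pid)
    train_ids: set[str] = set()
    for label in sorted(groups):
        pids = groups[label]
        order = rng.permutation(len(pids))
        n_train = int(round(fraction * len(pids)))
        train_ids.update(pids[i] for i in order[:n_train])
    train = [r for r in records if r.patient_id in train_ids]
    test = [r for r in records if r.patient_id not in train_ids]
    return train, test


@dataclass(frozen=True)
class FeatureFixtureConfig:
    """Class-conditional Gaussian feature fixture settings.

    On informative leads each class mean is displaced ``effect_size``
    within-class standard deviations from the grand center along a seeded
    random direction (so two classes sit ``2 * effect_size`` sd apart);
    non-informative leads share identical (zero) class means. Each patient contributes
    ``segments_per_patient`` feature rows plus a small patient-level random
    offset, so inter-patient structure is present.
    """

    classes: tuple[str, ...] = ("HC", "MI")
    n_train_patients: int = 8
    n_test_patients: int = 4
    segments_per_patient: int = 6
    feature_width: int = 512
    lengths: tuple[int, ...] = (1, 2, 3)
    leads: tuple[int, ...] = tuple(range(1, 13))
    informative_leads: tuple[int, ...] = (2, 4)
    effect_size: float = 3.0
    patient_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not self.informative_leads:
            raise ValueError("informative_leads must be non-empty")


def generate_feature_fixture(cfg: FeatureFixtureConfig) -> FeatureCache:
    """Fill a FeatureCache with planted class separation on informative leads."""
    rng = np.random.default_rng(cfg.seed)
    cache = FeatureCache(task="synthetic", feature_width=cfg.feature_width,
                         classes=tuple(sorted(cfg.classes)))
    n_cls = len(cfg.classes)
    # one mean direction per (lead, length); class means arranged along it
    for T_L in cfg.lengths:
        # common segment ordering across leads: iterate patients, segments
        plan = []  # (split, patient, class)
        for split, n_pat in (("train", cfg.n_train_patients),
                             ("test", cfg.n_test_patients)):
            for label in sorted(cfg.classes):
                for p in range(n_pat):
                    plan.append((split, f"{split}_{label}_p{p:02d}", label))
        patient_offsets = {pid: rng.normal(0, cfg.patient_sd, cfg.feature_width)
                           for _, pid, _ in plan}
        for lead in cfg.leads:
            direction = rng.normal(size=cfg.feature_width)
            direction /= np.linalg.norm(direction)
            informative = lead in cfg.informative_leads
            rows = {"train": [], "test": []}
            labs = {"train": [], "test": []}
            pats = {"train": [], "test": []}
            for split, pid, label in plan:
                k = sorted(cfg.classes).index(label)
                if informative:
                    # each class mean displaced effect_size sd from the
                    # grand center; adjacent classes are 2*effect apart
                    shift = (2 * k - (n_cls - 1)) * cfg.effect_size
                    mean = shift * direction
                else:
                    mean = 0.0
                base = mean + patient_offsets[pid]
                x = base + rng.normal(size=(cfg.segments_per_patient,
                                            cfg.feature_width))
                rows[split].append(x)
                labs[split].extend([label] * cfg.segments_per_patient)
                pats[split].extend([pid] * cfg.segments_per_patient)
            for split in ("train", "test"):
                cache.add(lead, T_L, split, np.vstack(rows[split]),
                          np.array(labs[split], dtype=object),
                          np.array(pats[split], dtype=object))
    return cache
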