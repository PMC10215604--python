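"""Raw multi-lead ECG preprocessing: denoise, segment, normalise.

Recordings arrive as variable-length 12-lead signals at 1000 Hz. For each
candidate segment length of 1-9 s the pipeline (a) removes baseline wander
and broadband noise per lead with a Daubechies-6 wavelet decomposition,
(b) cuts non-overlapping windows sequentially from sample 0 with no beat
detection, discarding the trailing partial window, and (c) z-scores each
lead of each window independently.

The wavelet recipe: decompose to a level whose approximation band lies below
about 2 Hz (level 8 at 1000 Hz), zero the approximation coefficients
(baseline wander), and soft-threshold the two finest detail bands with the
universal threshold (broadband / muscle noise). The recipe is isolated in
:func:`denoise` so it can be swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pywt

__all__ = [
    "LEAD_ORDER",
    "lead_index",
    "canonical_lead",
    "EcgRecord",
    "Segment",
    "denoise",
    "segment_record",
    "zscore",
    "zscore_rows",
    "preprocess_record",
    "SEGMENT_LENGTHS",
]

#: Canonical 12-lead order; index i corresponds to mask gene L_{i+1}.
LEAD_ORDER = ("I", "II", "III", "avR", "avL", "avF",
              "V1", "V2", "V3", "V4", "V5", "V6")

SEGMENT_LENGTHS = tuple(range(1, 10))

_ALIASES = {name.lower(): name for name in LEAD_ORDER}
_ALIASES.update({"avr": "avR", "avl": "avL", "avf": "avF"})

_ZERO_VAR_GUARD = 1e-8


def canonical_lead(name: str) -> str:
    """Map a lead name (case-insensitive, e.g. 'aVR') to canonical form."""
    try:
        return _ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown ECG lead name: {name!r}") from None


def lead_index(name: str) -> int:
    """0-based index of a lead in the canonical order."""
    return LEAD_ORDER.index(canonical_lead(name))


@dataclass
class EcgRecord:
    """One 12-lead recording: the unit of inter-patient splitting."""

    patient_id: str
    record_id: str
    signals: np.ndarray  # (12, n_samples), mV
    fs: float
    label: str
    lead_order: tuple[str, ...] = LEAD_ORDER

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2 or self.signals.shape[0] != 12:
            raise ValueError("signals must be a 12 x n_samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signals.shape[1] < self.fs:
            raise ValueError("record must be at least 1 s long")
        if tuple(self.lead_order) != LEAD_ORDER:
            raise ValueError("lead_order must be the canonical 12-lead order")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One fixed-length multi-lead fragment: the unit of model input."""

    patient_id: str
    record_id: str
    lead_signals: np.ndarray  # (12, T_L * fs)
    T_L: int
    label: str
    start_index: int

    def __post_init__(self):
        self.lead_signals = np.asarray(self.lead_signals, dtype=np.float64)
        if self.T_L not in SEGMENT_LENGTHS:
            raise ValueError(f"T_L must be in 1..9, got {self.T_L}")


def _decomposition_level(fs: float, n: int, wavelet: pywt.Wavelet) -> int:
    # approximation band [0, fs / 2**(level+1)]; aim below ~2 Hz
    target = max(1, math.ceil(math.log2(fs / 2.0)) - 1)
    return max(1, min(target, pywt.dwt_max_level(n, wavelet.dec_len)))


def denoise(signal: np.ndarray, fs: float, wavelet: str = "db6",
            threshold: bool = True) -> np.ndarray:
    """Wavelet baseline-wander and noise removal; length preserving.

    Parameters
    ----------
    signal : 1-D array of samples.
    fs : sampling rate in Hz.
    wavelet : discrete wavelet name.
    threshold : when False only the approximation band is zeroed, making the
        operator exactly linear (used by property tests).
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("denoise expects a 1-D signal")
    wav = pywt.Wavelet(wavelet)
    if x.size < wav.dec_len:
        raise ValueError(
            f"signal of length {x.size} is shorter than the {wavelet} "
            f"filter length {wav.dec_len}")
    level = _decomposition_level(fs, x.size, wav)
    # symmetric pad to a multiple of 2**level so the periodized transform
    # reconstructs the padded signal exactly (no end-of-record artifacts)
    pad = (-x.size) % (2 ** level)
    xp = np.pad(x, (0, pad), mode="symmetric") if pad else x
    coeffs = pywt.wavedec(xp, wav, level=level, mode="periodization")
    coeffs[0] = np.zeros_like(coeffs[0])  # kill the sub-2 Hz band
    if threshold:
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745 if finest.size else 0.0
        thr = sigma * math.sqrt(2.0 * math.log(max(xp.size, 2)))
        if thr > 0:
            for j in (-1, -2):
                if abs(j) <= len(coeffs) - 1:
                    coeffs[j] = pywt.threshold(coeffs[j], thr, mode="soft")
    out = pywt.waverec(coeffs, wav, mode="periodization")
    return out[:x.size]


def segment_record(record: EcgRecord, T_L: int) -> list[Segment]:
    """Cut floor(duration / T_L) non-overlapping windows from sample 0.

    Returns an empty list when the record is shorter than ``T_L`` seconds;
    the trailing remainder shorter than one window is discarded. Every
    segment inherits the record's label.
    """
    if T_L not in SEGMENT_LENGTHS:
        raise ValueError(f"T_L must be in 1..9, got {T_L}")
    width = int(round(T_L * record.fs))
    n_seg = record.n_samples // width
    segments = []
    for i in range(n_seg):
        start = i * width
        segments.append(Segment(
            patient_id=record.patient_id, record_id=record.record_id,
            lead_signals=record.signals[:, start:start + width].copy(),
            T_L=T_L, label=record.label, start_index=start))
    return segments


def zscore_rows(x: np.ndarray) -> np.ndarray:
    """Z-score each row independently; rows with sd below guard become zeros."""
    x = np.asarray(x, dtype=np.float64)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    ok = sd > _ZERO_VAR_GUARD
    return np.where(ok, (x - mean) / np.where(ok, sd, 1.0), 0.0)


def zscore(segment: Segment) -> Segment:
    """Per-lead, per-segment z-score normalisation."""
    return replace(segment, lead_signals=zscore_rows(segment.lead_signals))


def preprocess_record(record: EcgRecord, T_L: int,
                      denoise_signal: bool = True) -> list[Segment]:
    """Denoise each lead, segment at ``T_L`` seconds, and z-score."""
    if denoise_signal:
        cleaned = np.vstack([denoise(row, record.fs) for row in record.signals])
        record = replace(record, signals=cleaned)
    return [zscore(seg) for seg in segment_record(record, T_L)]
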