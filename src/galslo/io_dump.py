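"""Plain array-dump record format.

One record is a pair of files in a directory: ``<record_id>.npy`` holding the
12 x n signal matrix (mV) and ``<record_id>.json`` with metadata
(``patient_id``, ``label``, ``fs``, ``lead_order``). The synthetic generator
writes this format and tests read it back, bypassing WFDB entirely.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import LEAD_ORDER, EcgRecord, canonical_lead

__all__ = ["write_record", "read_record", "read_records", "write_records"]


def write_record(directory: str | Path, record: EcgRecord) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    npy = directory / f"{record.record_id}.npy"
    np.save(npy, record.signals)
    meta = {"patient_id": record.patient_id, "label": record.label,
            "fs": record.fs, "lead_order": list(record.lead_order)}
    (directory / f"{record.record_id}.json").write_text(json.dumps(meta, indent=2))
    return npy


def write_records(directory: str | Path, records: list[EcgRecord]) -> None:
    for rec in records:
        write_record(directory, rec)


def read_record(directory: str | Path, record_id: str) -> EcgRecord:
    directory = Path(directory)
    signals = np.load(directory / f"{record_id}.npy")
    meta = json.loads((directory / f"{record_id}.json").read_text())
    order = tuple(canonical_lead(n) for n in meta.get("lead_order", LEAD_ORDER))
    if order != LEAD_ORDER:
        # reorder rows into canonical order
        perm = [order.index(name) for name in LEAD_ORDER]
        signals = signals[perm]
    return EcgRecord(patient_id=str(meta["patient_id"]), record_id=record_id,
                     signals=signals, fs=float(meta["fs"]),
                     label=str(meta["label"]))


def read_records(directory: str | Path) -> list[EcgRecord]:
    directory = Path(directory)
    out = []
    for npy in sorted(directory.glob("*.npy")):
        out.append(read_record(directory, npy.stem))
    return out
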