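"""Minimal WFDB reader and writer for 12-lead format-16 records.

Supports the subset of the WFDB specification used by public 12-lead
1000 Hz diagnostic records: a text header (``.hea``) describing one
interleaved little-endian 16-bit signal file (``.dat``) with per-lead gain
and baseline. Lead names are mapped case-insensitively onto the canonical
order (I, II, III, avR, avL, avF, V1-V6); physical values are
``(adc - baseline) / gain`` in the units declared by the header (mV here).

The writer exists so the reader can be round-trip tested without any
external download; it is not a general-purpose WFDB exporter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import LEAD_ORDER, EcgRecord, canonical_lead

__all__ = ["read_wfdb_record", "write_wfdb_record", "read_wfdb_dir"]

_GAIN_RE = re.compile(r"^(?P<gain>-?[\d.]+)(\((?P<baseline>-?\d+)\))?(/(?P<units>\S+))?$")


@dataclass
class _SignalSpec:
    file: str
    fmt: str
    gain: float
    baseline: int
    name: str


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[_SignalSpec]]:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    specs = []
    for ln in lines[1:1 + n_sig]:
        fields = ln.split()
        fname, fmt = fields[0], fields[1]
        gain, baseline, m = 200.0, 0, None
        if len(fields) > 2:
            m = _GAIN_RE.match(fields[2])
            if m:
                gain = float(m.group("gain")) or 200.0
                if m.group("baseline") is not None:
                    baseline = int(m.group("baseline"))
        if len(fields) > 4 and m and m.group("baseline") is None:
            # adc zero column serves as baseline when none was given inline
            try:
                baseline = int(fields[4])
            except ValueError:
                pass
        name = fields[-1] if len(fields) > 5 else f"sig{len(specs)}"
        specs.append(_SignalSpec(fname, fmt, gain, baseline, name))
    return record_name, n_sig, fs, n_samples, specs


def read_wfdb_record(hea_path: str | Path, patient_id: str | None = None,
                     label: str = "") -> EcgRecord:
    """Read one 12-lead format-16 WFDB record into canonical lead order."""
    hea_path = Path(hea_path)
    record_name, n_sig, fs, n_samples, specs = _parse_header(hea_path)
    fmts = {s.fmt for s in specs}
    if fmts != {"16"}:
        raise ValueError(f"only WFDB format 16 is supported, header declares {sorted(fmts)}")
    dat_files = {s.file for s in specs}
    if len(dat_files) != 1:
        raise ValueError("only single-file interleaved records are supported")
    raw = np.fromfile(hea_path.parent / dat_files.pop(), dtype="<i2")
    if n_samples:
        raw = raw[:n_samples * n_sig]
    raw = raw.reshape(-1, n_sig).T.astype(np.float64)
    physical = np.stack([(raw[i] - specs[i].baseline) / specs[i].gain
                         for i in range(n_sig)])
    names = [canonical_lead(s.name) for s in specs]
    if set(names) != set(LEAD_ORDER):
        raise ValueError("record does not contain exactly the 12 standard leads")
    perm = [names.index(lead) for lead in LEAD_ORDER]
    return EcgRecord(patient_id=patient_id or record_name,
                     record_id=record_name, signals=physical[perm],
                     fs=fs, label=label)


def write_wfdb_record(directory: str | Path, record: EcgRecord,
                      gain: float = 2000.0) -> Path:
    """Write a format-16 header + signal pair (round-trip test support)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_sig, n_samples = record.signals.shape
    hea = directory / f"{record.record_id}.hea"
    dat_name = f"{record.record_id}.dat"
    adc = np.clip(np.round(record.signals * gain), -32768, 32767).astype("<i2")
    adc.T.reshape(-1).tofile(directory / dat_name)
    lines = [f"{record.record_id} {n_sig} {record.fs:g} {n_samples}"]
    for i, name in enumerate(record.lead_order):
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {adc[i, 0]} 0 0 {name}")
    hea.write_text("\n".join(lines) + "\n")
    return hea


def read_wfdb_dir(directory: str | Path,
                  labels: dict[str, str] | None = None,
                  patients: dict[str, str] | None = None) -> list[EcgRecord]:
    """Read every ``.hea`` record in a directory.

    ``labels`` / ``patients`` map record ids to class labels and patient ids;
    missing entries default to empty label and record id as its own patient.
    """
    labels = labels or {}
    patients = patients or {}
    out = []
    for hea in sorted(Path(directory).glob("*.hea")):
        rid = hea.stem
        out.append(read_wfdb_record(hea, patient_id=patients.get(rid),
                                    label=labels.get(rid, "")))
    return out
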