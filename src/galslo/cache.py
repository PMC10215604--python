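"""Per-(lead, length, split) feature cache: the substrate the GA searches on.

Each entry holds the GAP feature matrix for one lead at one segment length,
with index-aligned label and patient vectors. Entries for the same
``(lead, T_L)`` use identical segment ordering across leads, so selected
leads can be stacked row-for-row into a classification block. Train and test
entries must never share a patient (inter-patient paradigm); this is enforced
at insertion time.

Persistence is an HDF5 container with groups ``/<task>/<lead>/<T_L>/<split>``
(datasets ``features``, ``labels``, ``patients``) plus a JSON manifest
attribute recording the task, feature width, class set and training configs.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

__all__ = ["FeatureCache"]

SPLITS = ("train", "test")


class FeatureCache:
    def __init__(self, task: str, feature_width: int = 512,
                 classes: tuple[str, ...] = ()):
        self.task = task
        self.feature_width = int(feature_width)
        self.classes = tuple(classes)
        self._entries: dict[tuple[int, int, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.manifest: dict = {}

    # -- construction ------------------------------------------------------

    def add(self, lead: int, T_L: int, split: str, features: np.ndarray,
            labels: np.ndarray, patients: np.ndarray) -> None:
        if not (1 <= lead <= 12):
            raise ValueError(f"lead index must be 1..12, got {lead}")
        if split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
        features = np.asarray(features, dtype=np.float64)
        labels = np.asarray(labels, dtype=object)
        patients = np.asarray(patients, dtype=object)
        if features.ndim != 2 or features.shape[1] != self.feature_width:
            raise ValueError(
                f"features must be n x {self.feature_width}, got {features.shape}")
        if not (len(features) == len(labels) == len(patients)):
            raise ValueError("features, labels and patients must be aligned")
        other = "test" if split == "train" else "train"
        shared = set(patients) & self.patient_ids(other)
        if shared:
            raise ValueError(
                f"patients present in both train and test: {sorted(map(str, shared))[:5]}")
        self._entries[(lead, T_L, split)] = (features, labels, patients)
        new = set(map(str, labels)) - set(self.classes)
        if new:
            self.classes = tuple(sorted(set(self.classes) | new))

    # -- access ------------------------------------------------------------

    def get(self, lead: int, T_L: int, split: str):
        try:
            return self._entries[(lead, T_L, split)]
        except KeyError:
            raise KeyError(
                f"feature cache has no entry for lead={lead}, T_L={T_L}, "
                f"split={split!r}") from None

    def __contains__(self, key) -> bool:
        return tuple(key) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def keys(self):
        return sorted(self._entries)

    def leads(self) -> tuple[int, ...]:
        return tuple(sorted({k[0] for k in self._entries}))

    def lengths(self) -> tuple[int, ...]:
        return tuple(sorted({k[1] for k in self._entries}))

    def patient_ids(self, split: str) -> set:
        out: set = set()
        for (_, _, sp), (_, _, patients) in self._entries.items():
            if sp == split:
                out.update(patients)
        return out

    def block(self, T_L: int, leads: tuple[int, ...], split: str):
        """Stack the selected leads into an (n, n_leads, width) block.

        Rows are aligned across leads; label vectors must agree exactly.
        Returns ``(X, labels, patients)``.
        """
        if not leads:
            raise ValueError("at least one lead must be selected")
        mats, ref_labels, ref_patients = [], None, None
        for lead in sorted(leads):
            feats, labels, patients = self.get(lead, T_L, split)
            if ref_labels is None:
                ref_labels, ref_patients = labels, patients
            elif not np.array_equal(labels, ref_labels):
                raise ValueError(
                    f"segment ordering differs between leads at T_L={T_L}")
            mats.append(feats)
        X = np.stack(mats, axis=1)
        return X, ref_labels, ref_patients

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.attrs["manifest"] = json.dumps({
                "task": self.task, "feature_width": self.feature_width,
                "classes": list(self.classes), "extra": self.manifest})
            for (lead, T_L, split), (feats, labels, patients) in self._entries.items():
                grp = f.require_group(f"{self.task}/{lead}/{T_L}/{split}")
                grp.create_dataset("features", data=feats)
                grp.create_dataset("labels", data=np.array([str(v) for v in labels],
                                                           dtype=h5py.string_dtype()))
                grp.create_dataset("patients", data=np.array([str(v) for v in patients],
                                                             dtype=h5py.string_dtype()))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureCache":
        with h5py.File(path, "r") as f:
            manifest = json.loads(f.attrs["manifest"])
            cache = cls(manifest["task"], manifest["feature_width"],
                        tuple(manifest["classes"]))
            cache.manifest = manifest.get("extra", {})
            task_grp = f[manifest["task"]]
            for lead in task_grp:
                for T_L in task_grp[lead]:
                    for split in task_grp[lead][T_L]:
                        grp = task_grp[lead][T_L][split]
                        cache._entries[(int(lead), int(T_L), split)] = (
                            grp["features"][...],
                            grp["labels"].asstr()[...].astype(object),
                            grp["patients"].asstr()[...].astype(object))
        return cache
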