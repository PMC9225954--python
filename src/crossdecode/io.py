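"""File containers: HDF5 for epoch/pattern/feature sets, NIfTI for volumes,
tidy TSV for results.

Every container writes a ``format`` attribute and round-trips exactly;
loaders raise :class:`FormatError` naming the missing dataset when a file is
truncated or of the wrong kind.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .design import ConditionLabel
from .simulate import EEGEpochSet, FMRIPatternSet, FeatureActivationSet
from .spatiotemporal import SearchlightVolume

__all__ = [
    "FormatError",
    "save_eeg",
    "load_eeg",
    "save_fmri",
    "load_fmri",
    "save_features",
    "load_features",
    "save_searchlight_nifti",
    "load_nifti_volume",
    "results_to_tsv",
    "read_results_tsv",
]


class FormatError(IOError):
    """A container file does not match the expected schema."""

    def __init__(self, path, expected: str, found: str):
        super().__init__(f"{path}: expected {expected}, found {found}")
        self.expected = expected
        self.found = found


def _require(handle: h5py.File, path, *names: str) -> None:
    for name in names:
        if name not in handle:
            raise FormatError(path, f"dataset {name!r}", "missing")


def _labels_to_table(labels) -> np.ndarray:
    rows = [
        (
            lab.category,
            lab.location,
            lab.clutter,
            -1 if lab.exemplar is None else int(lab.exemplar),
        )
        for lab in labels
    ]
    return np.array(
        rows,
        dtype=[
            ("category", "S32"),
            ("location", "S32"),
            ("clutter", "S32"),
            ("exemplar", "i8"),
        ],
    )


def _labels_from_table(table: np.ndarray):
    out = []
    for row in table:
        ex = int(row["exemplar"])
        out.append(
            ConditionLabel(
                category=row["category"].decode(),
                location=row["location"].decode(),
                clutter=row["clutter"].decode(),
                exemplar=None if ex < 0 else ex,
            )
        )
    return out


# --------------------------------------------------------------------------
# EEG epochs
# --------------------------------------------------------------------------

def save_eeg(path, epochs: EEGEpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "crossdecode-eeg-v1"
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_ms", data=np.asarray(epochs.time_ms, dtype=float))
        f.create_dataset("channel_layout", data=np.asarray(epochs.channel_layout))
        f.create_dataset("labels", data=_labels_to_table(epochs.labels))


def load_eeg(path) -> EEGEpochSet:
    with h5py.File(path, "r") as f:
        fmt = f.attrs.get("format", "unknown")
        if fmt != "crossdecode-eeg-v1":
            raise FormatError(path, "crossdecode-eeg-v1", str(fmt))
        _require(f, path, "data", "time_ms", "channel_layout", "labels")
        return EEGEpochSet(
            data=f["data"][...],
            labels=_labels_from_table(f["labels"][...]),
            time_ms=f["time_ms"][...],
            channel_layout=f["channel_layout"][...],
        )


# --------------------------------------------------------------------------
# fMRI patterns
# --------------------------------------------------------------------------

def save_fmri(path, patterns: FMRIPatternSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "crossdecode-fmri-v1"
        f.create_dataset("data", data=patterns.data)
        f.create_dataset("voxel_coords", data=np.asarray(patterns.voxel_coords))
        f.create_dataset(
            "roi_labels",
            data=np.asarray([str(r) for r in patterns.roi_labels], dtype="S32"),
        )
        f.create_dataset("condition_labels", data=_labels_to_table(patterns.condition_labels))


def load_fmri(path) -> FMRIPatternSet:
    with h5py.File(path, "r") as f:
        fmt = f.attrs.get("format", "unknown")
        if fmt != "crossdecode-fmri-v1":
            raise FormatError(path, "crossdecode-fmri-v1", str(fmt))
        _require(f, path, "data", "voxel_coords", "roi_labels", "condition_labels")
        return FMRIPatternSet(
            data=f["data"][...],
            condition_labels=_labels_from_table(f["condition_labels"][...]),
            voxel_coords=f["voxel_coords"][...],
            roi_labels=np.asarray([s.decode() for s in f["roi_labels"][...]]),
        )


# --------------------------------------------------------------------------
# feature activations
# --------------------------------------------------------------------------

def save_features(path, features: FeatureActivationSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "crossdecode-features-v1"
        f.attrs["layer_names"] = json.dumps(list(features.layer_names))
        grp = f.create_group("layers")
        for name in features.layer_names:
            grp.create_dataset(name, data=features.data[name])
        f.create_dataset("labels", data=_labels_to_table(features.labels))


def load_features(path) -> FeatureActivationSet:
    with h5py.File(path, "r") as f:
        fmt = f.attrs.get("format", "unknown")
        if fmt != "crossdecode-features-v1":
            raise FormatError(path, "crossdecode-features-v1", str(fmt))
        _require(f, path, "layers", "labels")
        layer_names = json.loads(f.attrs["layer_names"])
        data = {name: f["layers"][name][...] for name in layer_names}
        return FeatureActivationSet(
            data=data,
            labels=_labels_from_table(f["labels"][...]),
            layer_names=layer_names,
        )


# --------------------------------------------------------------------------
# volumes and results
# --------------------------------------------------------------------------

def save_searchlight_nifti(
    path, volume: SearchlightVolume, affine: Optional[np.ndarray] = None
) -> None:
    """Write the accuracy grid as NIfTI-1, default identity affine."""
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(np.asarray(volume.accuracy, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


RESULT_COLUMNS = [
    "subject",
    "modality",
    "target",
    "clutter",
    "index",
    "accuracy",
    "n_cells",
    "seed",
]


def results_to_tsv(frame: pd.DataFrame, path) -> None:
    """Write a tidy result table as TSV with a stable float format."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
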