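"""Readers and writers for the on-disk study layout.

Volumes travel as NIfTI-1 (TR recorded in the header zooms), events as
tab-separated tables, behavior as CSV, trial patterns as a 4-D NIfTI (one
volume per trial) with a labels sidecar CSV, and ground truth as a JSON
sidecar.  Uncompressed ``.nii`` is the default so repeated writes are
byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import BoldRun, TrialPatterns, validate_events
from .volumes import MaskVolume

__all__ = [
    "write_bold", "read_bold",
    "write_mask", "read_mask",
    "write_events", "read_events",
    "write_behavior", "read_behavior",
    "write_patterns", "read_patterns",
    "write_truth", "read_truth",
]


def _nifti(data: np.ndarray, affine: np.ndarray) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_data_dtype(np.float32 if data.dtype.kind == "f" else np.int16)
    return img


def write_bold(bold: BoldRun, path: str | Path, mask_path: str | Path | None = None) -> None:
    img = _nifti(bold.data.astype(np.float32), bold.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = bold.tr_s
    img.header.set_zooms(zooms)
    img.header["pixdim"][4] = bold.tr_s
    nib.save(img, str(path))
    if mask_path is not None:
        write_mask(MaskVolume(bold.brain_mask, bold.affine, "brain"), mask_path)


def read_bold(path: str | Path, mask_path: str | Path) -> BoldRun:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    tr = float(img.header.get_zooms()[3])
    mask = read_mask(mask_path)
    return BoldRun(data, tr, mask.data, affine=np.asarray(img.affine))


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    nib.save(_nifti(mask.data.astype(np.int16), mask.affine), str(path))


def read_mask(path: str | Path, name: str | None = None) -> MaskVolume:
    img = nib.load(str(path))
    return MaskVolume(np.asanyarray(img.dataobj) > 0, np.asarray(img.affine),
                      name or Path(path).stem.replace(".nii", ""))


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events).to_csv(path, sep="\t", index=False,
                                   float_format="%.6f")


def read_events(path: str | Path) -> pd.DataFrame:
    return validate_events(pd.read_csv(path, sep="\t"))


def write_behavior(behavior: pd.DataFrame, path: str | Path) -> None:
    behavior.to_csv(path, index=False, float_format="%.6f")


def read_behavior(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_patterns(patterns: TrialPatterns, nifti_path: str | Path,
                   labels_path: str | Path) -> None:
    """4-D NIfTI (one volume per trial; 0 outside coverage) + labels CSV."""
    vols = patterns.to_volumes().astype(np.float32)
    # mark covered voxels so reading can reconstruct the coverage mask
    cover = np.zeros(patterns.grid_shape, dtype=bool)
    cover[tuple(patterns.voxel_coords.T)] = True
    nib.save(_nifti(vols, patterns.affine), str(nifti_path))
    labels = patterns.labels.copy()
    labels.insert(0, "trial", np.arange(len(labels)))
    labels["subject_id"] = patterns.subject_id
    labels["cohort"] = patterns.cohort
    labels.to_csv(labels_path, index=False, float_format="%.6f")
    cover_path = Path(str(nifti_path)).with_suffix("").with_suffix("")
    write_mask(MaskVolume(cover, patterns.affine, "coverage"),
               str(cover_path) + "_coverage.nii")


def read_patterns(nifti_path: str | Path, labels_path: str | Path) -> TrialPatterns:
    img = nib.load(str(nifti_path))
    vols = np.asanyarray(img.dataobj).astype(float)
    cover_path = Path(str(nifti_path)).with_suffix("").with_suffix("")
    cover = read_mask(str(cover_path) + "_coverage.nii")
    labels = pd.read_csv(labels_path)
    coords = np.argwhere(cover.data)
    values = vols[cover.data].T  # (n_trials, n_voxels)
    subject_id = str(labels["subject_id"].iloc[0])
    cohort = int(labels["cohort"].iloc[0])
    keep = [c for c in labels.columns if c not in ("trial", "subject_id", "cohort")]
    return TrialPatterns(values, labels[keep], coords, vols.shape[:3],
                         subject_id=subject_id, cohort=cohort,
                         affine=np.asarray(img.affine))


def write_truth(truth, path: str | Path, mask_path: str | Path | None = None) -> None:
    """Ground-truth sidecar as structured JSON (+ signal mask NIfTI)."""
    payload = {
        "selfishness": [float(v) for v in truth.selfishness],
        "per_subject_amplitude": [float(v) for v in truth.per_subject_amplitude],
        "cohort": [int(v) for v in truth.cohort],
        "expected_gap_eur": [float(v) for v in truth.expected_gap_eur],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if mask_path is not None:
        write_mask(MaskVolume(truth.signal_voxel_mask, name="signal"), mask_path)


def read_truth(path: str | Path, mask_path: str | Path):
    from .simulate import SyntheticTruth

    payload = json.loads(Path(path).read_text())
    mask = read_mask(mask_path)
    return SyntheticTruth(
        np.asarray(payload["selfishness"], float),
        np.asarray(payload["per_subject_amplitude"], float),
        np.asarray(payload["cohort"], int),
        mask.data,
        expected_gap_eur=np.asarray(payload["expected_gap_eur"], float))
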