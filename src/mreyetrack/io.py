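"""Format plumbing: NIfTI / DICOM images, model configs, traces.

Images are returned as (data, affine) with the affine mapping index
coordinates to physical mm.  Eye models round-trip losslessly through a
human-readable YAML file carrying the 9 parameters of each ellipsoid plus
the relative cornea/lens rotations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import EyeModel

__all__ = [
    "read_nifti",
    "read_dicom_series",
    "save_eye_model",
    "load_eye_model",
    "read_eyetracker_trace",
]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI image (3D, or 2D+t) as (float array, 4×4 affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def write_nifti(path, data: np.ndarray, affine: np.ndarray):
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_dicom_series(directory) -> tuple[np.ndarray, np.ndarray]:
    """Read a single-series DICOM directory into a frame stack.

    Files are sorted by InstanceNumber; returns (frames, 4×4 affine) where
    the affine encodes in-plane PixelSpacing on the first two axes (frame
    index is the third).
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    dsets = sorted(
        (pydicom.dcmread(str(f)) for f in files),
        key=lambda d: int(getattr(d, "InstanceNumber", 0)),
    )
    frames = np.stack([d.pixel_array.astype(float) for d in dsets])
    sp = [float(x) for x in getattr(dsets[0], "PixelSpacing", [1.0, 1.0])]
    affine = np.diag([sp[0], sp[1], 1.0, 1.0])
    return frames, affine


def save_eye_model(model: EyeModel, path):
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def load_eye_model(path) -> EyeModel:
    with open(path) as fh:
        return EyeModel.from_dict(yaml.safe_load(fh))


def read_eyetracker_trace(path) -> pd.DataFrame:
    """External video-eye-tracker trace CSV: time_ms, gaze_deg[, pupil]."""
    df = pd.read_csv(path)
    required = {"time_ms", "gaze_deg"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace must contain columns {sorted(required)}")
    return df
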