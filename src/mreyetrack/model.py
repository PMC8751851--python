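"""Model/Results interface for the two fitting problems.

`EyeSegmentation` fits the three-ellipsoid eye model to a static 3D volume;
`SliceMotion` fits per-frame rigid motion to a dynamic 2D slice sequence.
Both follow the familiar model-object pattern: construct from data, call
``fit()``, receive a results object carrying estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import EyeModel
from .kinematics import Trajectory, detect_blinks, fit_saccade
from .ngm import FitResult, MotionState, NGMConfig, segment_3d, track_sequence
from .plane_intersection import Plane, PlaneFrame, project_model
from .preprocessing import detect_eye_center
from .synthetic_data import default_eye_model

__all__ = ["EyeSegmentation", "EyeSegmentationResults", "SliceMotion",
           "SliceMotionResults"]


class EyeSegmentation:
    """Three-ellipsoid eye-model segmentation of a static 3D MR volume.

    Parameters
    ----------
    volume : 3D array of T2-weighted intensities (bright vitreous).
    affine : 4×4 index-to-mm affine.
    config : optional :class:`~mreyetrack.ngm.NGMConfig`.
    """

    def __init__(self, volume: np.ndarray, affine: np.ndarray,
                 config: NGMConfig | None = None):
        self.volume = np.asarray(volume, dtype=float)
        self.affine = np.asarray(affine, dtype=float)
        self.config = config or NGMConfig()

    @classmethod
    def from_nifti(cls, path, config: NGMConfig | None = None):
        from .io import read_nifti

        data, affine = read_nifti(path)
        return cls(data, affine, config)

    def fit(self, init: EyeModel | None = None) -> "EyeSegmentationResults":
        """Run the two-stage NGM fit; the starting model defaults to a
        population-mean eye centered on the radial-symmetry peak."""
        if init is None:
            center = detect_eye_center(self.volume, affine=self.affine)[0]
            init = default_eye_model(center)
        res = segment_3d(self.volume, self.affine, init, self.config)
        return EyeSegmentationResults(self, res)


@dataclass
class EyeSegmentationResults:
    model: EyeSegmentation
    fit_result: FitResult

    @property
    def eye_model(self) -> EyeModel:
        return self.fit_result.params

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def params(self) -> pd.Series:
        m = self.eye_model
        rows = {}
        for name, e in (("sclera", m.sclera), ("cornea", m.cornea),
                        ("lens", m.lens)):
            for k, ax in enumerate("xyz"):
                rows[f"{name}_center_{ax}_mm"] = e.center[k]
                rows[f"{name}_semi_{ax}_mm"] = e.semi_axes[k]
                rows[f"{name}_theta_{ax}_deg"] = e.rotation_angles[k]
        rows["eyeball_diameter_mm"] = m.diameter
        return pd.Series(rows)

    def summary(self) -> str:
        m = self.eye_model
        lines = [
            "NGM 3D eye segmentation",
            "=" * 55,
            f"final energy    {self.fit_result.final_energy: .6f}",
            f"evaluations     {self.fit_result.n_evaluations}",
            f"converged       {self.converged}",
            f"eyeball diameter (2·mean sclera semi-axis)  "
            f"{m.diameter:6.2f} mm",
            "-" * 55,
            f"{'structure':8s} {'center (mm)':>24s} {'semi-axes (mm)':>20s}",
        ]
        for name, e in (("sclera", m.sclera), ("cornea", m.cornea),
                        ("lens", m.lens)):
            c = "({: 6.2f},{: 6.2f},{: 6.2f})".format(*e.center)
            s = "({:5.2f},{:5.2f},{:5.2f})".format(*e.semi_axes)
            lines.append(f"{name:8s} {c:>24s} {s:>20s}")
        return "\n".join(lines)

    def save(self, path):
        from .io import save_eye_model

        save_eye_model(self.eye_model, path)

    def overlay_curves(self, plane: Plane):
        """Projected boundary polylines for plotting on a slice."""
        return project_model(self.eye_model, plane)


class SliceMotion:
    """Per-frame rigid eye-motion estimation from a single-slice sequence.

    Parameters
    ----------
    frames : (T, H, W) intensity stack.
    affine2d : 3×3 pixel-index → in-plane mm affine.
    plane : imaging :class:`~mreyetrack.plane_intersection.Plane`.
    eye_model : anatomy fitted previously from 3D data.
    frame_interval_ms : temporal resolution of the sequence.
    """

    def __init__(self, frames, affine2d, plane: Plane, eye_model: EyeModel,
                 frame_interval_ms: float = 37.8,
                 config: NGMConfig | None = None):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        self.frames = frames
        self.affine2d = np.asarray(affine2d, dtype=float)
        self.plane = plane
        self.eye_model = eye_model
        self.frame_interval_ms = float(frame_interval_ms)
        self.config = config or NGMConfig()

    def fit(self, init: MotionState | None = None,
            rotation_scan_first: np.ndarray | None = None) -> "SliceMotionResults":
        traj = track_sequence(
            self.frames, self.affine2d, self.plane, self.eye_model,
            init=init, config=self.config,
            frame_interval_ms=self.frame_interval_ms,
            rotation_scan_first=rotation_scan_first,
        )
        return SliceMotionResults(self, traj)


@dataclass
class SliceMotionResults:
    model: SliceMotion
    trajectory: Trajectory

    @property
    def converged_fraction(self) -> float:
        return float(self.trajectory.data["converged"].mean())

    def detect_blinks(self, **kw):
        return detect_blinks(self.trajectory, **kw)

    def fit_saccade(self, **kw):
        return fit_saccade(self.trajectory, **kw)

    def summary(self) -> str:
        d = self.trajectory.data
        lines = [
            "NGM slice-sequence motion tracking",
            "=" * 55,
            f"frames          {len(d)}",
            f"time span       {d['time_ms'].iloc[-1]:.1f} ms",
            f"converged       {100 * self.converged_fraction:.1f}% of frames",
            "-" * 55,
            "              min      max       sd",
        ]
        for col, label in (("ty", "retraction ty (mm)"), ("tz", "lift tz (mm)"),
                           ("rot_z_deg", "horiz rot (deg)"),
                           ("rot_x_deg", "vert rot (deg)")):
            v = d[col]
            lines.append(
                f"{label:20s}{v.min(): 8.3f} {v.max(): 8.3f} {v.std(ddof=0): 8.3f}"
            )
        return "\n".join(lines)

    def to_csv(self, path):
        self.trajectory.to_csv(path)
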