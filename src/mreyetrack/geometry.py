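"""Ellipsoid geometry and the three-ellipsoid eye model.

The eye is modelled by three general ellipsoids — sclera, cornea and the
inner part of the lens — each an affine image of the unit sphere

    x = x0 + R S (cos a cos b, sin a cos b, sin b)^T

with center ``x0``, rotation ``R = Rx(tx) Rz(tz) Ry(ty)`` and diagonal
scaling ``S = diag(rx, ry, rz)``.  Coordinates are right-handed patient
coordinates in millimetres (x = left-right, y = anterior-posterior,
z = inferior-superior); ``-e_y`` is the anterior direction, so the cornea
sits on the ``-y`` side of the eyeball center.

The cornea center is constrained to a 7 mm distance from the eyeball
(sclera) center, and the lens center is constrained to lie on the sclera
surface; both are parameterized by a rotation away from ``-e_y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "Ellipsoid",
    "EyeModel",
    "SurfaceSample",
    "rotation_matrix",
    "rotation_angles_from_matrix",
    "surface_point",
    "is_inside",
    "build_eye_model",
    "fibonacci_grid",
    "outer_border_sample",
]

# Distance from eyeball center to cornea center, mm (anatomical constraint).
CORNEA_CENTER_DISTANCE = 7.0

_EY = np.array([0.0, 1.0, 0.0])


def _rx(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_matrix(angles_deg) -> np.ndarray:
    """Rotation ``R = Rx(tx) · Rz(tz) · Ry(ty)`` from angles in degrees."""
    tx, ty, tz = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return _rx(tx) @ _rz(tz) @ _ry(ty)


def rotation_angles_from_matrix(R: np.ndarray) -> np.ndarray:
    """Invert :func:`rotation_matrix`: angles (tx, ty, tz) in degrees.

    Uses R[0,1] = -sin(tz); near gimbal lock (|cos tz| ~ 0) the x/y split is
    degenerate and ty is set to 0.
    """
    R = np.asarray(R, dtype=float)
    stz = -R[0, 1]
    stz = np.clip(stz, -1.0, 1.0)
    tz = np.arcsin(stz)
    if abs(np.cos(tz)) < 1e-9:  # pragma: no cover - pathological pose
        tx = np.arctan2(R[2, 0], R[2, 2])
        ty = 0.0
    else:
        tx = np.arctan2(R[2, 1], R[1, 1])
        ty = np.arctan2(R[0, 2], R[0, 0])
    return np.rad2deg(np.array([tx, ty, tz]))


@dataclass(frozen=True)
class Ellipsoid:
    """General ellipsoid: center (mm), rotation angles (deg), semi-axes (mm)."""

    center: np.ndarray
    rotation_angles: np.ndarray
    semi_axes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(
            self, "rotation_angles", np.asarray(self.rotation_angles, dtype=float)
        )
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, dtype=float))
        if self.center.shape != (3,) or self.semi_axes.shape != (3,):
            raise ValueError("center and semi_axes must be 3-vectors")
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi_axes must all be positive")
        object.__setattr__(self, "_R", rotation_matrix(self.rotation_angles))

    @property
    def R(self) -> np.ndarray:
        return self._R

    @classmethod
    def from_rotation_matrix(cls, center, R, semi_axes) -> "Ellipsoid":
        return cls(center, rotation_angles_from_matrix(R), semi_axes)

    # ---- implicit form ---------------------------------------------------
    def implicit_norm(self, x) -> np.ndarray:
        """``‖S⁻¹ Rᵀ (x − x0)‖`` — 1 on the surface, < 1 inside."""
        x = np.asarray(x, dtype=float)
        y = (x - self.center) @ self.R / self.semi_axes
        return np.linalg.norm(y, axis=-1)

    def contains(self, x) -> np.ndarray:
        """Strict interior test: implicit norm < 1 (surface points excluded)."""
        return self.implicit_norm(x) < 1.0

    def normal(self, x) -> np.ndarray:
        """Outward unit normal(s) from the implicit-quadric gradient.

        ∇‖S⁻¹Rᵀ(x−x0)‖² = 2 R S⁻² Rᵀ (x − x0), normalized.
        """
        x = np.asarray(x, dtype=float)
        R = self.R
        g = ((x - self.center) @ R / self.semi_axes**2) @ R.T
        return g / np.linalg.norm(g, axis=-1, keepdims=True)

    def surface_points_from_unit(self, u: np.ndarray) -> np.ndarray:
        """Map unit-sphere points ``u`` (N,3) onto the ellipsoid surface."""
        return self.center + (u * self.semi_axes) @ self.R.T

    def transformed(self, R=None, t=None, about=None) -> "Ellipsoid":
        """Rigidly move the ellipsoid: rotate by ``R`` about ``about`` then
        translate by ``t``."""
        c = self.center.copy()
        Rnew = self.R
        if R is not None:
            R = np.asarray(R, dtype=float)
            pivot = self.center if about is None else np.asarray(about, dtype=float)
            c = pivot + R @ (c - pivot)
            Rnew = R @ Rnew
        if t is not None:
            c = c + np.asarray(t, dtype=float)
        return Ellipsoid.from_rotation_matrix(c, Rnew, self.semi_axes)

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "rotation_angles": self.rotation_angles.tolist(),
            "semi_axes": self.semi_axes.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipsoid":
        return cls(d["center"], d["rotation_angles"], d["semi_axes"])


def surface_point(e: Ellipsoid, alpha: float, beta: float) -> np.ndarray:
    """Point on the ellipsoid surface from spherical parameters (radians)."""
    u = np.array(
        [
            np.cos(alpha) * np.cos(beta),
            np.sin(alpha) * np.cos(beta),
            np.sin(beta),
        ]
    )
    return e.center + e.R @ (e.semi_axes * u)


def is_inside(e: Ellipsoid, x) -> bool | np.ndarray:
    """Strict interior membership ``‖S⁻¹Rᵀ(x−x0)‖ < 1``."""
    return e.contains(x)


@dataclass(frozen=True)
class EyeModel:
    """Constrained triple of ellipsoids (sclera, cornea, lens).

    ``cornea_rotation`` / ``lens_rotation`` are the rotations (deg, same
    Rx·Rz·Ry composition) that carry ``-e_y`` to the cornea/lens direction
    relative to the sclera center.
    """

    sclera: Ellipsoid
    cornea: Ellipsoid
    lens: Ellipsoid
    cornea_rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    lens_rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(
            self, "cornea_rotation", np.asarray(self.cornea_rotation, dtype=float)
        )
        object.__setattr__(
            self, "lens_rotation", np.asarray(self.lens_rotation, dtype=float)
        )

    @property
    def center(self) -> np.ndarray:
        """Eyeball center = sclera center."""
        return self.sclera.center

    @property
    def diameter(self) -> float:
        """Eyeball diameter, defined as twice the mean sclera semi-axis."""
        return 2.0 * float(np.mean(self.sclera.semi_axes))

    def posed(self, rotation=None, translation=None) -> "EyeModel":
        """Rigid motion of the whole model about the eyeball center."""
        about = self.sclera.center
        return EyeModel(
            self.sclera.transformed(rotation, translation, about),
            self.cornea.transformed(rotation, translation, about),
            self.lens.transformed(rotation, translation, about),
            self.cornea_rotation,
            self.lens_rotation,
        )

    def to_dict(self) -> dict:
        return {
            "sclera": self.sclera.to_dict(),
            "cornea": self.cornea.to_dict(),
            "lens": self.lens.to_dict(),
            "cornea_rotation": self.cornea_rotation.tolist(),
            "lens_rotation": self.lens_rotation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EyeModel":
        return cls(
            Ellipsoid.from_dict(d["sclera"]),
            Ellipsoid.from_dict(d["cornea"]),
            Ellipsoid.from_dict(d["lens"]),
            np.asarray(d.get("cornea_rotation", [0, 0, 0]), dtype=float),
            np.asarray(d.get("lens_rotation", [0, 0, 0]), dtype=float),
        )


def build_eye_model(
    sclera: Ellipsoid,
    cornea_semi_axes,
    cornea_rotation,
    lens_semi_axes,
    lens_rotation,
) -> EyeModel:
    """Assemble the constrained eye model.

    Cornea center: ``x0_sclera − 7 · R_cornea · e_y``.
    Lens center: ``x0_sclera − R_lens·e_y / ‖S_sclera⁻¹ R_scleraᵀ R_lens·e_y‖``
    (on the sclera surface).  Ellipsoid orientations are the sclera-frame
    rotations composed with the structure's own relative rotation.
    """
    cornea_semi_axes = np.asarray(cornea_semi_axes, dtype=float)
    lens_semi_axes = np.asarray(lens_semi_axes, dtype=float)
    if np.any(cornea_semi_axes <= 0) or np.any(lens_semi_axes <= 0):
        raise ValueError("semi_axes must all be positive")
    Rc = rotation_matrix(cornea_rotation)
    Rl = rotation_matrix(lens_rotation)
    x0 = sclera.center

    cornea_center = x0 - CORNEA_CENTER_DISTANCE * (Rc @ _EY)
    cornea = Ellipsoid.from_rotation_matrix(cornea_center, Rc, cornea_semi_axes)

    d = Rl @ _EY
    denom = np.linalg.norm((sclera.R.T @ d) / sclera.semi_axes)
    lens_center = x0 - d / denom
    lens = Ellipsoid.from_rotation_matrix(lens_center, Rl, lens_semi_axes)

    return EyeModel(sclera, cornea, lens, np.asarray(cornea_rotation, float),
                    np.asarray(lens_rotation, float))


@dataclass
class SurfaceSample:
    """Discrete surface sample: points (N,3), outward unit normals (N,3) and
    per-point structure labels."""

    points: np.ndarray
    normals: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, mask: np.ndarray) -> "SurfaceSample":
        return SurfaceSample(self.points[mask], self.normals[mask], self.labels[mask])

    @staticmethod
    def concatenate(samples) -> "SurfaceSample":
        return SurfaceSample(
            np.concatenate([s.points for s in samples]),
            np.concatenate([s.normals for s in samples]),
            np.concatenate([s.labels for s in samples]),
        )


@lru_cache(maxsize=8)
def _fibonacci_unit_sphere(n: int) -> np.ndarray:
    """Fibonacci lattice on the unit sphere, (n,3); near-equidistributed."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts.setflags(write=False)
    return pts


def fibonacci_grid(e: Ellipsoid, n_points: int = 1000, label: str = "sclera") -> SurfaceSample:
    """Near-uniform surface sample with analytic outward normals.

    The Fibonacci lattice is generated on the unit sphere and mapped through
    the ellipsoid's affine transform; since the eyeball is close to spherical
    this is a good approximation to an equal-area sample.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    u = _fibonacci_unit_sphere(int(n_points))
    pts = e.surface_points_from_unit(u)
    # gradient of the implicit form at x0 + R S u is ∝ R S⁻¹ u
    g = (u / e.semi_axes) @ e.R.T
    normals = g / np.linalg.norm(g, axis=1, keepdims=True)
    labels = np.full(len(pts), label, dtype="<U8")
    return SurfaceSample(pts, normals, labels)


def outer_border_sample(
    m: EyeModel,
    n_points: int = 1000,
    exclude_lens: bool = False,
    lens_margin: float = 1.5,
) -> SurfaceSample:
    """Sample the outer eyeball border (sclera ∪ corneal protrusion).

    Keeps sclera surface points lying outside the cornea ellipsoid and cornea
    surface points lying outside the sclera ellipsoid (strict interior test);
    labels are preserved.  With ``exclude_lens`` the patch where the lens
    (dilated by ``lens_margin`` mm, roughly the image blur scale) crosses the
    outer border is removed as well — there the border is not a
    vitreous/surround edge, and the nearby lens/vitreous edge would otherwise
    attract the fit.
    """
    sc = fibonacci_grid(m.sclera, n_points, "sclera")
    co = fibonacci_grid(m.cornea, n_points, "cornea")
    sc = sc.subset(~m.cornea.contains(sc.points))
    co = co.subset(~m.sclera.contains(co.points))
    out = SurfaceSample.concatenate([sc, co])
    if exclude_lens:
        dilated = Ellipsoid(
            m.lens.center, m.lens.rotation_angles, m.lens.semi_axes + lens_margin
        )
        out = out.subset(~dilated.contains(out.points))
    return out
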