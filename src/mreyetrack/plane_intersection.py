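"""Closed-form intersection of an imaging plane with the eye-model ellipsoids.

A plane ``x·n = d`` is pulled back through the affine transform that maps the
ellipsoid to the unit sphere; there the intersection is a circle of radius
``sqrt(1 − δ²)`` around ``δ·ñ``, which maps forward to an ellipse given
parametrically by a center and two conjugate diameters,

    x(γ) = v0 + v1 cos γ + v2 sin γ.

The conjugate diameters are generally not the principal axes; a parameter
rotation by Ψ = ½·atan2(2 v1·v2, ‖v1‖² − ‖v2‖²) orthogonalizes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Ellipsoid, EyeModel

__all__ = [
    "Plane",
    "PlaneFrame",
    "IntersectionEllipse",
    "intersect",
    "principal_axes",
    "project_model",
]

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class Plane:
    """Plane ``x · normal = distance`` (normal unit-length, distance in mm)."""

    normal: np.ndarray
    distance: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(n)
        if nrm == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / nrm)
        object.__setattr__(self, "distance", float(self.distance))


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # manual 3-vector cross product (np.cross has large call overhead)
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _anchor_basis(n: np.ndarray) -> np.ndarray:
    """Unit vector orthogonal to ``n``: normalize(e_x × n), falling back to
    e_y × n when ``n`` is (anti)parallel to e_x."""
    v = _cross3(_EX, n)
    nv = np.sqrt(v @ v)
    if nv < 1e-8:
        v = _cross3(_EY, n)
        nv = np.sqrt(v @ v)
    return v / nv


@dataclass(frozen=True)
class PlaneFrame:
    """Orthonormal in-plane coordinate frame.

    Origin at the foot of the perpendicular from the world origin; basis
    (u, v) built from the plane normal with the e_x-anchor fallback rule, so
    the frame is reproducible across frames of one sequence.
    """

    plane: Plane
    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @classmethod
    def from_plane(cls, plane: Plane) -> "PlaneFrame":
        n = plane.normal
        u = _anchor_basis(n)
        v = _cross3(n, u)
        return cls(plane, plane.distance * n, u, v)

    def to_2d(self, x: np.ndarray) -> np.ndarray:
        """World points (…,3) → in-plane coordinates (…,2), mm."""
        rel = np.asarray(x, dtype=float) - self.origin
        return np.stack([rel @ self.u, rel @ self.v], axis=-1)

    def to_world(self, p2: np.ndarray) -> np.ndarray:
        p2 = np.asarray(p2, dtype=float)
        return self.origin + p2[..., :1] * self.u + p2[..., 1:2] * self.v


@dataclass(frozen=True)
class IntersectionEllipse:
    """Parametric ellipse ``x(γ) = center + d1 cos γ + d2 sin γ`` from a
    plane–ellipsoid intersection; ``d1, d2`` are conjugate diameters."""

    center: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    axis_angle: float
    parent_label: str = ""

    def points(self, gamma: np.ndarray) -> np.ndarray:
        g = np.asarray(gamma, dtype=float)[..., None]
        return self.center + self.d1 * np.cos(g) + self.d2 * np.sin(g)

    def tangents(self, gamma: np.ndarray) -> np.ndarray:
        g = np.asarray(gamma, dtype=float)[..., None]
        return -self.d1 * np.sin(g) + self.d2 * np.cos(g)

    @property
    def area(self) -> float:
        """Ellipse area ``π ‖d1 × d2‖`` (valid for conjugate diameters)."""
        c = _cross3(self.d1, self.d2)
        return float(np.pi * np.sqrt(c @ c))


def intersect(e: Ellipsoid, p: Plane, label: str = "") -> IntersectionEllipse | None:
    """Intersection ellipse, or ``None`` if the plane misses (or is tangent
    to) the ellipsoid."""
    R, S = e.R, e.semi_axes
    srt_n = S * (R.T @ p.normal)  # S Rᵀ n
    scale = np.linalg.norm(srt_n)
    n_t = srt_n / scale
    delta = (p.distance - e.center @ p.normal) / scale
    if abs(delta) >= 1.0 - 1e-12:
        return None
    rad = np.sqrt(1.0 - delta * delta)
    v1_t = rad * _anchor_basis(n_t)
    v2_t = _cross3(v1_t, n_t)
    v2_t *= rad / np.sqrt(v2_t @ v2_t)
    RS = R * S  # columns scaled: R @ diag(S)
    center = e.center + delta * (RS @ n_t)
    d1 = RS @ v1_t
    d2 = RS @ v2_t
    psi = 0.5 * np.arctan2(2.0 * d1 @ d2, d1 @ d1 - d2 @ d2)
    return IntersectionEllipse(center, d1, d2, float(psi), label)


def principal_axes(ie: IntersectionEllipse):
    """Orthogonal semi-axis vectors and lengths (descending).

    Rotating the conjugate-diameter pair by the ellipse's axis angle yields
    orthogonal diameters; returns (major_vec, minor_vec, lengths).
    """
    c, s = np.cos(ie.axis_angle), np.sin(ie.axis_angle)
    a1 = c * ie.d1 + s * ie.d2
    a2 = -s * ie.d1 + c * ie.d2
    l1, l2 = np.linalg.norm(a1), np.linalg.norm(a2)
    if l1 >= l2:
        return a1, a2, np.array([l1, l2])
    return a2, a1, np.array([l2, l1])


@dataclass(frozen=True)
class ProjectedCurve:
    """One structure's boundary in a slice: in-plane polyline with in-plane
    outward unit normals."""

    label: str
    gamma: np.ndarray
    points2d: np.ndarray
    normals2d: np.ndarray
    points3d: np.ndarray


def _curve_from_ellipse(
    ie: IntersectionEllipse, frame: PlaneFrame, n_steps: int
) -> ProjectedCurve:
    gamma = np.linspace(0.0, 2.0 * np.pi, n_steps, endpoint=False)
    pts3 = ie.points(gamma)
    pts2 = frame.to_2d(pts3)
    tan2 = np.stack(
        [ie.tangents(gamma) @ frame.u, ie.tangents(gamma) @ frame.v], axis=-1
    )
    nrm2 = np.stack([tan2[:, 1], -tan2[:, 0]], axis=-1)
    nrm2 /= np.linalg.norm(nrm2, axis=1, keepdims=True)
    # orient outward (away from the ellipse center); orientation is uniform
    # along a convex curve so the mean sign is reliable
    c2 = frame.to_2d(ie.center)
    if np.mean(np.sum(nrm2 * (pts2 - c2), axis=1)) < 0:
        nrm2 = -nrm2
    return ProjectedCurve(ie.parent_label, gamma, pts2, nrm2, pts3)


def _clip_curve(curve: ProjectedCurve, keep: np.ndarray) -> ProjectedCurve:
    return ProjectedCurve(
        curve.label,
        curve.gamma[keep],
        curve.points2d[keep],
        curve.normals2d[keep],
        curve.points3d[keep],
    )


def project_model(
    m: EyeModel,
    p: Plane,
    frame: PlaneFrame | None = None,
    n_steps: int = 360,
    lens_exclusion_margin: float | None = None,
) -> list[ProjectedCurve]:
    """Project the eye model onto a slice plane.

    Returns the per-structure intersection curves in in-plane coordinates.
    The sclera and cornea curves are clipped to the outer eyeball border:
    arc points of one ellipse lying strictly inside the other ellipsoid are
    dropped.  With ``lens_exclusion_margin`` (mm), sclera/cornea arc points
    inside the lens dilated by that margin are dropped too — where the lens
    crosses the outer border the edge carries no vitreous/surround
    contrast.  The lens curve is kept whole.  Empty list if the plane
    misses the sclera.
    """
    if frame is None:
        frame = PlaneFrame.from_plane(p)
    sc = intersect(m.sclera, p, "sclera")
    if sc is None:
        return []
    curves: list[ProjectedCurve] = []
    co = intersect(m.cornea, p, "cornea")
    dilated = None
    if lens_exclusion_margin is not None:
        from .geometry import Ellipsoid

        dilated = Ellipsoid(
            m.lens.center,
            m.lens.rotation_angles,
            m.lens.semi_axes + lens_exclusion_margin,
        )
    sc_curve = _curve_from_ellipse(sc, frame, n_steps)
    keep = np.ones(len(sc_curve.points3d), dtype=bool)
    if co is not None:
        keep &= ~m.cornea.contains(sc_curve.points3d)
    if dilated is not None:
        keep &= ~dilated.contains(sc_curve.points3d)
    sc_curve = _clip_curve(sc_curve, keep)
    if len(sc_curve.points2d):
        curves.append(sc_curve)
    if co is not None:
        co_curve = _curve_from_ellipse(co, frame, n_steps)
        keep = ~m.sclera.contains(co_curve.points3d)
        if dilated is not None:
            keep &= ~dilated.contains(co_curve.points3d)
        co_curve = _clip_curve(co_curve, keep)
        if len(co_curve.points2d):
            curves.append(co_curve)
    le = intersect(m.lens, p, "lens")
    if le is not None:
        curves.append(_curve_from_ellipse(le, frame, n_steps))
    return curves


def curves_to_table(curves: list[ProjectedCurve]):
    """Flatten projected curves to a (label, gamma, x, y) table for CSV
    export / overlay plotting."""
    import pandas as pd

    rows = []
    for c in curves:
        for g, (x, y) in zip(c.gamma, c.points2d):
            rows.append((c.label, g, x, y))
    return pd.DataFrame(rows, columns=["label", "gamma", "x", "y"])
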