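"""Normal Gradient Matching (NGM): energy, optimizer and fitting drivers.

NGM scores a candidate surface by the mean inner product of the model's
outward unit normals with the image intensity gradients,

    E = (1/|Ω|) Σ_Ω n · g,

normalized to the surface sample size so larger ellipsoids are not favored.
On T2 / bSSFP contrast the vitreous is bright and the surround dark, so the
gradient at the outer eyeball border points inward and E is negative when
the model sits on the border; fitting minimizes E.  The dark lens nucleus
has the opposite edge polarity, so the lens term enters with sign −1.

3D anatomy is segmented in two stages (sclera+cornea over the outer border,
then lens); per-frame 2D motion is estimated by matching the projected
ellipse arcs to the slice gradients.  Optimization uses a generalized
pattern search (derivative-free coordinate polling with mesh expansion /
contraction), mirroring the original method's optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .geometry import (
    Ellipsoid,
    EyeModel,
    SurfaceSample,
    build_eye_model,
    fibonacci_grid,
    outer_border_sample,
    rotation_matrix,
)
from .plane_intersection import Plane, PlaneFrame, project_model

__all__ = [
    "GradientField",
    "MotionState",
    "FitResult",
    "NGMConfig",
    "energy",
    "pattern_search",
    "segment_3d",
    "estimate_motion",
    "track_sequence",
]

DEFAULT_POLARITY = {"sclera": 1.0, "cornea": 1.0, "lens": -1.0}

# Out-of-plane motion constraints for single-slice tracking.
OUT_OF_PLANE_TRANSLATION_MM = 1.0
OUT_OF_PLANE_ROTATION_DEG = 5.0
IN_PLANE_ROTATION_BOUND_DEG = 35.0


class GradientField:
    """Continuously sampled intensity gradient of a 2D or 3D image.

    Gradients are Gaussian-derivative filtered at ``sigma`` (in index units)
    and sampled off-grid by linear interpolation; points outside the image
    extent return a zero gradient.  ``affine`` maps index coordinates to
    physical coordinates (mm); gradients are returned per-mm in physical
    axes.
    """

    def __init__(self, image: np.ndarray, affine: np.ndarray, sigma: float = 1.0):
        image = np.asarray(image, dtype=float)
        self.ndim = image.ndim
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (self.ndim + 1, self.ndim + 1):
            raise ValueError("affine must be (ndim+1) square")
        self.affine = affine
        self._M = affine[: self.ndim, : self.ndim]
        self._Minv = np.linalg.inv(self._M)
        self._t = affine[: self.ndim, self.ndim]
        self.sigma = float(sigma)
        self._grads = []
        for k in range(self.ndim):
            order = [0] * self.ndim
            order[k] = 1
            if sigma > 0:
                gk = ndimage.gaussian_filter(image, sigma, order=order)
            else:
                gk = np.gradient(image, axis=k)
            self._grads.append(gk)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Gradient vectors (per mm, physical axes) at physical points (N,d)."""
        pts = np.asarray(points, dtype=float)
        idx = (pts - self._t) @ self._Minv.T
        coords = idx.T
        g_idx = np.empty_like(pts)
        for k in range(self.ndim):
            g_idx[:, k] = ndimage.map_coordinates(
                self._grads[k], coords, order=1, mode="constant", cval=0.0,
                prefilter=False,
            )
        # chain rule: grad_phys = Minv^T grad_idx
        return g_idx @ self._Minv


@dataclass(frozen=True)
class MotionState:
    """Per-frame rigid eyeball motion: 3-axis translation (mm, world) and
    two rotation angles (deg) about the left-right (x) and
    inferior-superior (z) axes.  Torsion (about the anterior axis) is fixed
    at zero — it is out-of-plane for both imaged planes and not estimable
    from single-slice data."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rot_x: float = 0.0
    rot_z: float = 0.0
    torsion: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix([self.rot_x, self.torsion, self.rot_z])

    def apply(self, model: EyeModel) -> EyeModel:
        """Pose the eye model (rotation about the eyeball center, then
        translation)."""
        return model.posed(self.rotation, self.translation)


@dataclass
class FitResult:
    """Outcome of an NGM fit: optimal parameters, energy and bookkeeping."""

    params: object
    x: np.ndarray
    final_energy: float
    n_evaluations: int
    converged: bool
    n_accepted: int = 0


@dataclass
class NGMConfig:
    """Tunables of the NGM pipeline (units: mm / degrees / voxels)."""

    n_surface_points: int = 2000
    n_curve_steps: int = 240
    sigma_voxels: float = 1.0
    mesh_translation: float = 1.0
    mesh_angle: float = 2.0
    tol_translation: float = 0.01
    tol_angle: float = 0.05
    budget: int = 6000
    expand: float = 2.0
    contract: float = 0.5
    optimize_cornea_semi_axes: bool = True
    cornea_spherical: bool = True
    optimize_sclera_rotation: bool = True
    clip_2d_arcs: bool = True
    exclude_lens_patch: bool = True  # 3D outer-border fit
    exclude_lens_patch_2d: bool = False  # 2D arcs keep the anterior region
    lens_margin_mm: float = 1.5
    polarity: dict = field(default_factory=lambda: dict(DEFAULT_POLARITY))


def energy(sample: SurfaceSample, f: GradientField, polarity: dict | None = None) -> float:
    """NGM energy of a surface sample against a gradient field.

    Each structure label contributes the mean of n·g over its own points
    (E = E_sclera + E_cornea [+ E_lens]); points outside the image extent
    contribute zero but still count toward the normalization.
    """
    if len(sample) == 0:
        raise ValueError("empty surface sample (degenerate geometry)")
    if polarity is None:
        polarity = DEFAULT_POLARITY
    g = f.sample(sample.points)
    dots = np.einsum("ij,ij->i", sample.normals, g)
    total = 0.0
    for lab in np.unique(sample.labels):
        mask = sample.labels == lab
        total += polarity.get(lab, 1.0) * float(np.mean(dots[mask]))
    return total


def pattern_search(
    objective: Callable[[np.ndarray], float],
    x0: Sequence[float],
    scales: Sequence[float],
    tols: Sequence[float],
    bounds: Sequence[tuple[float, float]] | None = None,
    budget: int = 5000,
    expand: float = 2.0,
    contract: float = 0.5,
    max_mesh: float = 4.0,
    extra_directions: Sequence[np.ndarray] | None = None,
) -> FitResult:
    """Generalized pattern search with coordinate polling.

    Polls ±mesh·scale along each coordinate (opportunistic: restarts the
    poll on the first improvement), doubles the mesh after a successful
    poll and halves it after a full unsuccessful one.  Terminates when the
    mesh resolves every parameter below its tolerance, or on budget
    exhaustion.  Candidates are clamped to ``bounds``.  ``extra_directions``
    (vectors in natural parameter units, scaled by the mesh) extend the
    poll set beyond the coordinate basis — used for known compensation
    valleys.  After a successful sweep a Hooke-Jeeves pattern move follows
    the accumulated direction.  Fully deterministic.
    """
    x = np.asarray(x0, dtype=float).copy()
    scales = np.asarray(scales, dtype=float)
    tols = np.asarray(tols, dtype=float)
    if bounds is not None:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        x = np.clip(x, lo, hi)
    f = float(objective(x))
    if not np.isfinite(f):
        raise ValueError("objective not finite at starting point")
    nev = 1
    n_acc = 0
    mesh = 1.0
    # converged when mesh * scale_i < tol_i for every i
    stop_mesh = float(np.min(tols / scales))
    converged = False
    anchor = x.copy()  # position before the current run of successes
    while nev < budget:
        if mesh < stop_mesh:
            converged = True
            break
        improved = False
        directions = [
            sgn * np.eye(len(x))[i] * scales[i]
            for i in range(len(x))
            for sgn in (1.0, -1.0)
        ]
        if extra_directions is not None:
            directions += [
                sgn * np.asarray(d, dtype=float)
                for d in extra_directions
                for sgn in (1.0, -1.0)
            ]
        for d in directions:
            cand = x + mesh * d
            if bounds is not None:
                cand = np.clip(cand, lo, hi)
            if np.array_equal(cand, x):
                continue
            fc = float(objective(cand))
            nev += 1
            if fc < f:
                x, f = cand, fc
                n_acc += 1
                improved = True
                break
            if nev >= budget:
                break
        if improved:
            mesh = min(mesh * expand, max_mesh)
            # pattern move (Hooke-Jeeves): follow the accumulated direction
            # of recent successes, doubling while it keeps improving --
            # coordinate polls alone crawl along oblique valleys
            step = x - anchor
            while nev < budget and np.any(step != 0):
                cand = x + step
                if bounds is not None:
                    cand = np.clip(cand, lo, hi)
                if np.array_equal(cand, x):
                    break
                fc = float(objective(cand))
                nev += 1
                if fc < f:
                    x, f = cand, fc
                    n_acc += 1
                    step = step * 2.0
                else:
                    break
        else:
            mesh *= contract
            anchor = x.copy()
    if mesh < stop_mesh:
        converged = True
    return FitResult(None, x, f, nev, converged, n_acc)


# ---------------------------------------------------------------------------
# 3D anatomy segmentation
# ---------------------------------------------------------------------------

def _stage1_model(x: np.ndarray, cfg: NGMConfig, lens_semi, lens_rot) -> EyeModel:
    sclera = Ellipsoid(x[0:3], x[3:6], x[6:9])
    cornea_rot = (x[9], 0.0, x[10])
    csemi = (x[11], x[11], x[11]) if cfg.cornea_spherical else x[11:14]
    return build_eye_model(sclera, csemi, cornea_rot, lens_semi, lens_rot)


def segment_3d(
    volume: np.ndarray,
    affine: np.ndarray,
    init: EyeModel,
    config: NGMConfig | None = None,
) -> FitResult:
    """Two-stage NGM segmentation of the 3D eye anatomy.

    Stage 1 minimizes E_sclera + E_cornea over the outer-border sample,
    optimizing the sclera's 9 parameters plus the cornea's relative rotation
    (2) and semi-axes (3, optional).  Stage 2 freezes these and minimizes
    E_lens over the lens rotation (2) and semi-axes (3).  Returns a
    :class:`FitResult` whose ``params`` is the fitted :class:`EyeModel`.
    """
    cfg = config or NGMConfig()
    f3 = GradientField(volume, affine, cfg.sigma_voxels)

    lens_semi0 = init.lens.semi_axes.copy()
    lens_rot0 = init.lens_rotation.copy()

    mt, ma = cfg.mesh_translation, cfg.mesh_angle
    tt, ta = cfg.tol_translation, cfg.tol_angle
    c0 = init.sclera.center

    def obj1(x: np.ndarray) -> float:
        model = _stage1_model(x, cfg, lens_semi0, lens_rot0)
        sample = outer_border_sample(
            model, cfg.n_surface_points,
            exclude_lens=cfg.exclude_lens_patch, lens_margin=cfg.lens_margin_mm,
        )
        return energy(sample, f3, cfg.polarity)

    # Coarse-to-fine schedule for robustness of the 14-parameter fit.
    # Single-coordinate polling handles the strongly coupled directions
    # (global scale; center vs. cornea orientation) poorly, so those are
    # polled jointly in dedicated phases:
    #   A  center + global scale (near-spherical globe)
    #   A2 cornea orientation
    #   B  center + sclera semi-axes (bounded near the fitted scale so the
    #      sclera cannot absorb the corneal bulge)
    #   C  all 14 parameters
    #   D  center + cornea orientation jointly (traverses their valley)
    #   C' final polish of all parameters
    x = np.concatenate(
        [
            init.sclera.center,
            init.sclera.rotation_angles,
            init.sclera.semi_axes,
            [init.cornea_rotation[0], init.cornea_rotation[2]],
            init.cornea.semi_axes,
        ]
    )
    semi_init = init.sclera.semi_axes.copy()
    csemi_init = init.cornea.semi_axes.copy()

    def obj_a(p: np.ndarray) -> float:
        xa = x.copy()
        xa[0:3] = p[0:3]
        xa[6:9] = semi_init * p[3]
        xa[11:14] = csemi_init * p[3]
        return obj1(xa)

    res_a = pattern_search(
        obj_a, np.array([*c0, 1.0]),
        np.array([mt, mt, mt, 0.05]), np.array([tt, tt, tt, 0.002]),
        [(c0[k] - 8.0, c0[k] + 8.0) for k in range(3)] + [(0.7, 1.3)],
        budget=min(800, cfg.budget // 4),
        expand=cfg.expand, contract=cfg.contract,
    )
    x[0:3] = res_a.x[0:3]
    x[6:9] = semi_init * res_a.x[3]
    x[11:14] = csemi_init * res_a.x[3]
    used = res_a.n_evaluations

    # semi-axes stay within the plausible asphericity band around the
    # fitted global scale (sclera ±1.2 mm, cornea ±1.2 mm): the sclera
    # cannot absorb the corneal bulge and the cornea cannot collapse
    semi_lo = np.maximum(x[6:9] - 1.2, 8.0)
    semi_hi = np.minimum(x[6:9] + 1.2, 16.0)
    csemi_lo = np.maximum(x[11:14] - 1.2, 3.0)
    csemi_hi = np.minimum(x[11:14] + 1.2, 10.0)
    full_bounds = (
        [(c0[k] - 8.0, c0[k] + 8.0) for k in range(3)]
        + [(-30.0, 30.0)] * 3
        + list(zip(semi_lo, semi_hi))
        + [(-30.0, 30.0)] * 2
        + list(zip(csemi_lo, csemi_hi))
    )
    if not cfg.optimize_sclera_rotation:
        full_bounds[3:6] = [(x[3 + k], x[3 + k]) for k in range(3)]
    if not cfg.optimize_cornea_semi_axes:
        full_bounds[-3:] = [(x[11 + k], x[11 + k]) for k in range(3)]
    elif cfg.cornea_spherical:
        # single corneal radius: freeze the two redundant semi-axis slots
        full_bounds[-2:] = [(x[12], x[12]), (x[13], x[13])]
    full_scales = np.array([mt] * 3 + [ma] * 3 + [mt] * 3 + [ma] * 2 + [mt] * 3)
    full_tols = np.array([tt] * 3 + [ta] * 3 + [tt] * 3 + [ta] * 2 + [tt] * 3)

    def run_phase(mask, scales_m, tols_m, budget, extra_directions=None):
        nonlocal x, used
        idx = np.asarray(mask)

        def obj_m(p: np.ndarray) -> float:
            xm = x.copy()
            xm[idx] = p
            return obj1(xm)

        res = pattern_search(
            obj_m, x[idx].copy(), scales_m, tols_m,
            [full_bounds[i] for i in idx], budget,
            expand=cfg.expand, contract=cfg.contract,
            extra_directions=extra_directions,
        )
        x = x.copy()
        x[idx] = res.x
        used += res.n_evaluations
        return res

    # coarse grid over the two cornea-orientation angles (the energy there
    # has shallow secondary minima the poll can stall in); used once at the
    # near-spherical stage and again after the full fit
    def rescan_cornea_orientation():
        nonlocal x, used

        def obj_rot(p):
            xm = x.copy()
            xm[9:11] = p
            return obj1(xm)

        grid = np.arange(-20.0, 20.1, 4.0)
        best = (obj_rot(x[9:11]), x[9:11].copy())
        used += 1
        for gx in grid:
            for gz in grid:
                f_g = obj_rot(np.array([gx, gz]))
                used += 1
                if f_g < best[0]:
                    best = (f_g, np.array([gx, gz]))
        x = x.copy()
        x[9:11] = best[1]

    rescan_cornea_orientation()
    run_phase([9, 10], np.array([4.0, 4.0]), np.array([ta, ta]),
              min(400, cfg.budget // 8))                      # A2
    run_phase([0, 1, 2, 6, 7, 8], np.array([mt] * 6), np.array([tt] * 6),
              min(1200, cfg.budget // 3))                     # B
    # refinement cycle: full fit, then a multistart over the cornea
    # orientation — the energy couples the bulge direction with center and
    # shape through a shallow valley, so the best few grid candidates each
    # get a short full refit and the lowest-energy result wins
    res1 = run_phase(list(range(14)), full_scales, full_tols,
                     max((cfg.budget - used) // 2, 500))      # C
    for _ in range(2):
        # the multistart needs room for the grid scan plus short refits
        if cfg.budget - used < 1500:
            break
        e_before = res1.final_energy

        def obj_rot2(p):
            xm = x.copy()
            xm[9:11] = p
            return obj1(xm)

        grid = np.arange(-20.0, 20.1, 4.0)
        scored = []
        for gx in grid:
            for gz in grid:
                scored.append((obj_rot2(np.array([gx, gz])), gx, gz))
                used += 1
        scored.sort()
        starts = [np.array(x[9:11])]
        for _, gx, gz in scored:
            cand = np.array([gx, gz])
            if all(np.abs(cand - s).max() > 6.0 for s in starts):
                starts.append(cand)
            if len(starts) >= 3:
                break
        best = (res1.final_energy, x.copy(), res1)
        x_base = x.copy()
        for start in starts:
            x = x_base.copy()
            x[9:11] = start
            trial = run_phase(list(range(14)), full_scales, full_tols,
                              min(900, max(cfg.budget - used, 200)))
            if trial.final_energy < best[0]:
                best = (trial.final_energy, x.copy(), trial)
        _, x, res1 = best
        if e_before - res1.final_energy < 5e-4:
            break
    # final polish so the convergence flag reflects the selected optimum
    if not res1.converged:
        res1 = run_phase(list(range(14)), full_scales, full_tols,
                         max(cfg.budget - used, 300))
    res1.x = x
    res1.n_evaluations = used
    model1 = _stage1_model(res1.x, cfg, lens_semi0, lens_rot0)

    # ---- stage 2: lens --------------------------------------------------
    y0 = np.concatenate([[lens_rot0[0], lens_rot0[2]], lens_semi0])
    scales2 = np.array([ma, ma, mt, mt, mt])
    tols2 = np.array([ta, ta, tt, tt, tt])
    bounds2 = [(-30.0, 30.0)] * 2 + [(1.0, 7.0)] * 3

    def obj2(y: np.ndarray) -> float:
        lens_rot = (y[0], 0.0, y[1])
        model = build_eye_model(
            model1.sclera,
            model1.cornea.semi_axes,
            (res1.x[9], 0.0, res1.x[10]),
            y[2:5],
            lens_rot,
        )
        sample = fibonacci_grid(model.lens, cfg.n_surface_points, "lens")
        return energy(sample, f3, cfg.polarity)

    res2 = pattern_search(
        obj2, y0, scales2, tols2, bounds2, cfg.budget, cfg.expand, cfg.contract
    )
    final = build_eye_model(
        model1.sclera,
        model1.cornea.semi_axes,
        (res1.x[9], 0.0, res1.x[10]),
        res2.x[2:5],
        (res2.x[0], 0.0, res2.x[1]),
    )
    return FitResult(
        final,
        np.concatenate([res1.x, res2.x]),
        res1.final_energy + res2.final_energy,
        res1.n_evaluations + res2.n_evaluations,
        res1.converged and res2.converged,
        res1.n_accepted + res2.n_accepted,
    )


# ---------------------------------------------------------------------------
# 2D motion estimation
# ---------------------------------------------------------------------------

def _rotation_roles(plane: Plane) -> tuple[bool, bool]:
    """(rot_x_in_plane, rot_z_in_plane): a rotation is in-plane (fully
    visible) when its axis is parallel to the slice normal."""
    n = plane.normal
    return abs(n[0]) > 0.9, abs(n[2]) > 0.9


def _curves_to_sample(curves) -> SurfaceSample:
    return SurfaceSample(
        np.concatenate([c.points2d for c in curves]),
        np.concatenate([c.normals2d for c in curves]),
        np.concatenate(
            [np.full(len(c.points2d), c.label, dtype="<U8") for c in curves]
        ),
    )


def motion_energy(
    state: MotionState,
    model: EyeModel,
    plane: Plane,
    frame: PlaneFrame,
    f2: GradientField,
    cfg: NGMConfig,
) -> float:
    """2D NGM energy E_sclera + E_cornea + E_lens of a posed model's
    projected boundary against the slice gradient field.  Returns +inf when
    the plane misses the posed sclera."""
    posed = state.apply(model)
    margin = cfg.lens_margin_mm if cfg.exclude_lens_patch_2d else None
    curves = project_model(
        posed, plane, frame, cfg.n_curve_steps, lens_exclusion_margin=margin
    )
    if not curves:
        return np.inf
    if not cfg.clip_2d_arcs:
        from .plane_intersection import intersect, _curve_from_ellipse

        curves = [
            _curve_from_ellipse(ie, frame, cfg.n_curve_steps)
            for ie in (
                intersect(posed.sclera, plane, "sclera"),
                intersect(posed.cornea, plane, "cornea"),
                intersect(posed.lens, plane, "lens"),
            )
            if ie is not None
        ]
    return energy(_curves_to_sample(curves), f2, cfg.polarity)


def estimate_motion(
    image: np.ndarray,
    image_affine2d: np.ndarray,
    plane: Plane,
    model: EyeModel,
    init: MotionState | None = None,
    config: NGMConfig | None = None,
    rotation_scan: np.ndarray | None = None,
    frame: PlaneFrame | None = None,
    field2d: GradientField | None = None,
) -> FitResult:
    """Estimate one frame's rigid eyeball motion from a single slice.

    Parameters are the in-plane translation pair, the through-plane
    translation (box-limited to ±1 mm) and the two non-torsional rotations;
    the out-of-plane rotation is box-limited to ±5°.  ``image_affine2d`` is
    the 3×3 affine mapping pixel index (row, col) to in-plane mm
    coordinates of the slice's :class:`PlaneFrame`.  ``rotation_scan``
    optionally pre-scans the in-plane rotation on a coarse grid (degrees)
    to place the start inside the correct basin.
    """
    cfg = config or NGMConfig()
    if frame is None:
        frame = PlaneFrame.from_plane(plane)
    f2 = field2d or GradientField(image, image_affine2d, cfg.sigma_voxels)
    init = init or MotionState()

    n = plane.normal
    u, v = frame.u, frame.v
    rx_in, rz_in = _rotation_roles(plane)

    def to_state(p: np.ndarray) -> MotionState:
        t = p[0] * u + p[1] * v + p[2] * n
        return MotionState(t, rot_x=p[3], rot_z=p[4])

    t0 = init.translation
    x0 = np.array([t0 @ u, t0 @ v, t0 @ n, init.rot_x, init.rot_z])
    rb_x = IN_PLANE_ROTATION_BOUND_DEG if rx_in else OUT_OF_PLANE_ROTATION_DEG
    rb_z = IN_PLANE_ROTATION_BOUND_DEG if rz_in else OUT_OF_PLANE_ROTATION_DEG
    dn = OUT_OF_PLANE_TRANSLATION_MM
    bounds = [
        (x0[0] - 8.0, x0[0] + 8.0),
        (x0[1] - 8.0, x0[1] + 8.0),
        (-dn, dn),
        (-rb_x, rb_x),
        (-rb_z, rb_z),
    ]
    x0[2] = np.clip(x0[2], -dn, dn)
    x0[3] = np.clip(x0[3], -rb_x, rb_x)
    x0[4] = np.clip(x0[4], -rb_z, rb_z)

    def obj(p: np.ndarray) -> float:
        return motion_energy(to_state(p), model, plane, frame, f2, cfg)

    n_pre = 0
    if rotation_scan is not None:
        # translation-only prefit so the rotation scan runs from a centered
        # model, then coarse scan of the in-plane rotation
        def obj_t(pt: np.ndarray) -> float:
            p = x0.copy()
            p[0:3] = pt
            return obj(p)

        res_t = pattern_search(
            obj_t, x0[0:3].copy(),
            np.array([cfg.mesh_translation] * 3),
            np.array([0.05] * 3),
            bounds[0:3], budget=min(250, cfg.budget // 4),
            expand=cfg.expand, contract=cfg.contract,
        )
        x0[0:3] = res_t.x
        n_pre += res_t.n_evaluations
        k = 3 if rx_in else 4
        best = obj(x0)
        n_pre += 1
        for ang in np.asarray(rotation_scan, dtype=float):
            cand = x0.copy()
            cand[k] = np.clip(ang, bounds[k][0], bounds[k][1])
            fc = obj(cand)
            n_pre += 1
            if fc < best:
                best, x0 = fc, cand

    scales = np.array(
        [cfg.mesh_translation] * 3 + [cfg.mesh_angle] * 2
    )
    tols = np.array([cfg.tol_translation] * 3 + [cfg.tol_angle] * 2)
    res = pattern_search(
        obj, x0, scales, tols, bounds, max(cfg.budget - n_pre, 300),
        cfg.expand, cfg.contract,
    )
    res.n_evaluations += n_pre
    if not np.isfinite(res.final_energy):
        raise ValueError("degenerate energy: plane misses the posed eyeball")
    res.params = to_state(res.x)
    return res


def track_sequence(
    frames: np.ndarray,
    image_affine2d: np.ndarray,
    plane: Plane,
    model: EyeModel,
    init: MotionState | None = None,
    config: NGMConfig | None = None,
    frame_interval_ms: float = 37.8,
    rotation_scan_first: np.ndarray | None = None,
):
    """Track a 2D sequence frame by frame, warm-starting each frame at the
    previous frame's estimate.  Per-frame failures are recorded and tracking
    continues from the last good state.  Returns a
    :class:`~mreyetrack.kinematics.Trajectory`."""
    from .kinematics import Trajectory

    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    cfg = config or NGMConfig()
    pframe = PlaneFrame.from_plane(plane)
    state = init or MotionState()
    rows = []
    for k in range(len(frames)):
        scan = rotation_scan_first if k == 0 else None
        try:
            res = estimate_motion(
                frames[k], image_affine2d, plane, model, state, cfg,
                rotation_scan=scan, frame=pframe,
            )
            state = res.params
            rows.append(
                (k, k * frame_interval_ms, *state.translation, state.rot_x,
                 state.rot_z, res.final_energy, res.converged)
            )
        except ValueError:
            rows.append(
                (k, k * frame_interval_ms, *state.translation, state.rot_x,
                 state.rot_z, np.nan, False)
            )
    import pandas as pd

    df = pd.DataFrame(
        rows,
        columns=[
            "frame", "time_ms", "tx", "ty", "tz",
            "rot_x_deg", "rot_z_deg", "energy", "converged",
        ],
    )
    return Trajectory(df)
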