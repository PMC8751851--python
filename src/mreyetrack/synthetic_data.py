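"""Synthetic MR data with known ground truth — the validation test bed.

Emulates both acquisition modes at the intensity level (no MR physics):

* static T2-like 3D volumes: 0.49 × 0.49 × 0.5 mm voxels, 1 mm effective
  slice thickness along the acquisition axis;
* dynamic bSSFP-like 2D slices: 0.94 mm (axial) or 1.0 mm (sagittal)
  pixels, 3 mm slice thickness, ~35–38 ms per frame.

Rendering pipeline per instance: binary region map (vitreous/cornea
interior bright, lens nucleus and surround dark) → partial-volume
pixelation by sub-voxel supersampling of the region indicator over each
voxel's sensitive window (including through-slice thickness) → additive
Gaussian noise, N(0.7, 0.01) inside and N(0.2, 0.04) outside the eyeball
borders (variances) → Gaussian blur with SD of one pixel.  Ground truth
(model parameters / pose) travels with every rendered array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import Ellipsoid, EyeModel, build_eye_model
from .kinematics import Trajectory
from .ngm import MotionState
from .plane_intersection import Plane, PlaneFrame

__all__ = [
    "PopulationConfig",
    "IntensityModel",
    "VolumeProtocol",
    "SliceProtocol",
    "AXIAL",
    "SAGITTAL",
    "SimulatedEyeball",
    "SyntheticVolume",
    "SyntheticSlice",
    "sample_population",
    "default_eye_model",
    "render_volume",
    "render_slice",
    "slice_plane_through_lens",
    "sample_motion",
    "make_kinematic_fixture",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Population distribution of simulated eyeballs.

    Diameter ~ N(24, 1) mm anchored on the typical ~24 mm globe; per-axis
    shape ratios (x, y, z; y = anterior-posterior axis, slightly longest)
    have SD 2% around ocular-biometry means; structure orientations are
    N(0°, 5°).  All draws are clipped to physiologic bounds.
    """

    center_sd_mm: float = 1.0
    diameter_mean: float = 24.0
    diameter_sd: float = 1.0
    diameter_bounds: tuple[float, float] = (20.0, 28.0)
    axis_ratio_means: tuple[float, float, float] = (0.97, 1.04, 0.99)
    axis_ratio_sd: float = 0.02
    angle_sd_deg: float = 5.0
    angle_bound_deg: float = 20.0
    # cornea modelled as a sphere whose radius tracks eye size: the 7 mm
    # center constraint is fixed, so the corneal dome must scale with the
    # anterior sclera semi-axis to keep a ~2-3 mm protrusion
    cornea_radius_offset: float = 4.8
    structure_angle_jitter_deg: float = 2.0
    lens_semi_means: tuple[float, float, float] = (4.0, 1.8, 4.0)
    structure_semi_rel_sd: float = 0.02
    min_lens_containment: float = 0.98

    def validate(self):
        if self.diameter_sd < 0 or self.axis_ratio_sd < 0:
            raise ValueError("negative SD in population config")
        lo, hi = self.diameter_bounds
        if not (lo < self.diameter_mean < hi):
            raise ValueError("diameter mean outside bounds")


@dataclass(frozen=True)
class IntensityModel:
    """Region intensity statistics (means and noise SDs) and blur width."""

    inside_mean: float = 0.7
    inside_sd: float = 0.1  # variance 0.01
    outside_mean: float = 0.2
    outside_sd: float = 0.2  # variance 0.04
    lens_mean: float = 0.2
    lens_sd: float = 0.1
    blur_px: float = 1.0


@dataclass(frozen=True)
class VolumeProtocol:
    """T2-like static 3D geometry."""

    spacing: tuple[float, float, float] = (0.49, 0.49, 0.5)
    slice_thickness: float = 1.0
    slice_axis: int = 0  # sagittally acquired: slices stacked along x
    margin_mm: float = 6.0
    supersample: int = 4


@dataclass(frozen=True)
class SliceProtocol:
    """bSSFP-like dynamic single-slice geometry."""

    name: str = "axial"
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    pixel_spacing: float = 0.94
    slice_thickness: float = 3.0
    fov_mm: float = 44.0
    frame_interval_ms: float = 34.8
    supersample: int = 4


AXIAL = SliceProtocol("axial", (0.0, 0.0, 1.0), 0.94, 3.0, 44.0, 34.8)
SAGITTAL = SliceProtocol("sagittal", (1.0, 0.0, 0.0), 1.0, 3.0, 44.0, 37.8)


@dataclass
class SimulatedEyeball:
    """Ground-truth eye model drawn from the population distribution."""

    model: EyeModel
    index: int = 0


@dataclass
class SyntheticVolume:
    data: np.ndarray
    affine: np.ndarray
    truth: EyeModel
    protocol: VolumeProtocol


@dataclass
class SyntheticSlice:
    data: np.ndarray
    affine2d: np.ndarray  # 3x3: pixel index (row, col) -> in-plane mm
    plane: Plane
    frame: PlaneFrame
    truth: EyeModel
    pose: MotionState
    protocol: SliceProtocol


def default_eye_model(center=(0.0, 0.0, 0.0), diameter: float = 24.0) -> EyeModel:
    """Population-mean eye model; also the segmentation starting guess."""
    cfg = PopulationConfig()
    semi = diameter / 2.0 * np.asarray(cfg.axis_ratio_means)
    cr = semi[1] - cfg.cornea_radius_offset
    sclera = Ellipsoid(np.asarray(center, float), np.zeros(3), semi)
    return build_eye_model(
        sclera, (cr, cr, cr), np.zeros(3), cfg.lens_semi_means, np.zeros(3)
    )


def sample_population(
    n: int,
    config: PopulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[SimulatedEyeball]:
    """Draw ``n`` ground-truth eyeballs; reproducible for a given rng seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or PopulationConfig()
    cfg.validate()
    rng = np.random.default_rng(rng)
    out = []
    from .geometry import fibonacci_grid

    for i in range(n):
        for _ in range(200):
            d = float(
                np.clip(
                    rng.normal(cfg.diameter_mean, cfg.diameter_sd),
                    *cfg.diameter_bounds,
                )
            )
            q = rng.normal(cfg.axis_ratio_means, cfg.axis_ratio_sd)
            semi = d / 2.0 * q
            ab = cfg.angle_bound_deg
            sang = np.clip(rng.normal(0.0, cfg.angle_sd_deg, 3), -ab, ab)
            # cornea/lens orientations follow the globe's anterior axis with
            # small independent jitter (structures are nearly coaxial)
            base = np.array([sang[0], sang[2]])
            jit = cfg.structure_angle_jitter_deg
            cang = np.clip(base + rng.normal(0.0, jit, 2), -ab, ab)
            lang = np.clip(base + rng.normal(0.0, jit, 2), -ab, ab)
            cr = (semi[1] - cfg.cornea_radius_offset) * (
                1.0 + rng.normal(0.0, cfg.structure_semi_rel_sd)
            )
            lsem = np.asarray(cfg.lens_semi_means) * (
                1.0 + rng.normal(0.0, cfg.structure_semi_rel_sd, 3)
            )
            if cr <= 0:
                continue
            center = rng.normal(0.0, cfg.center_sd_mm, 3)
            sclera = Ellipsoid(center, sang, semi)
            model = build_eye_model(
                sclera, (cr, cr, cr), (cang[0], 0.0, cang[1]),
                lsem, (lang[0], 0.0, lang[1]),
            )
            # physiologic consistency: the lens must lie (almost) entirely
            # within the bright sclera ∪ cornea interior
            lp = fibonacci_grid(model.lens, 400, "lens").points
            contained = np.mean(
                model.sclera.contains(lp) | model.cornea.contains(lp)
            )
            if contained >= cfg.min_lens_containment:
                break
        out.append(SimulatedEyeball(model, i))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _region_fractions_at(model: EyeModel, points: np.ndarray):
    """Exclusive region labels at sample points: lens wins over eye interior."""
    in_lens = model.lens.contains(points)
    in_eye = (model.sclera.contains(points) | model.cornea.contains(points)) & ~in_lens
    return in_eye, in_lens


def _window_offsets(window: float, step_target: float) -> np.ndarray:
    """Centered sub-sample offsets tiling a sensitive window of given width."""
    m = max(int(np.ceil(window / step_target)), 1)
    j = np.arange(m)
    return window * ((j + 0.5) / m - 0.5)


def render_volume(
    eye: SimulatedEyeball | EyeModel,
    protocol: VolumeProtocol | None = None,
    rng: np.random.Generator | int | None = None,
    intensity: IntensityModel | None = None,
) -> SyntheticVolume:
    """Render a T2-like 3D volume around the eyeball with ground truth.

    Partial volume is computed by supersampling the region indicator ×4 per
    voxel dimension (the through-slice window uses the slice thickness,
    which exceeds the grid step for the overlapping-slice T2 protocol).
    Supersampling is restricted to voxels near a structure border; interior
    and exterior voxels are pure by construction.
    """
    model = eye.model if isinstance(eye, SimulatedEyeball) else eye
    prot = protocol or VolumeProtocol()
    inten = intensity or IntensityModel()
    rng = np.random.default_rng(rng)
    sp = np.asarray(prot.spacing)
    rmax = float(np.max(model.sclera.semi_axes))
    half = rmax + prot.margin_mm
    shape = tuple(int(np.ceil(2 * half / sp[k])) for k in range(3))
    origin = model.center - (np.array(shape) - 1) / 2.0 * sp
    affine = np.eye(4)
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = origin
    # eyeball must fit in the field of view
    lo = origin - sp / 2
    hi = origin + (np.array(shape) - 0.5) * sp
    if np.any(model.center - rmax < lo) or np.any(model.center + rmax > hi):
        raise ValueError("eyeball outside the simulated field of view")

    axes = [origin[k] + sp[k] * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    in_eye, in_lens = _region_fractions_at(model, centers)
    f_eye = in_eye.astype(float)
    f_lens = in_lens.astype(float)

    # windows: voxel spacing, except the acquisition axis uses slice thickness
    win = sp.copy()
    win[prot.slice_axis] = max(prot.slice_thickness, sp[prot.slice_axis])
    half_diag = 0.5 * float(np.linalg.norm(win))
    near = np.zeros(len(centers), dtype=bool)
    for ell in (model.sclera, model.cornea, model.lens):
        band = 1.5 * half_diag / float(np.min(ell.semi_axes))
        near |= np.abs(ell.implicit_norm(centers) - 1.0) < band
    idx = np.flatnonzero(near)
    if len(idx):
        offs = [
            _window_offsets(win[k], sp[k] / prot.supersample) for k in range(3)
        ]
        OX, OY, OZ = np.meshgrid(*offs, indexing="ij")
        offsets = np.stack([OX, OY, OZ], axis=-1).reshape(-1, 3)
        acc_eye = np.zeros(len(idx))
        acc_lens = np.zeros(len(idx))
        pts = centers[idx]
        for off in offsets:
            e, l = _region_fractions_at(model, pts + off)
            acc_eye += e
            acc_lens += l
        f_eye[idx] = acc_eye / len(offsets)
        f_lens[idx] = acc_lens / len(offsets)

    f_out = 1.0 - f_eye - f_lens
    mean = (
        f_eye * inten.inside_mean
        + f_lens * inten.lens_mean
        + f_out * inten.outside_mean
    )
    sd = f_eye * inten.inside_sd + f_lens * inten.lens_sd + f_out * inten.outside_sd
    img = mean + sd * rng.standard_normal(len(mean))
    img = img.reshape(shape)
    if inten.blur_px > 0:
        img = ndimage.gaussian_filter(img, inten.blur_px)
    return SyntheticVolume(img, affine, model, prot)


def slice_plane_through_lens(model: EyeModel, protocol: SliceProtocol) -> Plane:
    """Imaging plane of the protocol's orientation through the (rest-pose)
    lens center, ensuring lens visibility."""
    n = np.asarray(protocol.normal, float)
    return Plane(n, float(model.lens.center @ n))


def slice_geometry(model: EyeModel, protocol: SliceProtocol):
    """Plane, in-plane frame and pixel affine for a slice centered on the
    eyeball."""
    plane = slice_plane_through_lens(model, protocol)
    frame = PlaneFrame.from_plane(plane)
    c2 = frame.to_2d(model.center)
    npix = int(np.ceil(protocol.fov_mm / protocol.pixel_spacing))
    s = protocol.pixel_spacing
    origin2d = c2 - (npix - 1) / 2.0 * s
    affine2d = np.array([[s, 0.0, origin2d[0]], [0.0, s, origin2d[1]], [0, 0, 1.0]])
    return plane, frame, affine2d, (npix, npix)


def render_slice(
    eye: SimulatedEyeball | EyeModel,
    pose: MotionState | None = None,
    protocol: SliceProtocol | None = None,
    rng: np.random.Generator | int | None = None,
    intensity: IntensityModel | None = None,
    geometry=None,
) -> SyntheticSlice:
    """Render one bSSFP-like 2D slice of the posed eyeball.

    The slice sits at the rest-pose lens center (axial or sagittal per the
    protocol); through-plane partial volume averages the region indicator
    across the 3 mm slice thickness.  Same noise/blur recipe as 3D, in 2D.
    """
    model = eye.model if isinstance(eye, SimulatedEyeball) else eye
    prot = protocol or AXIAL
    inten = intensity or IntensityModel()
    rng = np.random.default_rng(rng)
    pose = pose or MotionState()
    if geometry is None:
        geometry = slice_geometry(model, prot)
    plane, frame, affine2d, shape = geometry

    posed = model.posed(pose.rotation, pose.translation)
    if abs(float(posed.sclera.center @ plane.normal) - plane.distance) >= float(
        np.max(posed.sclera.semi_axes)
    ):
        raise ValueError("plane misses the posed eyeball")

    s = prot.pixel_spacing
    rows = affine2d[0, 2] + s * np.arange(shape[0])
    cols = affine2d[1, 2] + s * np.arange(shape[1])
    offs_ip = _window_offsets(s, s / prot.supersample)
    offs_tp = _window_offsets(prot.slice_thickness, s / prot.supersample)

    U, V = np.meshgrid(rows, cols, indexing="ij")
    p2 = np.stack([U, V], axis=-1).reshape(-1, 2)

    acc_eye = np.zeros(len(p2))
    acc_lens = np.zeros(len(p2))
    n_sub = 0
    for du in offs_ip:
        for dv in offs_ip:
            base = frame.to_world(p2 + np.array([du, dv]))
            for dn in offs_tp:
                pts = base + dn * plane.normal
                e, l = _region_fractions_at(posed, pts)
                acc_eye += e
                acc_lens += l
                n_sub += 1
    f_eye = acc_eye / n_sub
    f_lens = acc_lens / n_sub
    f_out = 1.0 - f_eye - f_lens
    mean = (
        f_eye * inten.inside_mean
        + f_lens * inten.lens_mean
        + f_out * inten.outside_mean
    )
    sd = f_eye * inten.inside_sd + f_lens * inten.lens_sd + f_out * inten.outside_sd
    img = (mean + sd * rng.standard_normal(len(mean))).reshape(shape)
    if inten.blur_px > 0:
        img = ndimage.gaussian_filter(img, inten.blur_px)
    return SyntheticSlice(img, affine2d, plane, frame, model, pose, prot)


def sample_motion(
    n: int,
    translation_bound_mm: float = 2.0,
    rotation_bound_deg: float = 20.0,
    rng: np.random.Generator | int | None = None,
) -> list[MotionState]:
    """Uniform random rigid poses: translation ±2 mm on all three axes,
    rotation ±20° on both estimated axes and on torsion (torsion is
    rendered but never estimated)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    tb, rb = translation_bound_mm, rotation_bound_deg
    out = []
    for _ in range(n):
        t = rng.uniform(-tb, tb, 3)
        rx, rz, ry = rng.uniform(-rb, rb, 3)
        out.append(MotionState(t, rot_x=rx, rot_z=rz, torsion=ry))
    return out


# ---------------------------------------------------------------------------
# kinematic fixtures
# ---------------------------------------------------------------------------

def _raised_cosine(t: np.ndarray, t0: float, width: float, amp: float) -> np.ndarray:
    """Raised-cosine pulse: peak ``amp`` at t0+width/2, FWHM = width/2."""
    y = np.zeros_like(t)
    m = (t >= t0) & (t <= t0 + width)
    y[m] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[m] - t0) / width))
    return y


def _sigmoid(t: np.ndarray, t_mid: float, amp: float, tau: float, base: float):
    return base + amp / (1.0 + np.exp(-(t - t_mid) / tau))


def make_kinematic_fixture(
    kind: str = "blink",
    params: dict | None = None,
    rng: np.random.Generator | int | None = None,
    model: EyeModel | None = None,
    protocol: SliceProtocol | None = None,
    render: bool = True,
):
    """Smooth ground-truth trajectory (+ optionally rendered frames).

    Kinds: ``blink`` (raised-cosine retraction + lift), ``saccade``
    (sigmoid horizontal rotation step) and ``blink_saccade`` (both, with
    the gaze shift inside the retracted phase).  Returns
    ``(frames | None, truth Trajectory, model, geometry)``.
    """
    if kind not in ("blink", "saccade", "blink_saccade"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    p = {
        "duration_ms": 1200.0,
        "retraction_amp_mm": 1.2,
        "lift_amp_mm": 0.5,
        "blink_onset_ms": 250.0,
        "blink_width_ms": 500.0,  # FWHM = 250 ms
        "saccade_amp_deg": 12.0,
        "saccade_start_deg": -6.0,
        "saccade_mid_ms": 500.0,
        "saccade_tau_ms": 12.0,
    }
    p.update(params or {})
    rng = np.random.default_rng(rng)
    model = model or default_eye_model()
    prot = protocol or (SAGITTAL if kind == "blink" else AXIAL)
    dt = prot.frame_interval_ms
    t = np.arange(0.0, p["duration_ms"], dt)

    retr = np.zeros_like(t)
    lift = np.zeros_like(t)
    rot = np.zeros_like(t)
    if kind in ("blink", "blink_saccade"):
        retr = _raised_cosine(t, p["blink_onset_ms"], p["blink_width_ms"],
                              p["retraction_amp_mm"])
        lift = _raised_cosine(t, p["blink_onset_ms"], p["blink_width_ms"],
                              p["lift_amp_mm"])
    if kind in ("saccade", "blink_saccade"):
        rot = _sigmoid(t, p["saccade_mid_ms"], p["saccade_amp_deg"],
                       p["saccade_tau_ms"], p["saccade_start_deg"])

    import pandas as pd

    # retraction = anterior->posterior = +y; lift = inferior->superior = +z
    df = pd.DataFrame(
        {
            "frame": np.arange(len(t)),
            "time_ms": t,
            "tx": 0.0,
            "ty": retr,
            "tz": lift,
            "rot_x_deg": 0.0,
            "rot_z_deg": rot,
            "energy": np.nan,
            "converged": True,
        }
    )
    truth = Trajectory(df)
    geometry = slice_geometry(model, prot)
    frames = None
    if render:
        frames = np.stack(
            [
                render_slice(
                    model,
                    MotionState((0.0, retr[k], lift[k]), rot_x=0.0, rot_z=rot[k]),
                    prot,
                    rng,
                    geometry=geometry,
                ).data
                for k in range(len(t))
            ]
        )
    return frames, truth, model, geometry
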