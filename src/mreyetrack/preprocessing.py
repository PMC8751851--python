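"""Head-motion correction, automatic eye localization and temporal alignment.

Head translation during a dynamic sequence is estimated by subpixel
phase-correlation registration against a reference frame.  The eyeball is
localized with the fast radial symmetry transform (FRST), exploiting that a
typical eyeball is ~24 mm in diameter and appears as a bright, radially
symmetric blob.  External eye-tracker traces are matched to MR-derived
rotation traces by least-squares over a lag (and optional gain) grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "RegistrationResult",
    "register_frames",
    "radial_symmetry_map",
    "detect_eye_center",
    "AlignmentResult",
    "align_timeseries",
]


@dataclass
class RegistrationResult:
    """Per-frame translational shifts (pixels, subpixel) relative to the
    reference frame; the reference frame's shift is (0, 0)."""

    shifts: np.ndarray
    reference_index: int


def register_frames(
    frames: np.ndarray, upsample: int = 100, reference_index: int | None = None
) -> RegistrationResult:
    """Estimate each frame's translational offset vs. a reference frame.

    Uses subpixel image registration by cross-correlation (phase
    correlation with Fourier upsampling).  The reference defaults to the
    middle frame of the sequence, which is robust to blinks at the sequence
    edges.  The returned shift is the displacement of the frame's content
    relative to the reference: subtracting it re-aligns the frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("need a stack of >= 2 frames")
    ref_idx = len(frames) // 2 if reference_index is None else reference_index
    ref = frames[ref_idx]
    shifts = np.zeros((len(frames), 2))
    for k, frame in enumerate(frames):
        if k == ref_idx:
            continue
        if frame.std() == 0:
            warnings.warn(f"frame {k} is constant; assuming zero shift")
            continue
        # phase_cross_correlation returns the shift that maps the moving
        # image onto the reference; negate to get the frame's displacement
        s, _, _ = phase_cross_correlation(ref, frame, upsample_factor=upsample)
        shifts[k] = -s
    return RegistrationResult(shifts, ref_idx)


def radial_symmetry_map(
    image: np.ndarray,
    radii_px,
    alpha: float = 2.0,
    gradient_threshold_rel: float = 0.1,
) -> np.ndarray:
    """Fast radial symmetry transform for bright blobs (2D or 3D).

    For each radius, every strong gradient votes at the location the
    gradient points to (toward brighter tissue, i.e. the blob center),
    accumulating an orientation count and a magnitude sum; the per-radius
    symmetry map ``(O/k)^alpha * (M/k)`` is smoothed at the radius scale and
    the maps are averaged over radii.
    """
    image = np.asarray(image, dtype=float)
    grads = np.array(np.gradient(ndimage.gaussian_filter(image, 1.0)))
    mag = np.sqrt(np.sum(grads**2, axis=0))
    gmax = mag.max()
    out = np.zeros_like(image)
    if gmax == 0:
        return out
    mask = mag > gradient_threshold_rel * gmax
    pos = np.argwhere(mask)
    gvec = grads[:, mask].T
    gm = mag[mask]
    unit = gvec / gm[:, None]
    shape = image.shape
    for r in np.atleast_1d(radii_px):
        votes = np.rint(pos + r * unit).astype(int)
        ok = np.all((votes >= 0) & (votes < np.array(shape)), axis=1)
        flat = np.ravel_multi_index(tuple(votes[ok].T), shape)
        O = np.zeros(image.size)
        M = np.zeros(image.size)
        np.add.at(O, flat, 1.0)
        np.add.at(M, flat, gm[ok])
        kappa = max(O.max(), 1.0)
        F = (O / kappa) ** alpha * (M / kappa)
        out += ndimage.gaussian_filter(F.reshape(shape), max(r / 4.0, 1.0))
    return out / max(len(np.atleast_1d(radii_px)), 1)


def detect_eye_center(
    image: np.ndarray,
    spacing=None,
    affine: np.ndarray | None = None,
    radius_range_mm: tuple[float, float] = (10.0, 14.0),
    n_radii: int = 5,
    max_peaks: int = 1,
    min_separation_mm: float = 15.0,
    min_peak_rel: float = 0.5,
) -> np.ndarray:
    """Locate eyeball center(s) via the fast radial symmetry transform.

    Radii 10–14 mm (a ~24 mm globe) are converted to pixels per axis using
    the mean spacing; the multi-radius symmetry map's peaks are returned in
    physical coordinates (via ``affine`` if given, else ``index*spacing``).
    Raises ``ValueError`` when no symmetry peak exists (e.g. uniform image).
    """
    image = np.asarray(image, dtype=float)
    if spacing is None and affine is None:
        raise ValueError("spacing or affine required")
    if spacing is None:
        M = affine[: image.ndim, : image.ndim]
        spacing = np.sqrt(np.sum(M**2, axis=0))
    spacing = np.asarray(spacing, dtype=float)
    mean_sp = float(np.mean(spacing))
    radii_px = np.linspace(radius_range_mm[0], radius_range_mm[1], n_radii) / mean_sp
    smap = radial_symmetry_map(image, radii_px)
    if smap.max() <= 1e-12:
        raise ValueError("no radial symmetry peak found; provide a manual seed")
    # greedy peak picking with a physical separation constraint
    flat_order = np.argsort(smap, axis=None)[::-1]
    peaks: list[np.ndarray] = []
    vmax = smap.max()
    for fi in flat_order[: image.size // 10 + 1]:
        if len(peaks) >= max_peaks:
            break
        if smap.flat[fi] < min_peak_rel * vmax:
            break
        idx = np.array(np.unravel_index(fi, smap.shape), dtype=float)
        phys = idx * spacing
        if all(np.linalg.norm(phys - p) >= min_separation_mm for p in peaks):
            peaks.append(phys)
    pts = np.array(peaks)
    if affine is not None:
        idx_pts = pts / spacing
        M = affine[: image.ndim, : image.ndim]
        t = affine[: image.ndim, image.ndim]
        pts = idx_pts @ M.T + t
    return pts


@dataclass
class AlignmentResult:
    """Temporal match of an MR-derived trace to an external trace:
    ``mr(t) ≈ gain · ext(t − lag) + offset``."""

    lag_ms: float
    gain: float
    offset: float
    sse: float


def align_timeseries(
    t_mr: np.ndarray,
    y_mr: np.ndarray,
    t_ext: np.ndarray,
    y_ext: np.ndarray,
    max_lag_ms: float = 2000.0,
    lag_step_ms: float = 1.0,
    fit_gain: bool = True,
) -> AlignmentResult:
    """Least-squares temporal matching of two sampled traces.

    Scans lags on a grid (±max_lag at lag_step), resampling the external
    trace (typically 1 ms sampling) onto the MR time stamps, solving for
    gain/offset by ordinary least squares at each lag, then refines the
    best lag by parabolic interpolation of the SSE.
    """
    t_mr = np.asarray(t_mr, float)
    y_mr = np.asarray(y_mr, float)
    t_ext = np.asarray(t_ext, float)
    y_ext = np.asarray(y_ext, float)
    if t_mr.max() < t_ext.min() or t_mr.min() > t_ext.max():
        raise ValueError("time ranges do not overlap")

    lags = np.arange(-max_lag_ms, max_lag_ms + lag_step_ms / 2, lag_step_ms)

    def sse_at(lag: float) -> tuple[float, float, float]:
        ts = t_mr - lag
        inside = (ts >= t_ext[0]) & (ts <= t_ext[-1])
        if inside.sum() < 3:
            return np.inf, 1.0, 0.0
        ye = np.interp(ts[inside], t_ext, y_ext)
        ym = y_mr[inside]
        if fit_gain:
            A = np.column_stack([ye, np.ones_like(ye)])
            coef, *_ = np.linalg.lstsq(A, ym, rcond=None)
            gain, offset = float(coef[0]), float(coef[1])
        else:
            gain, offset = 1.0, float(np.mean(ym - ye))
        resid = ym - (gain * ye + offset)
        return float(resid @ resid), gain, offset

    sses = np.array([sse_at(l)[0] for l in lags])
    k = int(np.argmin(sses))
    lag = lags[k]
    # parabolic refinement on the discrete SSE minimum
    if 0 < k < len(lags) - 1 and np.isfinite(sses[k - 1 : k + 2]).all():
        a, b, c = sses[k - 1], sses[k], sses[k + 1]
        denom = a - 2 * b + c
        if denom > 0:
            lag = lags[k] + 0.5 * (a - c) / denom * lag_step_ms
    sse, gain, offset = sse_at(lag)
    return AlignmentResult(float(lag), gain, offset, sse)
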