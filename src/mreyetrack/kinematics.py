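"""Event detection and summary statistics on estimated eye trajectories.

Blink-related eye movements show as a retraction pulse (anterior→posterior
translation) with a simultaneous lift; gaze shifts show as a step in the
horizontal rotation trace.  Blink onset is the last crossing of 20% of the
peak retraction before the peak; retraction duration is the pulse's full
width at half maximum.  Saccade timing comes from a 4-parameter sigmoid
least-squares fit, whose midpoint is the analytic peak-velocity time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Trajectory",
    "BlinkEvent",
    "SaccadeFit",
    "detect_blinks",
    "fit_saccade",
    "interocular_lag",
    "retraction_vs_timing",
]


@dataclass
class Trajectory:
    """Per-frame motion time series.

    ``data`` columns: frame, time_ms, tx, ty, tz, rot_x_deg, rot_z_deg,
    energy, converged.  Retraction (anterior→posterior) is +ty; lift
    (inferior→superior) is +tz; horizontal gaze rotation is rot_z.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.data["time_ms"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.data["time_ms"].to_numpy()

    @property
    def retraction(self) -> np.ndarray:
        return self.data["ty"].to_numpy()

    @property
    def lift(self) -> np.ndarray:
        return self.data["tz"].to_numpy()

    @property
    def horizontal_rotation(self) -> np.ndarray:
        return self.data["rot_z_deg"].to_numpy()

    @property
    def vertical_rotation(self) -> np.ndarray:
        return self.data["rot_x_deg"].to_numpy()

    def to_csv(self, path):
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class BlinkEvent:
    """One blink: onset (20%-of-peak crossing), peak retraction and FWHM."""

    onset_ms: float
    peak_time_ms: float
    amplitude_mm: float
    fwhm_ms: float

    def __post_init__(self):
        if self.fwhm_ms <= 0:
            raise ValueError("blink duration must be positive")
        if self.onset_ms > self.peak_time_ms:
            raise ValueError("blink onset must precede the peak")


@dataclass
class SaccadeFit:
    """Sigmoid fit of a gaze step: baseline + amp / (1 + exp(-(t-t0)/tau))."""

    midpoint_ms: float
    amplitude_deg: float
    tau_ms: float
    baseline_deg: float
    rmse: float
    low_confidence: bool = False

    @property
    def peak_velocity_time_ms(self) -> float:
        """Analytic maximum-slope point of the fitted sigmoid."""
        return self.midpoint_ms


def _cross_time(t0, y0, t1, y1, level) -> float:
    """Linear-interpolated crossing time of ``level`` between two samples."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _last_crossing_before(t, y, k_peak, level) -> float:
    for k in range(k_peak, 0, -1):
        if (y[k - 1] - level) * (y[k] - level) <= 0 and y[k] >= level:
            return _cross_time(t[k - 1], y[k - 1], t[k], y[k], level)
    return t[0]


def _first_crossing_after(t, y, k_peak, level) -> float:
    for k in range(k_peak, len(y) - 1):
        if (y[k] - level) * (y[k + 1] - level) <= 0 and y[k] >= level:
            return _cross_time(t[k], y[k], t[k + 1], y[k + 1], level)
    return t[-1]


def detect_blinks(
    traj: Trajectory,
    search_windows=None,
    min_amplitude_mm: float = 0.2,
    onset_fraction: float = 0.2,
) -> list[BlinkEvent]:
    """Detect blink retraction pulses in the anterior/posterior trace.

    Within each search window (e.g. from video-eye-tracker pupil loss) or
    over the whole trace, the retraction peak is located; onset is the last
    20%-of-peak crossing before the peak (sub-frame, by linear
    interpolation) and duration is the pulse FWHM.  Peaks below
    ``min_amplitude_mm`` yield no event.
    """
    t = traj.times
    y = traj.retraction
    if search_windows is None:
        search_windows = [(t[0], t[-1])]
    events = []
    for lo, hi in search_windows:
        m = (t >= lo) & (t <= hi)
        if m.sum() < 3:
            continue
        tw, yw = t[m], y[m]
        base = float(np.min(yw))
        yw = yw - base
        k = int(np.argmax(yw))
        amp = float(yw[k])
        if amp < min_amplitude_mm:
            continue
        onset = _last_crossing_before(tw, yw, k, onset_fraction * amp)
        t_half0 = _last_crossing_before(tw, yw, k, 0.5 * amp)
        t_half1 = _first_crossing_after(tw, yw, k, 0.5 * amp)
        events.append(BlinkEvent(onset, float(tw[k]), amp, t_half1 - t_half0))
    return events


def fit_saccade(
    traj: Trajectory,
    window=None,
    component: str = "rot_z_deg",
    min_amplitude_deg: float = 1.0,
    rmse_threshold_deg: float = 1.0,
) -> SaccadeFit:
    """Least-squares 4-parameter sigmoid fit of a gaze transition.

    Raises ``ValueError`` when the window contains no transition; flags the
    fit low-confidence when the residual RMSE exceeds the threshold.
    """
    t = traj.times
    y = traj.data[component].to_numpy()
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    if len(t) < 5:
        raise ValueError("window too short for a sigmoid fit")
    amp0 = float(y[-1] - y[0])
    if abs(amp0) < min_amplitude_deg and np.ptp(y) < min_amplitude_deg:
        raise ValueError("no gaze transition in window")
    level = y[0] + 0.5 * amp0
    k = int(np.argmin(np.abs(y - level)))
    p0 = [float(t[k]), amp0, max(np.mean(np.diff(t)) / 2, 1.0), float(y[0])]

    def f(tt, t0, a, tau, b):
        return b + a / (1.0 + np.exp(-np.clip((tt - t0) / tau, -500, 500)))

    try:
        popt, _ = optimize.curve_fit(f, t, y, p0=p0, maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - pathological input
        raise ValueError(f"sigmoid fit failed: {err}") from err
    t0, a, tau, b = popt
    if abs(a) < min_amplitude_deg:
        raise ValueError("no gaze transition in window")
    rmse = float(np.sqrt(np.mean((f(t, *popt) - y) ** 2)))
    return SaccadeFit(
        float(t0), float(a), float(abs(tau)), float(b), rmse,
        low_confidence=rmse > rmse_threshold_deg,
    )


@dataclass
class LagResult:
    """Interocular timing difference: mean of per-pair peak-velocity time
    differences (first − second argument) with a one-sample t-test."""

    mean_lag_ms: float
    sem_ms: float
    t_stat: float
    p_value: float
    n: int
    zero_variance: bool = False


def interocular_lag(
    left: list[SaccadeFit], right: list[SaccadeFit], pairing=None
) -> LagResult:
    """Paired comparison of saccade peak-velocity times between the eyes."""
    if pairing is None:
        n = min(len(left), len(right))
        pairing = list(zip(range(n), range(n)))
    if len(pairing) < 2:
        raise ValueError("need at least 2 paired events")
    d = np.array(
        [left[i].peak_velocity_time_ms - right[j].peak_velocity_time_ms
         for i, j in pairing]
    )
    if np.allclose(d.std(ddof=1), 0.0):
        return LagResult(float(d.mean()), 0.0, np.nan, np.nan, len(d), True)
    res = stats.ttest_1samp(d, 0.0)
    sem = float(d.std(ddof=1) / np.sqrt(len(d)))
    return LagResult(float(d.mean()), sem, float(res.statistic),
                     float(res.pvalue), len(d))


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    df: int


def retraction_vs_timing(
    blinks: list[BlinkEvent], saccades: list[SaccadeFit]
) -> CorrelationResult:
    """Pearson correlation between retraction duration (FWHM) and saccade
    timing (peak-velocity time relative to blink onset) over matched
    blink/saccade pairs."""
    n = min(len(blinks), len(saccades))
    if n < 3:
        raise ValueError("need at least 3 matched pairs")
    x = np.array([b.fwhm_ms for b in blinks[:n]])
    y = np.array(
        [s.peak_velocity_time_ms - b.onset_ms
         for b, s in zip(blinks[:n], saccades[:n])]
    )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n - 2)
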