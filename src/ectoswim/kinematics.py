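"""Kinematic analysis of tracked trials.

Works from the averaged 3D location of the two tracking points (the
midpoint).  Speeds come in two flavours: full 3D frame-to-frame speed, and
a horizontal-only (2D) speed that nullifies the influence of imperfect
buoyancy on the vertical component.  Acceleration is the slope of an
ordinary least-squares line fitted to the 2D speed over the motor-on
window(s).  Rocking is the deviation of the inter-point axis from vertical
relative to its static angle; yaw trials report the unwrapped bearing of
the inter-point axis and its frame-differenced angular velocity.

Group comparisons use a Welch one-way ANOVA (unequal variances) with a
Games-Howell post hoc: pairwise Welch t statistics referred to the
studentized-range distribution with q = t*sqrt(2) and Welch-Satterthwaite
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .simulate import TrackedTrial

__all__ = [
    "KinematicsResult",
    "YawResult",
    "velocity_series",
    "fit_acceleration",
    "rocking_angle",
    "yaw_series",
    "summarize_trial",
    "group_summary",
    "welch_anova",
    "games_howell",
    "welch_anova_games_howell",
    "interpoint_distance_sd",
]

#: a trial is "at rest" when the smoothed horizontal speed stays below this
REST_SPEED_MPS = 0.01
REST_HOLD_S = 0.5
SMOOTH_FRAMES = 5


def _midpoint_speeds(trial: TrackedTrial, mode: str) -> tuple:
    if trial.n_frames < 2:
        raise ValueError("need at least 2 frames")
    t = trial.time
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    mid = trial.midpoints
    d = np.diff(mid, axis=0)
    if mode == "2d":
        dist = np.hypot(d[:, 0], d[:, 1])
    elif mode == "3d":
        dist = np.linalg.norm(d, axis=1)
    else:
        raise ValueError("mode must be '2d' or '3d'")
    return t[1:], dist / np.diff(t)


def velocity_series(trial: TrackedTrial, mode: str = "2d"):
    """Frame-to-frame speed of the tracking-point midpoint (m/s).

    Returns ``(times, speeds)``; times are the trailing edge of each frame
    interval.  Mode ``"2d"`` drops the vertical component.
    """
    return _midpoint_speeds(trial, mode)


def _smooth(v: np.ndarray, window: int = SMOOTH_FRAMES) -> np.ndarray:
    if len(v) < window:
        return v.copy()
    kernel = np.ones(window) / window
    sm = np.convolve(v, kernel, mode="same")
    # restore edges where the kernel ran off the series
    half = window // 2
    sm[:half] = v[:half]
    sm[-half:] = v[-half:]
    return sm


@dataclass
class AccelerationFit:
    slope_mps2: float
    intercept_mps: float
    r_squared: float
    n_frames: int

    @property
    def slope_cms2(self) -> float:
        return self.slope_mps2 * 100.0


def _motor_windows(trial: TrackedTrial):
    on = trial.motor_on.astype(int)
    edges = np.diff(np.concatenate([[0], on, [0]]))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return [(trial.time[a], trial.time[min(b, trial.n_frames) - 1])
            for a, b in zip(starts, stops)]


def fit_acceleration(trial: TrackedTrial, windows=None,
                     mode: str = "2d") -> AccelerationFit:
    """OLS line through the speed series over the jet-pulse window(s);
    slope is the acceleration (m/s^2, also exposed in cm/s^2)."""
    if windows is None:
        windows = _motor_windows(trial)
        if not windows:
            raise ValueError("trial has no motor-on window")
    t, v = velocity_series(trial, mode)
    mask = np.zeros(len(t), dtype=bool)
    for a, b in windows:
        mask |= (t >= a) & (t <= b)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 frames in the fit window")
    res = _stats.linregress(t[mask], v[mask])
    return AccelerationFit(float(res.slope), float(res.intercept),
                           float(res.rvalue ** 2), int(mask.sum()))


def rocking_angle(trial: TrackedTrial, theta_tp: float = 0.0) -> np.ndarray:
    """Pitch deviation from static posture, degrees per frame.

    The inter-point axis (anterior p1 to posterior p2) makes an angle
    ``arccos((z2 - z1)/|p2 - p1|)`` with true vertical; subtracting the
    static tracking-point angle ``theta_tp`` leaves the rocking deviation.
    """
    d = trial.p2 - trial.p1
    norm = np.linalg.norm(d, axis=1)
    if np.any(norm < 1e-12):
        raise ValueError("coincident tracking points")
    ang = np.degrees(np.arccos(np.clip(d[:, 2] / norm, -1.0, 1.0)))
    return ang - theta_tp


@dataclass
class YawResult:
    """Unwrapped yaw of the inter-point axis."""

    time: np.ndarray
    net_angle_deg: np.ndarray
    omega_deg_s: np.ndarray
    peak_omega_deg_s: float
    revolutions: float


def yaw_series(trial: TrackedTrial) -> YawResult:
    """Net yaw angle (deg, counter-clockwise positive from above) and
    frame-differenced angular velocity (deg/s)."""
    d = (trial.p1 - trial.p2)[:, :2]
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r < 1e-12):
        raise ValueError("tracking points vertically stacked: bearing undefined")
    bearing = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    net = np.degrees(bearing - bearing[0])
    omega = np.diff(net) / np.diff(trial.time)
    peak = float(np.max(np.abs(omega))) if len(omega) else 0.0
    return YawResult(trial.time, net, omega, peak,
                     float(np.max(np.abs(net)) / 360.0))


# ----------------------------------------------------------------------------
# per-trial and per-group summaries
# ----------------------------------------------------------------------------
@dataclass
class TrialSummary:
    peak_velocity_mps: float
    coasting_distance_m: float
    duration_s: float
    accel: AccelerationFit | None = None


def summarize_trial(trial: TrackedTrial,
                    rest_speed: float = REST_SPEED_MPS,
                    rest_hold: float = REST_HOLD_S) -> TrialSummary:
    """Peak (smoothed) horizontal speed, coasting distance, and duration.

    Coasting distance is the horizontal path length of the midpoint from
    motor-off until the smoothed speed stays below ``rest_speed`` for
    ``rest_hold`` seconds (or the track ends); duration runs from the first
    frame to that rest point.
    """
    t, v = velocity_series(trial, "2d")
    vs = _smooth(v)
    peak = float(np.max(vs))
    accel = None
    windows = _motor_windows(trial)
    if windows:
        accel = fit_acceleration(trial, windows)
    # rest detection
    hold = max(int(round(rest_hold * trial.frame_rate)), 1)
    below = vs < rest_speed
    rest_idx = len(t)
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= hold:
            rest_idx = i - hold + 1
            break
    duration = float(t[min(rest_idx, len(t) - 1)] - trial.time[0])
    # coasting distance from motor-off
    if windows:
        t_off = windows[-1][1]
    else:
        t_off = trial.time[0]
    mid = trial.midpoints[:, :2]
    steps = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    coast_mask = (t > t_off) & (np.arange(len(t)) <= rest_idx)
    coasting = float(steps[coast_mask].sum())
    return TrialSummary(peak, coasting, duration, accel)


def group_summary(values) -> dict:
    """Mean with a 95% t-interval for one group of per-trial values."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("empty group")
    mean = float(x.mean())
    if len(x) < 2:
        return {"n": 1, "mean": mean, "ci95": (mean, mean), "sd": 0.0}
    sem = x.std(ddof=1) / math.sqrt(len(x))
    tcrit = _stats.t.ppf(0.975, len(x) - 1)
    return {
        "n": int(len(x)),
        "mean": mean,
        "sd": float(x.std(ddof=1)),
        "ci95": (mean - tcrit * sem, mean + tcrit * sem),
    }


def interpoint_distance_sd(trial: TrackedTrial) -> float:
    """SD of the reconstructed inter-point distance (m): the calibration
    quality gate (videogrammetry wand scores accept < 1 cm)."""
    d = np.linalg.norm(trial.p1 - trial.p2, axis=1)
    return float(d.std(ddof=1))


# ----------------------------------------------------------------------------
# Welch ANOVA and Games-Howell
# ----------------------------------------------------------------------------
def _group_stats(groups: dict):
    names = list(groups)
    n = np.array([len(groups[g]) for g in names], dtype=float)
    if len(names) < 2 or np.any(n < 2):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    means = np.array([np.mean(groups[g]) for g in names])
    var = np.array([np.var(groups[g], ddof=1) for g in names])
    return names, n, means, var


def welch_anova(groups: dict) -> dict:
    """Welch's heteroscedastic one-way ANOVA.

    ``groups`` maps labels to 1D samples; returns the F* statistic, the
    degrees of freedom, and the p-value.
    """
    names, n, means, var = _group_stats(groups)
    if np.any(var <= 0):
        raise ValueError("zero within-group variance")
    k = len(names)
    w = n / var
    mw = float((w * means).sum() / w.sum())
    num = float((w * (means - mw) ** 2).sum() / (k - 1))
    h = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    den = 1.0 + 2.0 * (k - 2) / (k ** 2 - 1) * h
    f = num / den
    df2 = (k ** 2 - 1) / (3.0 * h)
    p = float(_stats.f.sf(f, k - 1, df2))
    return {"F": f, "df1": k - 1, "df2": float(df2), "p": p}


def games_howell(groups: dict) -> list:
    """Games-Howell pairwise comparisons.

    For each pair: t = (mi - mj)/sqrt(si^2/ni + sj^2/nj) with
    Welch-Satterthwaite df; the p-value refers q = |t|*sqrt(2) to the
    studentized-range distribution with k groups.  Returns a symmetric list
    of records.
    """
    names, n, means, var = _group_stats(groups)
    k = len(names)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = var[i] / n[i] + var[j] / n[j]
            if se2 <= 0:
                raise ValueError(
                    f"zero variance comparing {names[i]!r} and {names[j]!r}")
            t = (means[i] - means[j]) / math.sqrt(se2)
            df = se2 ** 2 / (
                (var[i] / n[i]) ** 2 / (n[i] - 1)
                + (var[j] / n[j]) ** 2 / (n[j] - 1)
            )
            q = abs(t) * math.sqrt(2.0)
            p = float(_stats.studentized_range.sf(q, k, df))
            out.append({
                "a": names[i], "b": names[j],
                "mean_diff": float(means[i] - means[j]),
                "t": float(t), "df": float(df), "q": q, "p": p,
            })
    return out


def welch_anova_games_howell(groups: dict) -> dict:
    """Omnibus Welch ANOVA plus the Games-Howell pairwise table."""
    return {"anova": welch_anova(groups), "pairwise": games_howell(groups)}
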