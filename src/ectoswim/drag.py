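"""Drag-coefficient estimation from coasting deceleration.

After the jet ceases, a neutrally buoyant rigid body coasts under pure
quadratic drag:

    (m + m_a) dv/dt = -1/2 rho Cd A v^2
    =>  v(t) = v0 / (1 + k v0 t),   k = rho Cd A / (2 (m + m_a))

Fitting this closed form to the horizontal speed series over the coasting
window recovers ``k`` and hence the drag coefficient.  Conventions carried
in every fit report: the reference area is the frontal (motion-normal)
projected area of the displaced-water body, and the effective mass includes
a constant added-mass allowance.  Known caveats of this rough estimate --
pitch rocking, yaw turning the body out of the motion direction late in the
coast, velocity-dependent added mass -- are the reasons fits on noisy
trials can carry low R-squared; the window therefore refuses frames after
the heading has turned past a configurable bearing change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares

from .kinematics import velocity_series, _motor_windows, _smooth
from .mesh import TriMesh, signed_volume
from .simulate import TrackedTrial

__all__ = [
    "DragFit",
    "coasting_velocity_model",
    "fit_drag_coefficient",
    "frontal_area",
]


def coasting_velocity_model(v0: float, k: float, t) -> np.ndarray:
    """Closed-form coasting speed v(t) = v0 / (1 + k v0 t).

    ``k`` is in 1/m: the exact solution of quadratic-drag coasting with
    k = rho Cd A / (2 m_eff).
    """
    if v0 <= 0 or k < 0:
        raise ValueError("v0 must be positive and k non-negative")
    t = np.asarray(t, dtype=float)
    return v0 / (1.0 + k * v0 * t)


@dataclass
class DragFit:
    """Result of a coasting-decay fit."""

    cd: float
    v0_mps: float
    k_per_m: float
    r_squared: float
    reference_area_cm2: float
    effective_mass_g: float
    fluid_density_gcm3: float
    window_frames: tuple
    physical: bool
    convention: str = (
        "reference area = frontal projected area of the displaced-water "
        "body; effective mass = body mass + constant added mass"
    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _coasting_window(trial: TrackedTrial, max_bearing_change_deg: float,
                     settle_time_s: float = 0.25):
    """Frame indices of the usable coasting window: motor-off (plus a short
    settle period for the thrust tail and wake) to rest/track end, truncated
    where the horizontal heading has turned too far."""
    windows = _motor_windows(trial)
    if windows:
        t_off = windows[-1][1] + settle_time_s
        start = int(np.searchsorted(trial.time, t_off, side="right"))
    else:
        start = 1  # pure coasting trial: velocities defined from frame 1
    stop = trial.n_frames
    if max_bearing_change_deg is not None:
        mid = trial.midpoints[:, :2]
        if len(mid) >= 5:  # damp tracking noise before judging headings
            kernel = np.ones(5) / 5.0
            sm = np.column_stack([np.convolve(mid[:, j], kernel, mode="same")
                                  for j in range(2)])
            sm[:2], sm[-2:] = mid[:2], mid[-2:]
        else:
            sm = mid
        steps = np.diff(sm, axis=0)
        # sub-millimetre steps carry no usable heading
        ok = np.linalg.norm(steps, axis=1) > 1e-3
        bearing = np.full(len(steps), np.nan)
        bearing[ok] = np.degrees(np.arctan2(steps[ok, 1], steps[ok, 0]))
        ref_idx = min(max(start - 1, 0), len(steps) - 1)
        ref = bearing[ref_idx] if ok[ref_idx] else np.nan
        for i in range(start, len(steps)):
            if ok[i] and np.isfinite(ref):
                dev = (bearing[i] - ref + 180.0) % 360.0 - 180.0
                if abs(dev) > max_bearing_change_deg:
                    stop = i + 1
                    break
    return start, stop


def fit_drag_coefficient(
    trial: TrackedTrial,
    frontal_area_cm2: float,
    effective_mass_g: float,
    fluid_density_gcm3: float = 1.025,
    max_bearing_change_deg: float = 60.0,
    min_frames: int = 10,
    smooth: bool = False,
    robust: bool = False,
    settle_time_s: float = 0.25,
) -> DragFit:
    """Fit the quadratic-drag coasting model to a trial's horizontal speeds.

    The fit window starts strictly after motor-off (never inside the thrust
    phase; ``settle_time_s`` additionally skips the pump's decay tail) and
    ends at the track end or where yaw has rotated the heading beyond
    ``max_bearing_change_deg``.  Least squares on the speeds (not their
    logs); ``robust`` switches to a soft-L1 loss for noisy tails.
    """
    if frontal_area_cm2 <= 0 or effective_mass_g <= 0:
        raise ValueError("area and effective mass must be positive")
    start, stop = _coasting_window(trial, max_bearing_change_deg,
                                   settle_time_s)
    t_all, v_all = velocity_series(trial, "2d")
    # velocity sample i spans frames (i, i+1); keep those fully in-window
    lo = max(start, 1) - 1
    idx = np.arange(lo, min(stop - 1, len(v_all)))
    if len(idx) < min_frames:
        raise ValueError(
            f"coasting window has {len(idx)} frames; need >= {min_frames}")
    t = t_all[idx] - t_all[idx[0]]
    v = _smooth(v_all[idx]) if smooth else v_all[idx]

    v0_init = max(float(v[0]), 1e-6)
    k_init = 1.0
    if v[-1] > 0 and v[-1] < v0_init:
        k_init = max((v0_init / float(v[-1]) - 1.0) / (v0_init * max(t[-1], 1e-9)),
                     1e-6)

    def resid(p):
        v0, k = p
        return v0 / (1.0 + np.clip(k, None, 1e6) * v0 * t) - v

    sol = least_squares(
        resid, x0=[v0_init, k_init],
        loss="soft_l1" if robust else "linear",
        bounds=([1e-9, -np.inf], [np.inf, np.inf]),
    )
    v0_fit, k_fit = map(float, sol.x)
    ss_res = float(np.sum(sol.fun ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    # Cd from k = rho Cd A / (2 m_eff), SI
    rho = fluid_density_gcm3 * 1e3
    area = frontal_area_cm2 * 1e-4
    m_eff = effective_mass_g * 1e-3
    cd = 2.0 * k_fit * m_eff / (rho * area)
    return DragFit(
        cd=cd,
        v0_mps=v0_fit,
        k_per_m=k_fit,
        r_squared=r2,
        reference_area_cm2=frontal_area_cm2,
        effective_mass_g=effective_mass_g,
        fluid_density_gcm3=fluid_density_gcm3,
        window_frames=(int(idx[0] + 1), int(idx[-1] + 2)),
        physical=bool(k_fit >= 0),
    )


def frontal_area(mesh: TriMesh, direction) -> float:
    """Projected silhouette area (cm^2) of a watertight mesh onto the plane
    normal to ``direction``.

    Computed as the polygon union of the projected front-facing triangles.
    """
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("direction must be non-zero")
    d = d / norm
    signed_volume(mesh)  # watertightness gate
    # orthonormal basis of the projection plane
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    tri = mesh.vertices[mesh.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    front = normals @ d > 0  # front-facing triangles cover the silhouette
    uv = np.stack([tri @ e1, tri @ e2], axis=-1)
    polys = []
    for f in np.flatnonzero(front):
        p = Polygon(uv[f])
        if p.is_valid and p.area > 0:
            polys.append(p)
    return float(unary_union(polys).area)
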