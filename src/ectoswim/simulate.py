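"""Rigid-body jet-propulsion trial simulator.

Stands in for the pool experiments: a neutrally buoyant, ~1 kg, ~15 cm
rigid body is driven by one-second jet pulses (~0.3 N time-averaged,
Nautilus-like) and tracked at two body-fixed points sampled at 23.975
frames/s, as a stereo-videogrammetry rig would deliver.

Linear trials integrate

    (m + m_a) dv/dt = T(t) - 1/2 rho Cd A v|v|

along the jet axis (added mass ``m_a`` as a fixed coefficient times body
mass), with optional buoyancy-imbalance vertical drift, lateral drift,
pitch rocking of the tracking points, and Gaussian position noise.  Yaw
trials integrate

    Izz dw/dt = T(t) L - c_rot w|w|

about the vertical axis (counter-clockwise positive from above), the thrust
torque acting through a 90-degree elbow on the hyponome lever arm ``L``.
Rotational resistance is modelled as quadratic in the yaw rate; the wake
re-encounter oscillations seen in pool footage are not modelled.

Integration is explicit RK4 at a 1 ms internal step, resampled to the frame
rate; every trial is deterministic given its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "JetProfile",
    "BodyParams",
    "TrackedTrial",
    "simulate_linear_trial",
    "simulate_yaw_trial",
    "make_fixture_suite",
    "MORPHOTYPE_BODIES",
]

FRAME_RATE = 23.975  # frames per second
G_MPS2 = 9.81


def time_averaged_thrust(peak_thrust_n: float = 2.0,
                         fraction: float = 0.23) -> float:
    """Time-averaged pulse thrust from a peak measurement.

    Adult Nautilus peaks near 2 N during escape jetting; the pulse-averaged
    value runs about 23% of peak (0.46 N), bracketing the ~0.3 N the robot
    pumps deliver as a conservative Nautilus-like thrust.
    """
    if peak_thrust_n < 0 or not (0 <= fraction <= 1):
        raise ValueError("peak thrust must be >= 0 and fraction in [0, 1]")
    return peak_thrust_n * fraction


@dataclass
class JetProfile:
    """Thrust pulse train.

    The thrust rises exponentially to a plateau when the motor switches on
    and decays exponentially after switch-off (time constants ~50 ms,
    mimicking an impeller pump that quickly reaches its maximum thrust and
    quickly declines).  ``n_pulses = 0`` gives an unpowered (coasting-only)
    trial.
    """

    pulse_duration: float = 1.0   # s
    refill_duration: float = 1.0  # s
    n_pulses: int = 1
    thrust_plateau: float = 0.3   # N
    rise_tau: float = 0.05        # s
    decay_tau: float = 0.05       # s

    def __post_init__(self):
        if self.pulse_duration <= 0 or self.refill_duration <= 0:
            raise ValueError("durations must be positive")
        if self.thrust_plateau < 0 or self.n_pulses < 0:
            raise ValueError("thrust and pulse count must be non-negative")

    @classmethod
    def from_mean_thrust(cls, mean_thrust: float, **kwargs) -> "JetProfile":
        """Choose the plateau so the time-average over one pulse equals
        ``mean_thrust`` (the ~0.3 N figure is a pulse-averaged value)."""
        jp = cls(thrust_plateau=1.0, **kwargs)
        d, tau = jp.pulse_duration, jp.rise_tau
        avg_unit = 1.0 - (tau / d) * (1.0 - math.exp(-d / tau))
        jp.thrust_plateau = mean_thrust / avg_unit
        return jp

    def thrust(self, t: float) -> float:
        """Thrust (N) at time ``t`` (s), t = 0 at first motor-on.

        Zero rise/decay time constants give an ideal rectangular pulse.
        """
        if self.n_pulses == 0 or t < 0:
            return 0.0
        period = self.pulse_duration + self.refill_duration
        total = 0.0
        for i in range(self.n_pulses):
            t0 = i * period
            if t < t0:
                break
            dt = t - t0
            if dt <= self.pulse_duration:
                if self.rise_tau <= 0:
                    total += self.thrust_plateau
                else:
                    total += self.thrust_plateau * (
                        1.0 - math.exp(-dt / self.rise_tau))
            elif self.decay_tau > 0:
                if self.rise_tau <= 0:
                    t_end = self.thrust_plateau
                else:
                    t_end = self.thrust_plateau * (
                        1.0 - math.exp(-self.pulse_duration / self.rise_tau))
                total += t_end * math.exp(
                    -(dt - self.pulse_duration) / self.decay_tau)
        return total

    def breakpoints(self) -> list:
        """Times where the thrust profile is non-smooth (pulse edges);
        integration substeps split here."""
        period = self.pulse_duration + self.refill_duration
        out = []
        for i in range(self.n_pulses):
            out += [i * period, i * period + self.pulse_duration]
        return out

    def motor_on(self, t: float) -> bool:
        if self.n_pulses == 0 or t < 0:
            return False
        period = self.pulse_duration + self.refill_duration
        if t >= self.n_pulses * period - self.refill_duration:
            return False
        return (t % period) < self.pulse_duration


@dataclass
class BodyParams:
    """Physical parameters of one robot/morphotype.

    Masses in grams, lengths in cm, densities in g/cm^3 (converted to SI
    internally); ``added_mass_coefficient`` scales the body mass to give the
    effective linear inertia (the body accelerates nearby water with it).
    ``rotational_drag_nms2`` is the quadratic yaw-resistance coefficient
    (torque = -c w|w|, N m s^2).
    """

    mass_g: float = 982.0
    added_mass_coefficient: float = 0.5
    frontal_area_cm2: float = math.pi * 7.5 ** 2
    drag_coefficient: float = 0.5
    fluid_density_gcm3: float = 1.025
    izz_gcm2: float = 22000.0
    rotational_drag_nms2: float = 3e-4
    lever_arm_cm: float = 7.5
    tracking_point_offsets_cm: tuple = ((6.0, 0.0, 3.0), (-6.0, 0.0, -3.0))
    buoyancy_imbalance_g: float = 0.0
    rocking_amplitude_deg: float = 0.0
    rocking_frequency_hz: float = 0.8
    name: str = "body"

    def __post_init__(self):
        for v in (self.mass_g, self.frontal_area_cm2, self.izz_gcm2):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("mass, frontal area and Izz must be positive")
        if self.drag_coefficient < 0 or self.rotational_drag_nms2 < 0:
            raise ValueError("drag coefficients must be non-negative")

    # SI conversions -------------------------------------------------------
    @property
    def mass_kg(self) -> float:
        return self.mass_g * 1e-3

    @property
    def effective_mass_kg(self) -> float:
        return self.mass_kg * (1.0 + self.added_mass_coefficient)

    @property
    def frontal_area_m2(self) -> float:
        return self.frontal_area_cm2 * 1e-4

    @property
    def fluid_density_kgm3(self) -> float:
        return self.fluid_density_gcm3 * 1e3

    @property
    def izz_kgm2(self) -> float:
        return self.izz_gcm2 * 1e-7

    @property
    def lever_arm_m(self) -> float:
        return self.lever_arm_cm * 1e-2

    @property
    def drag_factor(self) -> float:
        """1/2 rho Cd A in kg/m."""
        return 0.5 * self.fluid_density_kgm3 * self.drag_coefficient \
            * self.frontal_area_m2


@dataclass
class TrackedTrial:
    """Two tracked points of one trial, world coordinates in metres."""

    time: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    motor_on: np.ndarray
    frame_rate: float = FRAME_RATE
    ground_truth: dict | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        self.motor_on = np.asarray(self.motor_on, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.p1 + self.p2)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "t_s": self.time,
            "p1x": self.p1[:, 0], "p1y": self.p1[:, 1], "p1z": self.p1[:, 2],
            "p2x": self.p2[:, 0], "p2y": self.p2[:, 1], "p2z": self.p2[:, 2],
            "motor_on": self.motor_on.astype(int),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ground_truth: dict | None = None) -> "TrackedTrial":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy()
        fr = 1.0 / np.median(np.diff(t)) if len(t) > 1 else FRAME_RATE
        return cls(
            time=t,
            p1=df[["p1x", "p1y", "p1z"]].to_numpy(),
            p2=df[["p2x", "p2y", "p2z"]].to_numpy(),
            motor_on=df["motor_on"].to_numpy().astype(bool),
            frame_rate=fr,
            ground_truth=ground_truth,
        )


# ----------------------------------------------------------------------------
# integration
# ----------------------------------------------------------------------------
def _frame_times(duration: float, frame_rate: float) -> np.ndarray:
    n = int(math.floor(duration * frame_rate)) + 1
    return np.arange(n) / frame_rate


def _integrate_frames(deriv, y0: np.ndarray, frame_t: np.ndarray,
                      dt: float, breakpoints=()) -> np.ndarray:
    """RK4 with substeps landing exactly on each frame time and on every
    derivative breakpoint (no interpolation); returns the state per frame."""
    y = np.asarray(y0, dtype=float)
    out = np.empty((len(frame_t), len(y)))
    out[0] = y
    bps = sorted(b for b in breakpoints
                 if frame_t[0] < b < frame_t[-1])
    t = frame_t[0]
    for i in range(1, len(frame_t)):
        stops = [b for b in bps if t < b < frame_t[i]] + [frame_t[i]]
        for stop in stops:
            span = stop - t
            nsub = max(int(math.ceil(span / dt - 1e-12)), 1)
            h = span / nsub
            for _ in range(nsub):
                k1 = deriv(t, y)
                k2 = deriv(t + 0.5 * h, y + 0.5 * h * k1)
                k3 = deriv(t + 0.5 * h, y + 0.5 * h * k2)
                k4 = deriv(t + h, y + h * k3)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
            t = stop
        out[i] = y
    return out


def _rot_z(psi: float) -> np.ndarray:
    c, s = math.cos(psi), math.sin(psi)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def simulate_linear_trial(
    body: BodyParams,
    jet: JetProfile,
    noise_sd: float = 0.0,
    seed: int | None = None,
    duration: float = 8.0,
    frame_rate: float = FRAME_RATE,
    initial_velocity: float = 0.0,
    lateral_drift: float = 0.0,
    dt: float = 1e-3,
) -> TrackedTrial:
    """Simulate a horizontal jetting/coasting trial.

    The jet axis is world +x (the robot travels backwards along its jet).
    ``noise_sd`` is the per-axis Gaussian tracking noise in metres;
    ``initial_velocity`` (m/s) allows pure-coasting trials.
    """
    m_eff = body.effective_mass_kg
    kq = body.drag_factor
    f_buoy = body.buoyancy_imbalance_g * 1e-3 * G_MPS2  # N, + up

    def deriv(t, y):
        _, vx, _, vz = y
        ax = (jet.thrust(t) - kq * vx * abs(vx)) / m_eff
        az = (f_buoy - kq * vz * abs(vz)) / m_eff
        return np.array([vx, ax, vz, az])

    ft = _frame_times(duration, frame_rate)
    states = _integrate_frames(
        deriv, np.array([0.0, initial_velocity, 0.0, 0.0]), ft, dt,
        breakpoints=jet.breakpoints())
    centers = np.column_stack([states[:, 0], lateral_drift * ft, states[:, 2]])

    offs = np.asarray(body.tracking_point_offsets_cm, dtype=float) * 1e-2  # m
    amp = math.radians(body.rocking_amplitude_deg)
    om = 2.0 * math.pi * body.rocking_frequency_hz
    p1 = np.empty_like(centers)
    p2 = np.empty_like(centers)
    for i, t in enumerate(ft):
        phi = amp * math.sin(om * t)
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])  # pitch
        p1[i] = centers[i] + rot @ offs[0]
        p2[i] = centers[i] + rot @ offs[1]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p1 = p1 + rng.normal(0.0, noise_sd, p1.shape)
        p2 = p2 + rng.normal(0.0, noise_sd, p2.shape)
    motor = np.array([jet.motor_on(t) for t in ft])
    gt = {
        "kind": "linear",
        "body": asdict(body),
        "jet": asdict(jet),
        "noise_sd_m": noise_sd,
        "seed": seed,
        "initial_velocity_mps": initial_velocity,
    }
    return TrackedTrial(ft, p1, p2, motor, frame_rate, gt)


def simulate_yaw_trial(
    body: BodyParams,
    jet: JetProfile,
    noise_sd: float = 0.0,
    seed: int | None = None,
    duration: float = 10.0,
    frame_rate: float = FRAME_RATE,
    dt: float = 1e-3,
) -> TrackedTrial:
    """Simulate a yaw-maneuverability trial (top-down view).

    The hyponome's 90-degree elbow turns the jet into a torque about the
    vertical axis; the body spins counter-clockwise (positive) viewed from
    above, rotating the two tracking points rigidly about the body centre.
    """
    izz = body.izz_kgm2
    tau_arm = body.lever_arm_m
    c_rot = body.rotational_drag_nms2

    def deriv(t, y):
        _, w = y
        alpha = (jet.thrust(t) * tau_arm - c_rot * w * abs(w)) / izz
        return np.array([w, alpha])

    ft = _frame_times(duration, frame_rate)
    states = _integrate_frames(deriv, np.zeros(2), ft, dt,
                               breakpoints=jet.breakpoints())

    offs = np.asarray(body.tracking_point_offsets_cm, dtype=float) * 1e-2
    p1 = np.empty((len(ft), 3))
    p2 = np.empty((len(ft), 3))
    for i in range(len(ft)):
        rot = _rot_z(states[i, 0])
        p1[i] = rot @ offs[0]
        p2[i] = rot @ offs[1]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p1 = p1 + rng.normal(0.0, noise_sd, p1.shape)
        p2 = p2 + rng.normal(0.0, noise_sd, p2.shape)
    motor = np.array([jet.motor_on(t) for t in ft])
    gt = {
        "kind": "yaw",
        "body": asdict(body),
        "jet": asdict(jet),
        "noise_sd_m": noise_sd,
        "seed": seed,
    }
    return TrackedTrial(ft, p1, p2, motor, frame_rate, gt)


# ----------------------------------------------------------------------------
# fixture suite
# ----------------------------------------------------------------------------
def _sphere_area(radius_cm: float = 7.5) -> float:
    return math.pi * radius_cm ** 2


#: study-condition parameter sets for the four morphotypes: drag
#: coefficients as reported for the robots (oxycone lowest ~0.14,
#: sphaerocone highest ~0.61, serpenticone/center ~0.5); frontal areas
#: scaled by section compression; compressed flanks resist yaw strongly
#: (high rotational drag), sphere-like bodies spin freely.
MORPHOTYPE_BODIES = {
    "serpenticone": BodyParams(
        name="serpenticone", drag_coefficient=0.5,
        frontal_area_cm2=0.45 * _sphere_area(), added_mass_coefficient=0.2,
        rotational_drag_nms2=1.8e-2, lever_arm_cm=9.0,
        rocking_amplitude_deg=4.0),
    "oxycone": BodyParams(
        name="oxycone", drag_coefficient=0.14,
        frontal_area_cm2=0.30 * _sphere_area(), added_mass_coefficient=0.2,
        rotational_drag_nms2=2.2e-2, lever_arm_cm=9.0,
        rocking_amplitude_deg=3.0),
    "sphaerocone": BodyParams(
        name="sphaerocone", drag_coefficient=0.61,
        frontal_area_cm2=_sphere_area(), added_mass_coefficient=0.5,
        rotational_drag_nms2=3e-4, lever_arm_cm=7.5,
        rocking_amplitude_deg=5.0),
    "center": BodyParams(
        name="center", drag_coefficient=0.5,
        frontal_area_cm2=0.75 * _sphere_area(), added_mass_coefficient=0.4,
        rotational_drag_nms2=8e-4, lever_arm_cm=7.5,
        rocking_amplitude_deg=5.0),
}

COMPRESSED = ("serpenticone", "oxycone")
INFLATED = ("sphaerocone", "center")


def make_fixture_suite(
    outdir,
    seed: int = 0,
    n_linear: int = 9,
    n_yaw: int = 15,
    noise_sd: float = 0.003,
    morphotypes=tuple(MORPHOTYPE_BODIES),
) -> dict:
    """Emit a full synthetic trial suite with a manifest.

    Per morphotype: ``n_linear`` single-pulse linear trials and ``n_yaw``
    yaw trials (matching the pool campaign's trial counts), plus demo conch
    specs and a demo robot mass budget.  Regeneration with the same seed is
    bit-identical; different seeds redraw the noise but share ground truth.
    """
    from .conch import demo_spec

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = {"seed": seed, "noise_sd_m": noise_sd, "frame_rate": FRAME_RATE,
                "trials": [], "specs": [], "budgets": []}
    jet = JetProfile()
    for morph in morphotypes:
        body = MORPHOTYPE_BODIES[morph]
        for i in range(n_linear):
            sub = int(rng.integers(0, 2 ** 31 - 1))
            trial = simulate_linear_trial(
                body, jet, noise_sd=noise_sd, seed=sub,
                lateral_drift=float(rng.normal(0.0, 0.005)),
            )
            path = outdir / f"{morph}_linear_{i:02d}.csv"
            trial.to_csv(path)
            manifest["trials"].append(
                {"file": path.name, "kind": "linear", "morphotype": morph,
                 "seed": sub})
        for i in range(n_yaw):
            sub = int(rng.integers(0, 2 ** 31 - 1))
            trial = simulate_yaw_trial(body, jet, noise_sd=noise_sd, seed=sub)
            path = outdir / f"{morph}_yaw_{i:02d}.csv"
            trial.to_csv(path)
            manifest["trials"].append(
                {"file": path.name, "kind": "yaw", "morphotype": morph,
                 "seed": sub})
        spec = demo_spec(morph)
        spath = outdir / f"{morph}_spec.json"
        spath.write_text(spec.to_json())
        manifest["specs"].append(spath.name)
        (outdir / f"{morph}_body.json").write_text(
            json.dumps(asdict(body), indent=2))
    # a demo robot budget (placeholder bulk masses for electronics/motor)
    from .robot import MassBudget, MassComponent, solve_budget

    budget = MassBudget(
        components=[
            MassComponent("electronics_cartridge", 120.0, (1.0, 0.0, 1.5)),
            MassComponent("motor", 60.0, (-2.0, 0.0, -1.0)),
            MassComponent("battery_7v4", 90.0, (2.5, 0.0, 0.5)),
            MassComponent("battery_3v7", 25.0, (2.0, 0.0, 1.0)),
            MassComponent("counterweight", 180.0, (0.0, 0.0, -4.0),
                          movable=True),
            MassComponent("trim_liquid", 9.0, (0.0, 0.0, -2.0)),
        ],
        displaced_mass=982.0,
        target_center=np.array([0.0, 0.0, -0.5]),
    )
    solve_budget(budget)
    bpath = outdir / "demo_budget.json"
    bpath.write_text(budget.to_json())
    manifest["budgets"].append(bpath.name)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
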