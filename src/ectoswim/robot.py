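"""Biomimetic-robot mass-budget design.

A self-propelled replica of a conch must be neutrally buoyant and hold the
same static orientation as the virtual hydrostatic model while packing a
motor, batteries, electronics, trim liquid, and a dense counterweight.  The
3D-printed thermoplastic (PETG) body is the free variable: its mass is
whatever closes the buoyancy budget, and its centre of mass is placed so the
full component assembly reproduces the target centre of mass:

    D_PETG = (M * m_total - sum_i D_i m_i) / m_PETG

per axis, where the first product runs over the total mass (PETG included)
and the sum over the fixed components only -- the algebraically consistent
reading, guaranteed by the round-trip property that the mass-weighted mean
over all components returns the target M.

A bismuth counterweight is then lowered to exaggerate hydrostatic stability
(pulling the z component of the mass centre down while leaving the
horizontal components untouched), decoupling trial kinematics from the
animal's own thrust-angle sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .hydro import total_center_of_mass, stability_index

__all__ = [
    "MassComponent",
    "MassBudget",
    "petg_mass_for_neutrality",
    "petg_center",
    "solve_budget",
    "place_counterweight",
    "compare_inertia",
]

PETG = "petg"


@dataclass
class MassComponent:
    """One robot part: a mass at a local centre, optionally solvable.

    Fixed parts (motor, batteries, electronics, trim liquid) are immutable
    during solving; the PETG body and the counterweight are movable.
    ``izz_local`` is the part's own moment about a vertical axis through its
    centre (g cm^2), used for composite moments of inertia; point masses
    leave it 0.
    """

    name: str
    mass: float
    center: np.ndarray
    movable: bool = False
    izz_local: float = 0.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.mass < 0:
            raise ValueError(f"component {self.name!r} has negative mass")


@dataclass
class MassBudget:
    """Component table plus the targets the solved robot must meet.

    ``displaced_mass`` (g) comes from the scaled virtual model;
    ``target_center`` is the virtual model's total centre of mass.
    """

    components: list
    displaced_mass: float
    target_center: np.ndarray
    solved: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.target_center = np.asarray(self.target_center, dtype=float).reshape(3)
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")

    def component(self, name: str) -> MassComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def fixed_components(self) -> list:
        return [c for c in self.components if c.name != PETG]

    def total_mass(self) -> float:
        return sum(c.mass for c in self.components)

    def center_of_mass(self) -> np.ndarray:
        return total_center_of_mass([(c.mass, c.center) for c in self.components])

    # serialisation --------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "displaced_mass_g": self.displaced_mass,
                "target_center_cm": self.target_center.tolist(),
                "solved": self.solved,
                "components": [
                    {**asdict(c), "center": c.center.tolist()}
                    for c in self.components
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MassBudget":
        d = json.loads(text)
        comps = [MassComponent(**c) for c in d["components"]]
        return cls(comps, d["displaced_mass_g"],
                   np.asarray(d["target_center_cm"]), d.get("solved", False))

    @classmethod
    def load(cls, path) -> "MassBudget":
        return cls.from_json(Path(path).read_text())


def petg_mass_for_neutrality(budget: MassBudget) -> float:
    """PETG mass closing the buoyancy budget: displaced mass minus the mass
    of every other component."""
    other = sum(c.mass for c in budget.fixed_components)
    m = budget.displaced_mass - other
    if m <= 0:
        raise ValueError(
            f"components too heavy for neutral buoyancy: fixed mass {other:.1f} g "
            f">= displaced {budget.displaced_mass:.1f} g"
        )
    return m


def petg_center(budget: MassBudget, petg_mass: float | None = None) -> np.ndarray:
    """PETG centre placement reproducing the target centre of mass.

    Per axis: ``D = (M * m_total - sum_fixed D_i m_i) / m_PETG`` with
    ``m_total`` the full (PETG-inclusive) mass; the mass-weighted mean over
    all components then returns the target exactly.
    """
    if petg_mass is None:
        petg_mass = petg_mass_for_neutrality(budget)
    if petg_mass <= 1e-12:
        raise ValueError("PETG mass ~ 0: centre of mass indeterminate")
    m_total = sum(c.mass for c in budget.fixed_components) + petg_mass
    fixed_sum = sum(c.mass * c.center for c in budget.fixed_components)
    return (budget.target_center * m_total - fixed_sum) / petg_mass


def solve_budget(budget: MassBudget) -> MassBudget:
    """Solve (or re-solve) the PETG mass and centre in place; idempotent."""
    m = petg_mass_for_neutrality(budget)
    center = petg_center(budget, m)
    try:
        petg = budget.component(PETG)
        petg.mass, petg.center = m, center
    except KeyError:
        budget.components.append(
            MassComponent(PETG, m, center, movable=True)
        )
    budget.solved = True
    return budget


def place_counterweight(
    budget: MassBudget,
    name: str,
    target_st: float,
    buoyancy_center,
    displaced_volume: float,
    z_min: float | None = None,
) -> np.ndarray:
    """Lower a counterweight to reach a target stability index.

    Only the counterweight's z is adjusted, so the horizontal components of
    the total centre of mass are untouched; the resulting mass centre sits
    the required distance below the buoyancy centre.  Raises if the hull
    floor ``z_min`` stops the counterweight short, reporting the maximum
    attainable index.
    """
    cw = budget.component(name)
    B = np.asarray(buoyancy_center, dtype=float)
    if cw.mass == 0.0:
        return cw.center
    m_total = budget.total_mass()
    others_z = sum(c.mass * c.center[2] for c in budget.components
                   if c.name != name)
    # require M_z = B_z - target_st * V^(1/3) (mass centre below buoyancy)
    mz_req = B[2] - target_st * displaced_volume ** (1.0 / 3.0)
    z = (mz_req * m_total - others_z) / cw.mass
    if z_min is not None and z < z_min:
        mz_best = (others_z + cw.mass * z_min) / m_total
        st_best = stability_index(B, [B[0], B[1], mz_best], displaced_volume)
        raise ValueError(
            f"hull too shallow: counterweight bottoms out at z={z_min:.2f} cm "
            f"with St={st_best:.4f} < target {target_st:.4f}"
        )
    cw.center = np.array([cw.center[0], cw.center[1], z])
    return cw.center


def composite_izz(components, pivot) -> float:
    """Moment of inertia about the vertical axis through ``pivot`` (g cm^2);
    additive over components via the parallel-axis theorem."""
    pivot = np.asarray(pivot, dtype=float)
    total = 0.0
    for c in components:
        d = c.center[:2] - pivot[:2]
        total += c.izz_local + c.mass * float(d @ d)
    return total


def compare_inertia(
    robot_budget: MassBudget,
    animal_components,
    pivot,
    torque_ncm: float = 0.0,
    duration_s: float = 1.0,
):
    """Compare robot and animal moments of inertia about the shared vertical
    axis, and the vacuum yaw each would reach under a constant torque.

    ``torque_ncm`` is in N cm; angular velocities are rad/s.  In water,
    hydrodynamic resistance dominates: observed 1-s yaw rates run about an
    order of magnitude below these vacuum values.
    """
    izz_robot = composite_izz(robot_budget.components, pivot)
    izz_animal = composite_izz(animal_components, pivot)
    if izz_animal <= 0 or izz_robot <= 0:
        raise ValueError("moments of inertia must be positive")
    out = {
        "izz_robot_gcm2": izz_robot,
        "izz_animal_gcm2": izz_animal,
        "ratio_robot_over_animal": izz_robot / izz_animal,
    }
    if torque_ncm:
        tau = torque_ncm * 1e5  # N cm -> g cm^2 / s^2
        out["omega_vacuum_robot_rad_s"] = tau * duration_s / izz_robot
        out["omega_vacuum_animal_rad_s"] = tau * duration_s / izz_animal
    return out
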