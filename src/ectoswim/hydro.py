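"""Hydrostatics of multi-component conch models.

An ectocochleate cephalopod is neutrally buoyant when its organismal mass
(soft body + shell + chamber contents) equals the mass of the water it
displaces.  The chamber-content mix of cameral liquid and gas that satisfies
this condition is solved in closed form; the centres of buoyancy and mass
then give the hydrostatic stability index, the resting (apertural)
orientation, and the thrust angle of the hyponome.

The printed chamber-fill formula

    Phi = (R - rho_cl) / (rho_cg - rho_cl),
    R   = (V_wd rho_wd - V_sb rho_sb - V_sh rho_sh) / V_ct

evaluates to the *gas* fraction of the total chamber volume (Phi = 0 when
the chambers must be all liquid, Phi = 1 when all gas); its complement
``1 - Phi`` is the liquid fraction.  Both readings are carried explicitly in
:class:`ChamberFill` so reports can state which complement they quote.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .mesh import TriMesh, centroid, signed_volume
from .conch import ConchModel

__all__ = [
    "DensityTable",
    "HydrostaticModel",
    "ChamberFill",
    "HydrostaticResult",
    "chamber_fill_fraction",
    "total_center_of_mass",
    "stability_index",
    "apertural_orientation",
    "thrust_angle",
    "scale_to_displaced_mass",
    "compute_hydrostatics",
    "fit_body_chamber",
    "model_from_conch",
]


@dataclass
class DensityTable:
    """Material densities, g/cm^3 (defaults for Nautilus-like tissue and
    shell, seawater cameral liquid, and near-vacuum cameral gas)."""

    soft_body: float = 1.049
    shell: float = 2.54
    cameral_liquid: float = 1.025
    cameral_gas: float = 0.001
    water_displaced: float = 1.025

    def __post_init__(self):
        vals = asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("densities must be positive")
        if self.cameral_gas >= self.cameral_liquid:
            raise ValueError("cameral gas must be less dense than cameral liquid")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def load(cls, path) -> "DensityTable":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class HydrostaticModel:
    """Named component meshes with resolved densities.

    ``components`` maps names to ``(TriMesh, density)``; it must include a
    ``water_displaced`` envelope and a ``cameral`` chamber-space mesh.
    ``hyponome_point`` marks the ventral edge of the aperture.
    """

    components: dict
    hyponome_point: np.ndarray
    aperture_direction: np.ndarray

    def volume(self, name: str) -> float:
        return signed_volume(self.components[name][0])


def model_from_conch(conch: ConchModel, densities: DensityTable) -> HydrostaticModel:
    """Assemble a hydrostatic model from a generated conch (septa are shell
    material and are merged into the shell component for mass purposes)."""
    from .conch import _concatenate

    shell_parts = [conch.shell] + list(conch.septa)
    shell = _concatenate(shell_parts, name="shell")
    return HydrostaticModel(
        components={
            "shell": (shell, densities.shell),
            "soft_body": (conch.soft_body, densities.soft_body),
            "cameral": (conch.cameral_volumes, None),  # split liquid/gas later
            "water_displaced": (conch.water_displaced, densities.water_displaced),
        },
        hyponome_point=np.asarray(conch.hyponome_point, dtype=float),
        aperture_direction=np.asarray(conch.aperture_direction, dtype=float),
    )


# ----------------------------------------------------------------------------
# chamber fill
# ----------------------------------------------------------------------------
@dataclass
class ChamberFill:
    """Chamber-content solution for neutral buoyancy.

    ``phi`` follows the printed formula and is the gas fraction of the total
    chamber volume; ``liquid_fraction`` is its complement.  ``residual`` is
    the organismal-minus-displaced mass when ``phi`` is substituted back
    (zero by construction).  ``attainable`` is False when neutral buoyancy
    would need a fill outside [0, 1] at this geometry.
    """

    phi: float
    liquid_fraction: float
    residual: float
    attainable: bool
    residual_density: float

    def __post_init__(self):
        assert abs(self.phi + self.liquid_fraction - 1.0) < 1e-15


def chamber_fill_fraction(
    v_wd: float, v_sb: float, v_sh: float, v_ct: float,
    densities: DensityTable | None = None,
) -> ChamberFill:
    """Solve the chamber gas/liquid split that makes the model neutrally
    buoyant (volumes in cm^3)."""
    d = densities or DensityTable()
    if v_ct <= 0:
        raise ValueError("total chamber volume must be positive")
    R = (v_wd * d.water_displaced - v_sb * d.soft_body - v_sh * d.shell) / v_ct
    phi = (R - d.cameral_liquid) / (d.cameral_gas - d.cameral_liquid)
    organismal = (
        v_sb * d.soft_body + v_sh * d.shell
        + v_ct * (phi * d.cameral_gas + (1.0 - phi) * d.cameral_liquid)
    )
    residual = organismal - v_wd * d.water_displaced
    return ChamberFill(
        phi=phi,
        liquid_fraction=1.0 - phi,
        residual=residual,
        attainable=bool(0.0 <= phi <= 1.0),
        residual_density=R,
    )


def total_center_of_mass(components) -> np.ndarray:
    """Mass-weighted mean of component centres.

    ``components`` is an iterable of ``(mass, center)`` pairs; the mean is
    applied independently per axis.
    """
    masses = np.array([m for m, _ in components], dtype=float)
    centers = np.array([np.asarray(c, dtype=float) for _, c in components])
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    return (masses[:, None] * centers).sum(axis=0) / total


def stability_index(B, M, volume: float) -> float:
    """Hydrostatic stability St = |B - M| / V^(1/3) (dimensionless)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return float(np.linalg.norm(np.asarray(B, float) - np.asarray(M, float))
                 / volume ** (1.0 / 3.0))


# ----------------------------------------------------------------------------
# equilibrium orientation
# ----------------------------------------------------------------------------
def _equilibrium_rotation(B: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Rotation matrix bringing the buoyancy centre vertically above the
    mass centre (the smallest such rotation; ties broken by identity)."""
    d = np.asarray(B, float) - np.asarray(M, float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("B and M coincide; equilibrium orientation undefined")
    d = d / norm
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(d, z)
    s = np.linalg.norm(axis)
    c = float(d @ z)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any horizontal axis
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def apertural_orientation(aperture_direction, B, M) -> float:
    """Apertural angle (degrees) at hydrostatic equilibrium.

    The model is first rotated so B sits vertically above M; the angle of
    the aperture-facing direction from horizontal is then reported: 0 means
    a horizontally facing soft body, +90 upward-facing, -90 downward-facing.
    """
    Rmat = _equilibrium_rotation(B, M)
    a = Rmat @ (np.asarray(aperture_direction, float)
                / np.linalg.norm(aperture_direction))
    return math.degrees(math.asin(np.clip(a[2], -1.0, 1.0)))


def thrust_angle(hyponome_point, B, M) -> float:
    """Thrust angle (degrees) of the hyponome at equilibrium.

    Measured from the hyponome (ventral edge of the aperture) to the
    midpoint of the hydrostatic centres, with respect to the horizontal.
    0 is idealized horizontal backward jetting; +90 and -90 transmit energy
    most efficiently into downward and upward movement respectively (jet
    reaction acts from the hyponome toward the midpoint, so a hyponome
    *above* the midpoint drives the animal downward).
    """
    Rmat = _equilibrium_rotation(B, M)
    B = Rmat @ np.asarray(B, float)
    M = Rmat @ np.asarray(M, float)
    hyp = Rmat @ np.asarray(hyponome_point, float)
    mid = 0.5 * (B + M)
    d = hyp - mid
    horiz = math.hypot(d[0], d[1])
    if horiz < 1e-15 and abs(d[2]) < 1e-15:
        raise ValueError("hyponome coincides with the hydrostatic midpoint")
    return math.degrees(math.atan2(d[2], horiz))


# ----------------------------------------------------------------------------
# full pipeline on a conch model
# ----------------------------------------------------------------------------
@dataclass
class HydrostaticResult:
    phi: float
    liquid_fraction: float
    attainable: bool
    B: np.ndarray
    M: np.ndarray
    St: float
    apertural_angle: float
    thrust_angle: float
    total_mass: float
    displaced_mass: float
    volumes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "phi_gas_fraction": self.phi,
            "liquid_fraction": self.liquid_fraction,
            "attainable": self.attainable,
            "center_of_buoyancy_cm": list(self.B),
            "center_of_mass_cm": list(self.M),
            "stability_index": self.St,
            "apertural_angle_deg": self.apertural_angle,
            "thrust_angle_deg": self.thrust_angle,
            "total_mass_g": self.total_mass,
            "displaced_mass_g": self.displaced_mass,
            "volumes_cm3": self.volumes,
            "note": ("phi_gas_fraction follows the printed fill formula and is "
                     "the gas fraction of chamber volume; liquid_fraction is "
                     "its complement"),
        }
        return json.dumps(d, indent=2)


def compute_hydrostatics(model: HydrostaticModel,
                         densities: DensityTable | None = None) -> HydrostaticResult:
    """Solve neutral buoyancy and derive every hydrostatic quantity.

    The chamber contents (liquid and gas) share a single centre -- the
    centre of volume of all chambers -- a minor simplification relative to
    the capillary retention of liquid around septal margins in life.
    """
    d = densities or DensityTable()
    sh, _ = model.components["shell"]
    sb, _ = model.components["soft_body"]
    ct, _ = model.components["cameral"]
    wd, _ = model.components["water_displaced"]
    v_sh, v_sb = signed_volume(sh), signed_volume(sb)
    v_ct, v_wd = signed_volume(ct), signed_volume(wd)
    fill = chamber_fill_fraction(v_wd, v_sb, v_sh, v_ct, d)
    chamber_density = fill.phi * d.cameral_gas + (1 - fill.phi) * d.cameral_liquid
    parts = [
        (v_sh * d.shell, centroid(sh)),
        (v_sb * d.soft_body, centroid(sb)),
        (v_ct * chamber_density, centroid(ct)),
    ]
    M = total_center_of_mass(parts)
    B = centroid(wd)
    St = stability_index(B, M, v_wd)
    total_mass = sum(m for m, _ in parts)
    return HydrostaticResult(
        phi=fill.phi,
        liquid_fraction=fill.liquid_fraction,
        attainable=fill.attainable,
        B=B,
        M=M,
        St=St,
        apertural_angle=apertural_orientation(model.aperture_direction, B, M),
        thrust_angle=thrust_angle(model.hyponome_point, B, M),
        total_mass=total_mass,
        displaced_mass=v_wd * d.water_displaced,
        volumes={"shell": v_sh, "soft_body": v_sb, "cameral": v_ct,
                 "water_displaced": v_wd},
    )


def scale_to_displaced_mass(conch: ConchModel, target_mass: float,
                            densities: DensityTable | None = None):
    """Uniformly scale a conch so the displaced water mass equals
    ``target_mass`` grams; returns ``(scaled_model, factor)``.  The
    stability index is scale-invariant and unchanged."""
    d = densities or DensityTable()
    if target_mass <= 0:
        raise ValueError("target mass must be positive")
    v_wd = signed_volume(conch.water_displaced)
    factor = (target_mass / (d.water_displaced * v_wd)) ** (1.0 / 3.0)
    return conch.scaled(factor), factor


# ----------------------------------------------------------------------------
# body-chamber solver
# ----------------------------------------------------------------------------
def _liquid_fraction_fast(spec, surfaces, v_outer, grid, vcum, angle,
                          densities) -> float:
    """Liquid fraction at a candidate body-chamber angle, from cumulative
    cavity volumes (no meshing)."""
    import dataclasses

    from .conch import _septa_layout

    trial = dataclasses.replace(spec, body_chamber_angle=angle)
    theta_bc = spec.theta_max - angle
    v_cavity = vcum[-1]
    v_sb = v_cavity - np.interp(theta_bc, grid, vcum)
    v_septa = 0.0
    records = _septa_layout(trial)
    for rec in records:
        sec = surfaces.inner_section(rec.theta)
        x, y = sec[:, 0], sec[:, 1]
        area = abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        v_septa += area * rec.thickness
    # the final septum's concave face bulges adapically by its dome depth;
    # the soft body fills that bulge (volume A * depth / 2 for the
    # parabolic cap profile), at the phragmocone's expense
    sec = surfaces.inner_section(records[0].theta)
    x, y = sec[:, 0], sec[:, 1]
    a_bc = abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    bulge = 0.5 * a_bc * records[0].dome_depth
    v_sb += bulge
    v_ct = np.interp(theta_bc, grid, vcum) - v_septa - bulge
    v_sh = v_outer - v_cavity + v_septa
    fill = chamber_fill_fraction(v_outer, v_sb, v_sh, v_ct, densities)
    return fill.liquid_fraction


def _mesh_liquid_fraction(spec, angle: float, d: DensityTable) -> float:
    """Exact liquid fraction from a full mesh build at one candidate angle."""
    import dataclasses

    from .conch import build_conch_model

    trial = dataclasses.replace(spec, body_chamber_angle=angle)
    v = build_conch_model(trial).component_volumes()
    fill = chamber_fill_fraction(v["water_displaced"], v["soft_body"],
                                 v["shell"], v["cameral"], d)
    return fill.liquid_fraction


def fit_body_chamber(spec, phi_target: float = 0.12, tol: float = 0.005,
                     densities: DensityTable | None = None,
                     max_iter: int = 60):
    """Solve the body-chamber angle giving a target chamber liquid fraction.

    Bisects on the body-chamber angle until the neutral-buoyancy liquid
    fraction of the phragmocone equals ``phi_target`` within ``tol``
    (Nautilus retains roughly 12% cameral liquid).  Returns
    ``(angle_deg, achieved_fraction)``, with the fraction measured on the
    final mesh model at the returned angle.

    The bracketing search evaluates candidate angles with a fast
    cumulative-volume integral of the cavity (no meshing); the root is then
    polished with secant steps on exact mesh volumes.
    """
    import dataclasses

    d = densities or DensityTable()
    from .conch import generate_conch

    base = dataclasses.replace(spec, body_chamber_angle=spec.septal_spacing_deg)
    surfaces = generate_conch(base)
    grid, vcum = surfaces.cavity_volume_cumulative()
    v_outer = signed_volume(surfaces.outer_mesh())

    lo = spec.septal_spacing_deg * 1.5
    hi = spec.theta_max - spec.septal_spacing_deg * 3.0
    f = lambda a: _liquid_fraction_fast(spec, surfaces, v_outer, grid, vcum, a, d)
    f_lo, f_hi = f(lo), f(hi)
    # liquid fraction decreases with body-chamber angle
    if not (min(f_lo, f_hi) - tol <= phi_target <= max(f_lo, f_hi) + tol):
        raise ValueError(
            f"target liquid fraction {phi_target} unattainable within the "
            f"spiral extent: bracket [{f_hi:.4f}, {f_lo:.4f}] at angles "
            f"[{lo:.1f}, {hi:.1f}] deg"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - phi_target) <= 0.2 * tol:
            break
        if (f_mid - phi_target) * (f_lo - phi_target) > 0:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    angle = 0.5 * (lo + hi)

    # polish on exact mesh volumes (secant; the response is near-linear)
    a0, a1 = angle, angle
    g0 = _mesh_liquid_fraction(spec, a0, d)
    if abs(g0 - phi_target) <= tol:
        return a0, g0
    slope = (f(angle + 5.0) - f(angle - 5.0)) / 10.0
    for _ in range(6):
        a1 = a0 - (g0 - phi_target) / slope
        a1 = float(np.clip(a1, spec.septal_spacing_deg * 1.5,
                           spec.theta_max - spec.septal_spacing_deg * 3.0))
        g1 = _mesh_liquid_fraction(spec, a1, d)
        if abs(g1 - phi_target) <= tol or abs(a1 - a0) < 1e-6:
            return a1, g1
        slope = (g1 - g0) / (a1 - a0)
        a0, g0 = a1, g1
    return a1, g1
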