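"""Theoretical planispiral conch generation.

A conch is grown as a logarithmic spiral in the x-z plane (coiling axis along
*y*): a closed whorl section is replicated at small angular steps, each copy
rotated about the coiling axis and scaled so the venter radius expands by the
whorl-expansion factor ``W`` per 360 degrees.  Successive sections are lofted
into a single tessellated tube; an inward-offset copy of each section builds
the internal shell interface, so the shell wall thickness is a fixed fraction
of the inner whorl height.  Septa are placed at a constant angular spacing,
partitioning the phragmocone cavity into chambers; the remaining adapertural
tube is the soft body.  The outer tube doubles as the water-displaced
envelope used for buoyancy.

Where an involute section would cut into the previous whorl, its dorsal
vertices are clamped radially onto the previous whorl's venter (the
impression zone of real ammonoids).  This keeps every emitted surface free of
self-intersection, so volumes of the spiral tube and of its partition into
chambers, septa, and soft body are additive to machine precision.

Septum shape: real septa are domed, sutured surfaces.  Here each septum is a
thin lofted slice of the whorl tube whose two faces carry a configurable
spherical-cap concavity (bulging adapically); hydrostatic quantities are
dominated by septal thickness and volume, not suture geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .mesh import TriMesh, signed_volume, validate_watertight

__all__ = [
    "ConchSpec",
    "ConchSurfaces",
    "ConchModel",
    "MorphospacePoint",
    "generate_whorl_section",
    "generate_conch",
    "insert_septa",
    "partition_soft_body",
    "build_conch_model",
    "conch_measurements",
    "westermann_coordinates",
    "demo_spec",
    "DEMO_MORPHOTYPES",
]

_EPS = 1e-9


# ----------------------------------------------------------------------------
# specification
# ----------------------------------------------------------------------------
@dataclass
class ConchSpec:
    """Parametric description of a planispiral conch.

    Parameters
    ----------
    expansion_per_rev : float
        Whorl-height expansion factor ``W`` per full revolution; > 1.
    umbilical_exposure : float
        Fraction of the previous whorl height left exposed (0 = fully
        involute, -> 1 = whorls barely touching, serpenticone-like).
    inflation : float
        Section breadth / section height.
    total_revolutions : float
        Number of revolutions from the initial section to the aperture.
    body_chamber_angle : float
        Degrees of spiral occupied by the soft body, measured back from the
        aperture.
    shell_thickness_ratio, septal_thickness_ratio : float
        Wall / septum thickness as a fraction of the inner whorl height
        (venter-to-previous-venter distance).
    septal_spacing_deg : float
        Angular spacing between consecutive septa.
    section_exponent : float
        Superellipse exponent of the default whorl section (2 = ellipse).
    section_polyline : (k, 2) array, optional
        Imported whorl-section outline (radial, lateral); overrides the
        superellipse.  Normalised to unit height on input.
    ontogeny_segments : list of (start_deg, end_deg, overrides)
        Piecewise overrides of ``expansion_per_rev`` / ``umbilical_exposure``
        / ``inflation`` over angular intervals, for allometric coiling.
    step_deg : float
        Angular tessellation step; must divide 360.
    n_section_points : int
        Vertices per whorl section ring.
    septal_concavity : float
        Depth of the septal dome as a fraction of half the section height
        (0 = flat discs).
    """

    expansion_per_rev: float = 2.0
    umbilical_exposure: float = 0.3
    inflation: float = 1.0
    total_revolutions: float = 3.5
    body_chamber_angle: float = 280.0
    shell_thickness_ratio: float = 0.031
    septal_thickness_ratio: float = 0.021
    septal_spacing_deg: float = 23.0
    section_exponent: float = 2.5
    section_polyline: np.ndarray | None = None
    ontogeny_segments: list = field(default_factory=list)
    step_deg: float = 1.0
    n_section_points: int = 64
    septal_concavity: float = 0.3
    name: str = "conch"

    def __post_init__(self) -> None:
        if self.expansion_per_rev <= 1.0:
            raise ValueError("expansion_per_rev must be > 1")
        if not (0.0 <= self.umbilical_exposure < 1.0):
            raise ValueError("umbilical_exposure must be in [0, 1)")
        for r in (self.shell_thickness_ratio, self.septal_thickness_ratio):
            if not (0.0 < r < 0.2):
                raise ValueError("thickness ratios must lie in (0, 0.2)")
        if self.inflation <= 0.05:
            raise ValueError("inflation must be positive")
        if abs(360.0 / self.step_deg - round(360.0 / self.step_deg)) > 1e-9:
            raise ValueError("step_deg must divide 360")
        if self.n_section_points < 8 or self.n_section_points % 2:
            raise ValueError("n_section_points must be an even number >= 8")
        if self.body_chamber_angle < 0 or self.body_chamber_angle > self.theta_max:
            raise ValueError("body_chamber_angle exceeds the spiral extent")
        if self.section_polyline is not None:
            self.section_polyline = _normalize_polyline(
                np.asarray(self.section_polyline, dtype=float)
            )

    @property
    def theta_max(self) -> float:
        return 360.0 * self.total_revolutions

    # piecewise ontogeny ---------------------------------------------------
    def _param(self, key: str, theta: float) -> float:
        val = getattr(self, key)
        for start, end, over in self.ontogeny_segments:
            if start <= theta < end and key in over:
                val = over[key]
        return float(val)

    def W(self, theta: float) -> float:
        return self._param("expansion_per_rev", theta)

    def u(self, theta: float) -> float:
        return self._param("umbilical_exposure", theta)

    def infl(self, theta: float) -> float:
        return self._param("inflation", theta)

    # radii ----------------------------------------------------------------
    def venter_radius(self, theta: float) -> float:
        """Venter (outermost) radius at spiral angle ``theta`` (degrees),
        with r = 1 at theta = 0; piecewise-exponential in the ontogeny."""
        if not self.ontogeny_segments:
            return float(self.expansion_per_rev ** (theta / 360.0))
        # integrate log-expansion across override breakpoints
        brk = sorted({0.0, theta} | {
            b for s in self.ontogeny_segments for b in s[:2] if 0.0 < b < theta
        })
        logr = 0.0
        for a, b in zip(brk[:-1], brk[1:]):
            logr += math.log(self.W(0.5 * (a + b))) * (b - a) / 360.0
        return math.exp(logr)

    def whorl_height(self, theta: float) -> float:
        W, u = self.W(theta), self.u(theta)
        return self.venter_radius(theta) * (W - 1.0) / (W - (1.0 - u))

    def inner_whorl_height(self, theta: float) -> float:
        """Venter-to-previous-venter distance, the thickness reference."""
        rv = self.venter_radius(theta)
        if theta >= 360.0:
            return rv - self.venter_radius(theta - 360.0)
        return rv * (1.0 - 1.0 / self.W(theta))

    # serialisation ----------------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        if d["section_polyline"] is not None:
            d["section_polyline"] = np.asarray(d["section_polyline"]).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConchSpec":
        d = json.loads(text)
        if d.get("section_polyline") is not None:
            d["section_polyline"] = np.asarray(d["section_polyline"], dtype=float)
        d["ontogeny_segments"] = [tuple(s) for s in d.get("ontogeny_segments", [])]
        return cls(**d)

    @classmethod
    def load(cls, path) -> "ConchSpec":
        return cls.from_json(Path(path).read_text())


def _normalize_polyline(pts: np.ndarray) -> np.ndarray:
    """Centre an imported section outline and scale it to unit height."""
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("section_polyline must be (k, 2) with k >= 4")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    try:
        from shapely.geometry import LinearRing

        if not LinearRing(pts).is_valid:
            raise ValueError("section_polyline is self-intersecting")
    except ImportError:  # pragma: no cover
        pass
    height = pts[:, 0].max() - pts[:, 0].min()
    if height <= 0:
        raise ValueError("section_polyline has zero height")
    center = np.array(
        [0.5 * (pts[:, 0].max() + pts[:, 0].min()),
         0.5 * (pts[:, 1].max() + pts[:, 1].min())]
    )
    return (pts - center) / height


def _resample_closed(pts: np.ndarray, n: int) -> np.ndarray:
    """Arc-length resampling of a closed polyline to ``n`` points, starting
    from the point of maximum first coordinate (the venter)."""
    start = int(np.argmax(pts[:, 0]))
    pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


# ----------------------------------------------------------------------------
# whorl sections
# ----------------------------------------------------------------------------
def generate_whorl_section(spec: ConchSpec, angle_deg: float) -> np.ndarray:
    """Closed planar whorl-section outline at a given ontogenetic angle.

    Returns an (n, 2) array of (radial, lateral) coordinates in the section
    plane, centred radially on the whorl-tube axis at ``angle_deg`` and
    scaled to the local whorl height; unclamped (pure section shape).
    """
    h = spec.whorl_height(angle_deg)
    c = spec.venter_radius(angle_deg) - 0.5 * h
    n = spec.n_section_points
    if spec.section_polyline is not None:
        pts = _resample_closed(spec.section_polyline * h, n)
        pts[:, 0] += c
        return pts
    b = spec.infl(angle_deg) * h
    p = spec.section_exponent
    t = 2.0 * np.pi * np.arange(n) / n
    ct, st = np.cos(t), np.sin(t)
    dr = 0.5 * h * np.sign(ct) * np.abs(ct) ** (2.0 / p)
    y = 0.5 * b * np.sign(st) * np.abs(st) ** (2.0 / p)
    return np.column_stack([c + dr, y])


def _prev_venter_branch(spec: ConchSpec, theta: float, y: np.ndarray) -> np.ndarray:
    """Outer (venter-side) radius of the previous whorl at lateral offsets
    ``y``; -inf where the previous whorl does not extend laterally."""
    tp = theta - 360.0
    hp = spec.whorl_height(tp)
    cp = spec.venter_radius(tp) - 0.5 * hp
    if spec.section_polyline is not None:
        sec = generate_whorl_section(spec, tp)
        upper = sec[sec[:, 0] >= cp - _EPS]
        order = np.argsort(upper[:, 1])
        r = np.interp(y, upper[order, 1], upper[order, 0],
                      left=-np.inf, right=-np.inf)
        r[np.abs(y) > np.abs(upper[:, 1]).max()] = -np.inf
        return r
    bp = spec.infl(tp) * hp
    p = spec.section_exponent
    frac = np.abs(2.0 * y / bp)
    r = np.full_like(y, -np.inf, dtype=float)
    inside = frac < 1.0
    r[inside] = cp + 0.5 * hp * (1.0 - frac[inside] ** p) ** (1.0 / p)
    return r


def _clamped_section(spec: ConchSpec, theta: float) -> np.ndarray:
    """Whorl section with dorsal vertices clamped onto the previous whorl's
    venter (impression zone); identical to the raw section for the first
    revolution."""
    sec = generate_whorl_section(spec, theta)
    if theta < 360.0:
        return sec
    limit = _prev_venter_branch(spec, theta, sec[:, 1])
    clamped = np.maximum(sec[:, 0], limit)
    depth = np.max(clamped - sec[:, 0])
    h = spec.whorl_height(theta)
    if depth > 0.85 * h:
        raise ValueError(
            f"whorl section at {theta:.1f} deg overlaps the previous whorl over "
            f"{depth / h:.0%} of its height; adjust umbilical_exposure or "
            "expansion_per_rev"
        )
    sec = sec.copy()
    sec[:, 0] = clamped
    return sec


def _offset_inward(sec: np.ndarray, t: float) -> np.ndarray:
    """Offset a closed CCW section polygon inward by ``t`` along vertex
    normals (miter-free; adequate for smooth convex-ish sections)."""
    nxt = np.roll(sec, -1, axis=0)
    prv = np.roll(sec, 1, axis=0)
    e1 = sec - prv
    e2 = nxt - sec
    # inward normal of a CCW polygon edge (dx, dy) is (-dy, dx)
    n1 = np.column_stack([-e1[:, 1], e1[:, 0]])
    n2 = np.column_stack([-e2[:, 1], e2[:, 0]])
    n1 /= np.maximum(np.linalg.norm(n1, axis=1, keepdims=True), 1e-300)
    n2 /= np.maximum(np.linalg.norm(n2, axis=1, keepdims=True), 1e-300)
    n = n1 + n2
    norm = np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)
    n /= norm
    return sec + t * n


def _ring3d(sec: np.ndarray, theta: float) -> np.ndarray:
    th = math.radians(theta)
    er = np.array([math.cos(th), 0.0, math.sin(th)])
    ey = np.array([0.0, 1.0, 0.0])
    return sec[:, :1] * er + sec[:, 1:2] * ey


def _tangent(spec: ConchSpec, theta: float) -> np.ndarray:
    """Unit tangent of the whorl-tube axis, pointing adaperturally."""
    th = math.radians(theta)
    h = spec.whorl_height(theta)
    c = spec.venter_radius(theta) - 0.5 * h
    dc = c * math.log(spec.W(theta)) / 360.0  # per degree
    er = np.array([math.cos(th), 0.0, math.sin(th)])
    et = np.array([-math.sin(th), 0.0, math.cos(th)])
    t = dc * er + c * (math.pi / 180.0) * et
    return t / np.linalg.norm(t)


# ----------------------------------------------------------------------------
# lofting machinery
# ----------------------------------------------------------------------------
@dataclass
class _Cap:
    """End-cap description: dome displacement direction and depth (0 = flat
    fan).  Identical parameters yield bit-identical vertices, so two
    segments sharing a boundary close against exactly the same surface."""

    depth: float = 0.0
    dome_dir: np.ndarray | None = None
    n_radial: int = 3


def _cap_geometry(ring: np.ndarray, cap: _Cap):
    """Concentric cap rings (excluding the boundary ring) plus apex point."""
    center = ring.mean(axis=0)
    disp = np.zeros(3) if cap.dome_dir is None else cap.dome_dir * cap.depth
    fracs = np.linspace(1.0, 0.0, cap.n_radial + 2)[1:-1]
    rings = [center + (ring - center) * s + disp * (1.0 - s * s) for s in fracs]
    apex = center + disp
    return rings, apex


def _loft_mesh(rings, cap_a: _Cap, cap_b: _Cap, name: str = "") -> TriMesh:
    """Watertight, outward-oriented loft through ``rings`` with end caps."""
    n = rings[0].shape[0]
    verts = [np.concatenate(rings, axis=0)]
    nv = len(rings) * n
    faces = []

    def band(i0, i1, flip=False):
        k = np.arange(n)
        k1 = (k + 1) % n
        a, b, c, d = i0 + k, i0 + k1, i1 + k1, i1 + k
        if flip:
            tri = np.concatenate(
                [np.column_stack([a, c, b]), np.column_stack([a, d, c])], axis=0
            )
        else:
            tri = np.concatenate(
                [np.column_stack([a, b, c]), np.column_stack([a, c, d])], axis=0
            )
        faces.append(tri)

    for m in range(len(rings) - 1):
        band(m * n, (m + 1) * n)

    def add_cap(ring_offset, ring_pts, cap, flip):
        nonlocal nv
        cap_rings, apex = _cap_geometry(ring_pts, cap)
        prev = ring_offset
        for cr in cap_rings:
            verts.append(cr)
            band(prev, nv, flip=flip)
            prev = nv
            nv += n
        verts.append(apex[None, :])
        k = np.arange(n)
        k1 = (k + 1) % n
        if flip:
            tri = np.column_stack([prev + k, np.full(n, nv), prev + k1])
        else:
            tri = np.column_stack([prev + k, prev + k1, np.full(n, nv)])
        faces.append(tri)
        nv += 1

    # cap at the start ring faces backwards (flip), at the end ring forwards
    add_cap(0, rings[0], cap_a, flip=True)
    add_cap((len(rings) - 1) * n, rings[-1], cap_b, flip=False)

    mesh = TriMesh(np.concatenate(verts, axis=0), np.concatenate(faces, axis=0),
                   name=name)
    if mesh.as_trimesh().volume < 0:
        mesh = mesh.inverted()
    return mesh


def _shell_wall_mesh(outer_rings, inner_rings, name: str = "shell") -> TriMesh:
    """Solid shell wall: outer loft + inverted inner loft + end annuli."""
    n = outer_rings[0].shape[0]
    m = len(outer_rings)
    verts = np.concatenate(outer_rings + inner_rings, axis=0)
    faces = []
    k = np.arange(n)
    k1 = (k + 1) % n

    def band(i0, i1, flip=False):
        a, b, c, d = i0 + k, i0 + k1, i1 + k1, i1 + k
        if flip:
            faces.append(np.column_stack([a, c, b]))
            faces.append(np.column_stack([a, d, c]))
        else:
            faces.append(np.column_stack([a, b, c]))
            faces.append(np.column_stack([a, c, d]))

    off = m * n
    for i in range(m - 1):
        band(i * n, (i + 1) * n)               # outer, outward
        band(off + i * n, off + (i + 1) * n, flip=True)  # inner, inward
    band(0, off, flip=True)                     # apex annulus
    band((m - 1) * n, off + (m - 1) * n)        # aperture annulus
    mesh = TriMesh(verts, np.concatenate(faces, axis=0), name=name)
    if mesh.as_trimesh().volume < 0:
        mesh = mesh.inverted()
    return mesh


# ----------------------------------------------------------------------------
# conch assembly
# ----------------------------------------------------------------------------
class ConchSurfaces:
    """Outer and inner shell surfaces on a shared angular grid.

    Rings at arbitrary angles are computed analytically and cached, so
    segment meshes built later (septa, chambers, soft body) close against
    bit-identical boundary rings.
    """

    def __init__(self, spec: ConchSpec, extra_angles=()):
        self.spec = spec
        base = np.arange(0.0, spec.theta_max + 0.5 * spec.step_deg, spec.step_deg)
        base[-1] = spec.theta_max
        grid = np.concatenate([base, np.asarray(list(extra_angles), dtype=float)])
        grid = np.unique(np.round(grid, 9))
        grid = grid[(grid >= -_EPS) & (grid <= spec.theta_max + _EPS)]
        self.grid = grid
        self._outer: dict[float, np.ndarray] = {}
        self._inner: dict[float, np.ndarray] = {}

    def _key(self, theta: float) -> float:
        return round(float(theta), 9)

    def outer_section(self, theta: float) -> np.ndarray:
        return _clamped_section(self.spec, theta)

    def inner_section(self, theta: float) -> np.ndarray:
        sec = self.outer_section(theta)
        t = self.spec.shell_thickness_ratio * self.spec.inner_whorl_height(theta)
        return _offset_inward(sec, t)

    def outer_ring(self, theta: float) -> np.ndarray:
        k = self._key(theta)
        if k not in self._outer:
            self._outer[k] = _ring3d(self.outer_section(k), k)
        return self._outer[k]

    def inner_ring(self, theta: float) -> np.ndarray:
        k = self._key(theta)
        if k not in self._inner:
            self._inner[k] = _ring3d(self.inner_section(k), k)
        return self._inner[k]

    def grid_between(self, a: float, b: float) -> np.ndarray:
        inside = self.grid[(self.grid > a + _EPS) & (self.grid < b - _EPS)]
        return np.concatenate([[a], inside, [b]])

    # meshes ---------------------------------------------------------------
    def outer_mesh(self, name: str = "water_displaced") -> TriMesh:
        rings = [self.outer_ring(t) for t in self.grid]
        return _loft_mesh(rings, _Cap(), _Cap(), name=name)

    def cavity_mesh(self, name: str = "cavity") -> TriMesh:
        rings = [self.inner_ring(t) for t in self.grid]
        return _loft_mesh(rings, _Cap(), _Cap(), name=name)

    def shell_mesh(self, name: str = "shell") -> TriMesh:
        outer = [self.outer_ring(t) for t in self.grid]
        inner = [self.inner_ring(t) for t in self.grid]
        return _shell_wall_mesh(outer, inner, name=name)

    def inner_segment(self, a: float, b: float, cap_a: _Cap, cap_b: _Cap,
                      name: str) -> TriMesh:
        thetas = self.grid_between(a, b)
        rings = [self.inner_ring(t) for t in thetas]
        return _loft_mesh(rings, cap_a, cap_b, name=name)

    # fast volume integrals (Pappus), used by the body-chamber solver -------
    def cavity_volume_cumulative(self):
        """Cumulative internal-cavity volume along the grid (theta -> V)."""
        areas, radii = [], []
        for t in self.grid:
            sec = self.inner_section(t)
            x, y = sec[:, 0], sec[:, 1]
            a2 = x * np.roll(y, -1) - np.roll(x, -1) * y
            area = 0.5 * np.sum(a2)
            cx = np.sum((x + np.roll(x, -1)) * a2) / (6.0 * area)
            areas.append(abs(area))
            radii.append(cx)
        areas = np.asarray(areas)
        radii = np.asarray(radii)
        dtheta = np.diff(self.grid) * math.pi / 180.0
        slabs = 0.5 * (areas[:-1] * radii[:-1] + areas[1:] * radii[1:]) * dtheta
        return self.grid, np.concatenate([[0.0], np.cumsum(slabs)])


@dataclass
class SeptumRecord:
    index: int
    theta: float          # adapertural face angle
    theta_lo: float       # adapical face angle
    thickness: float      # cm, along the whorl-tube axis
    dome_depth: float
    dome_dir: np.ndarray


def _septa_layout(spec: ConchSpec) -> list[SeptumRecord]:
    """Angular placement of every septum, adaperturally to adapically."""
    theta_bc = spec.theta_max - spec.body_chamber_angle
    if spec.body_chamber_angle < spec.septal_spacing_deg:
        raise ValueError("body chamber shorter than one septal spacing")
    records = []
    j = 0
    while True:
        s = theta_bc - j * spec.septal_spacing_deg
        h = spec.whorl_height(s) if s > 0 else 0.0
        c = spec.venter_radius(s) - 0.5 * h if s > 0 else 0.0
        if s <= 0 or c <= 0:
            break
        t_s = spec.septal_thickness_ratio * spec.inner_whorl_height(s)
        delta = math.degrees(t_s / c)
        # leave a workable apical chamber rather than a sliver at the apex
        if s - delta <= 0.25 * spec.septal_spacing_deg:
            break
        chamber_arc = c * math.radians(max(spec.septal_spacing_deg - delta, 0.0))
        depth = min(spec.septal_concavity * 0.5 * h, 0.4 * chamber_arc)
        records.append(
            SeptumRecord(j, s, s - delta, t_s, depth, -_tangent(spec, s))
        )
        j += 1
    if not records:
        raise ValueError("no septum fits adapically of the body chamber")
    # the dome of each septum bulges into its adapical chamber; cap the depth
    # by that chamber's actual angular extent so it never punches through
    for i, rec in enumerate(records):
        lo_bound = records[i + 1].theta if i + 1 < len(records) else 0.0
        extent = rec.theta_lo - lo_bound
        h = spec.whorl_height(rec.theta)
        c = spec.venter_radius(rec.theta) - 0.5 * h
        rec.dome_depth = min(rec.dome_depth, 0.4 * c * math.radians(extent))
    return records


def generate_conch(spec: ConchSpec, extra_angles=()) -> ConchSurfaces:
    """Build the outer and inner shell surfaces for a spec.

    ``extra_angles`` inserts additional section rings (septum faces, the
    body-chamber boundary) into the loft so that later partitions close
    against rings already present in the tube tessellation.
    """
    return ConchSurfaces(spec, extra_angles=extra_angles)


def insert_septa(surfaces: ConchSurfaces):
    """Septum meshes and chamber (cameral void) meshes.

    Returns ``(septa, chambers, records)``; chambers are ordered adapically
    (the first contains the apex).
    """
    spec = surfaces.spec
    records = _septa_layout(spec)
    septa, chambers = [], []
    for rec in records:
        cap_lo = _Cap(rec.dome_depth, rec.dome_dir)
        cap_hi = _Cap(rec.dome_depth, rec.dome_dir)
        septa.append(
            surfaces.inner_segment(rec.theta_lo, rec.theta, cap_lo, cap_hi,
                                   name=f"septum_{rec.index}")
        )
    # chambers: apex cap -> first septum, then between consecutive septa
    ordered = list(reversed(records))  # adapical first
    lo = 0.0
    lo_cap = _Cap()
    for i, rec in enumerate(ordered):
        chambers.append(
            surfaces.inner_segment(lo, rec.theta_lo, lo_cap,
                                   _Cap(rec.dome_depth, rec.dome_dir),
                                   name=f"chamber_{i}")
        )
        lo = rec.theta
        lo_cap = _Cap(rec.dome_depth, rec.dome_dir)
    return septa, chambers, records


def partition_soft_body(surfaces: ConchSurfaces,
                        body_chamber_angle: float | None = None) -> TriMesh:
    """Soft-body mesh filling the shell tube adapertural of the last septum."""
    spec = surfaces.spec
    if body_chamber_angle is None:
        body_chamber_angle = spec.body_chamber_angle
    if body_chamber_angle < 0 or body_chamber_angle > spec.theta_max:
        raise ValueError("body_chamber_angle exceeds the spiral extent")
    if body_chamber_angle == 0.0:
        return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int),
                       name="soft_body")
    theta_bc = spec.theta_max - body_chamber_angle
    if theta_bc <= 0:
        return surfaces.cavity_mesh(name="soft_body")
    records = _septa_layout(spec) if body_chamber_angle == spec.body_chamber_angle \
        else None
    if records is not None and abs(records[0].theta - theta_bc) < 1e-6:
        rec = records[0]
        cap = _Cap(rec.dome_depth, rec.dome_dir)
    else:
        cap = _Cap()
    return surfaces.inner_segment(theta_bc, spec.theta_max, cap, _Cap(),
                                  name="soft_body")


# ----------------------------------------------------------------------------
# assembled model
# ----------------------------------------------------------------------------
@dataclass
class ConchModel:
    """Named component meshes of one theoretical conch."""

    spec: ConchSpec
    shell: TriMesh
    septa: list
    soft_body: TriMesh
    cameral_volumes: TriMesh
    water_displaced: TriMesh
    body_chamber_angle: float
    hyponome_point: np.ndarray
    aperture_direction: np.ndarray
    n_chambers: int

    def component_volumes(self) -> dict:
        return {
            "shell": signed_volume(self.shell)
            + sum(signed_volume(s) for s in self.septa),
            "soft_body": signed_volume(self.soft_body),
            "cameral": signed_volume(self.cameral_volumes),
            "water_displaced": signed_volume(self.water_displaced),
        }

    def scaled(self, factor: float) -> "ConchModel":
        return ConchModel(
            spec=self.spec,
            shell=self.shell.scaled(factor),
            septa=[s.scaled(factor) for s in self.septa],
            soft_body=self.soft_body.scaled(factor),
            cameral_volumes=self.cameral_volumes.scaled(factor),
            water_displaced=self.water_displaced.scaled(factor),
            body_chamber_angle=self.body_chamber_angle,
            hyponome_point=self.hyponome_point * factor,
            aperture_direction=self.aperture_direction.copy(),
            n_chambers=self.n_chambers,
        )


def build_conch_model(spec: ConchSpec) -> ConchModel:
    """Generate every component mesh for a spec (deterministic)."""
    records = _septa_layout(spec)
    theta_bc = spec.theta_max - spec.body_chamber_angle
    extra = [theta_bc] + [r.theta for r in records] + [r.theta_lo for r in records]
    surfaces = generate_conch(spec, extra_angles=extra)
    septa, chambers, _ = insert_septa(surfaces)
    soft = partition_soft_body(surfaces)
    shell = surfaces.shell_mesh()
    outer = surfaces.outer_mesh()
    cameral = _concatenate(chambers, name="cameral_volumes")
    # hyponome: ventral (venter) edge of the aperture
    ring = surfaces.outer_ring(spec.theta_max)
    hyponome = ring[0].copy()
    return ConchModel(
        spec=spec,
        shell=shell,
        septa=septa,
        soft_body=soft,
        cameral_volumes=cameral,
        water_displaced=outer,
        body_chamber_angle=spec.body_chamber_angle,
        hyponome_point=hyponome,
        aperture_direction=_tangent(spec, spec.theta_max),
        n_chambers=len(chambers),
    )


def _concatenate(meshes, name: str = "") -> TriMesh:
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += len(m.vertices)
    return TriMesh(np.concatenate(verts, axis=0), np.concatenate(faces, axis=0),
                   name=name)


# ----------------------------------------------------------------------------
# Westermann morphospace
# ----------------------------------------------------------------------------
@dataclass
class MorphospacePoint:
    """Normalised ternary coordinates in the Westermann morphospace.

    Corners: high whorl expansion (oxycone), high umbilical exposure
    (serpenticone), high conch inflation (sphaerocone).
    """

    w_exp: float
    u_exp: float
    th_infl: float

    def __post_init__(self):
        total = self.w_exp + self.u_exp + self.th_infl
        if abs(total - 1.0) > 1e-9:
            raise ValueError("ternary coordinates must sum to 1")
        if min(self.w_exp, self.u_exp, self.th_infl) < -1e-12:
            raise ValueError("ternary coordinates must be non-negative")

    def as_tuple(self):
        return (self.w_exp, self.u_exp, self.th_infl)


def westermann_coordinates(diameter: float, umbilical_diameter: float,
                           apertural_height: float,
                           apertural_breadth: float) -> MorphospacePoint:
    """Place a conch in the Westermann morphospace from four measurements.

    The raw indices are dimensionless ratios: expansion ``2*ah/D`` (apertural
    height relative to the conch radius), exposure ``U/D``, and inflation
    ``b/D``; the ternary point is their normalisation to unit sum.  This is
    the package's documented operationalisation of the morphospace, chosen so
    that the three classical end-members each maximise their own corner.
    """
    D, U, ah, ab = diameter, umbilical_diameter, apertural_height, apertural_breadth
    if min(D, ah, ab) <= 0 or U < 0:
        raise ValueError("measurements must be positive (umbilicus >= 0)")
    if U >= D:
        raise ValueError("umbilical diameter must be smaller than the diameter")
    if ah > D or ab > 2 * D:
        raise ValueError("non-physical apertural measurements")
    raw = np.array([2.0 * ah / D, U / D, ab / D])
    raw = raw / raw.sum()
    return MorphospacePoint(*raw)


def conch_measurements(spec: ConchSpec) -> dict:
    """Classical conch measurements (diameter, umbilical diameter, apertural
    height and breadth) evaluated analytically from the spiral parameters."""
    tm = spec.theta_max
    rv = spec.venter_radius(tm)
    rv_back = spec.venter_radius(tm - 180.0)
    h = spec.whorl_height(tm)
    rd = rv - h
    rd_back = rv_back - spec.whorl_height(tm - 180.0)
    return {
        "diameter": rv + rv_back,
        "umbilical_diameter": max(rd + rd_back, 0.0),
        "apertural_height": h,
        "apertural_breadth": spec.infl(tm) * h,
    }


# ----------------------------------------------------------------------------
# demonstration morphotypes
# ----------------------------------------------------------------------------
DEMO_MORPHOTYPES = ("serpenticone", "oxycone", "sphaerocone", "center")

_DEMO_PARAMS = {
    # evolute, compressed, many slowly expanding whorls
    "serpenticone": dict(expansion_per_rev=1.7, umbilical_exposure=0.85,
                         inflation=0.9, total_revolutions=4.0,
                         body_chamber_angle=330.0, section_exponent=2.0),
    # involute, strongly compressed, fast expansion
    "oxycone": dict(expansion_per_rev=2.8, umbilical_exposure=0.05,
                    inflation=0.45, total_revolutions=3.0,
                    body_chamber_angle=240.0, section_exponent=2.2),
    # involute, globular, breadth exceeding height
    "sphaerocone": dict(expansion_per_rev=1.9, umbilical_exposure=0.1,
                        inflation=2.2, total_revolutions=3.0,
                        body_chamber_angle=270.0, section_exponent=2.0),
    # intermediate in every index
    "center": dict(expansion_per_rev=2.0, umbilical_exposure=0.35,
                   inflation=1.1, total_revolutions=3.25,
                   body_chamber_angle=280.0, section_exponent=2.2),
}


def demo_spec(morphotype: str, step_deg: float = 2.0,
              n_section_points: int = 48) -> ConchSpec:
    """Bundled spec approximating one of the four study morphotypes.

    These are qualitative stand-ins placed in the appropriate region of the
    Westermann morphospace, not reconstructions of the figured specimens.
    """
    if morphotype not in _DEMO_PARAMS:
        raise KeyError(f"unknown morphotype {morphotype!r}; "
                       f"choose from {DEMO_MORPHOTYPES}")
    return ConchSpec(name=morphotype, step_deg=step_deg,
                     n_section_points=n_section_points,
                     **_DEMO_PARAMS[morphotype])
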