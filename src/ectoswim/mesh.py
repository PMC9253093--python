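"""Triangle-mesh primitives and integral properties.

All downstream stages (conch generation, hydrostatics, robot design, drag
reference areas) consume the :class:`TriMesh` container defined here.  Units
are fixed package-wide as centimetres, grams, and seconds; densities are
g/cm**3.  The coordinate frame is right-handed with *z* vertically up and the
planispiral coiling axis along *y*.

Integral properties (signed volume, centre of volume, inertia tensor) are
exact surface integrals over the triangulation via the divergence theorem,
delegated to :mod:`trimesh`; meshes must be closed, consistently wound
2-manifolds for these to be meaningful, which :func:`validate_watertight`
diagnoses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "InertiaResult",
    "WatertightReport",
    "NonWatertightError",
    "signed_volume",
    "centroid",
    "inertia_tensor",
    "validate_watertight",
    "load_mesh",
    "save_mesh",
]

#: triangles with area below this (cm^2) are dropped before integration
DEGENERATE_AREA_TOL = 1e-12


class NonWatertightError(ValueError):
    """Raised when an integral property is requested of an open mesh."""


@dataclass
class TriMesh:
    """A triangle surface mesh with an optional density tag.

    Parameters
    ----------
    vertices : (n, 3) float array, cm
    faces : (m, 3) int array
        0-based vertex index triples, counter-clockwise when viewed from
        outside for an outward-oriented surface.
    name : str
        Component label (e.g. ``"shell"``, ``"soft_body"``).
    density : float or None
        Material density in g/cm**3, if the mesh represents a solid of
        uniform density.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    density: float | None = None
    degenerate_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces):
            areas = _face_areas(self.vertices, self.faces)
            keep = areas > DEGENERATE_AREA_TOL
            self.degenerate_dropped = int((~keep).sum())
            if self.degenerate_dropped:
                self.faces = self.faces[keep]

    # -- conversions ------------------------------------------------------
    def as_trimesh(self) -> _trimesh.Trimesh:
        """Backing :class:`trimesh.Trimesh`; ``process=False`` preserves
        vertex order and winding (hence volume sign)."""
        return _trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(
        cls, mesh: _trimesh.Trimesh, name: str = "", density: float | None = None
    ) -> "TriMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), name, density)

    # -- convenience ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.name, self.density)

    def transformed(self, matrix: np.ndarray) -> "TriMesh":
        """Apply a 4x4 homogeneous transform and return a new mesh."""
        matrix = np.asarray(matrix, dtype=float)
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        return TriMesh(v, self.faces.copy(), self.name, self.density)

    def scaled(self, factor: float, origin=(0.0, 0.0, 0.0)) -> "TriMesh":
        origin = np.asarray(origin, dtype=float)
        v = (self.vertices - origin) * factor + origin
        return TriMesh(v, self.faces.copy(), self.name, self.density)

    def inverted(self) -> "TriMesh":
        """Flip every face winding (reverses orientation / volume sign)."""
        return TriMesh(self.vertices.copy(), self.faces[:, ::-1].copy(),
                       self.name, self.density)


@dataclass
class InertiaResult:
    """Mass, centre, and second moments of a uniform-density solid.

    ``tensor`` is the 3x3 inertia tensor about ``center`` (g cm^2);
    ``izz_vertical`` is the moment about the vertical (*z*) axis through the
    requested pivot, obtained by the parallel-axis theorem.
    """

    mass: float
    center: np.ndarray
    tensor: np.ndarray
    izz_vertical: float

    @property
    def principal_moments(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.tensor)


@dataclass
class WatertightReport:
    """Diagnostics from :func:`validate_watertight`."""

    boundary_edges: list
    nonmanifold_edges: list
    inconsistent_edges: int
    degenerate_dropped: int
    inward_oriented: bool

    @property
    def passed(self) -> bool:
        return (
            not self.boundary_edges
            and not self.nonmanifold_edges
            and self.inconsistent_edges == 0
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "n_boundary_edges": len(self.boundary_edges),
                "boundary_edges": [list(map(int, e)) for e in self.boundary_edges[:50]],
                "n_nonmanifold_edges": len(self.nonmanifold_edges),
                "nonmanifold_edges": [
                    list(map(int, e)) for e in self.nonmanifold_edges[:50]
                ],
                "inconsistent_edges": self.inconsistent_edges,
                "degenerate_dropped": self.degenerate_dropped,
                "inward_oriented": self.inward_oriented,
            },
            indent=2,
        )


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    return 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )


def validate_watertight(mesh: TriMesh) -> WatertightReport:
    """Report open boundaries, non-manifold edges, and winding consistency.

    A mesh passes iff every undirected edge is shared by exactly two faces
    with opposite winding.  Purely diagnostic: never raises.
    """
    faces = mesh.faces
    if len(faces) == 0:
        return WatertightReport([], [], 0, mesh.degenerate_dropped, False)
    # directed edges per face
    directed = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    und = np.sort(directed, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    boundary = [tuple(e) for e in uniq[counts == 1]]
    nonmanifold = [tuple(e) for e in uniq[counts > 2]]
    # winding: each undirected edge with count 2 must appear once per direction
    duniq, dcounts = np.unique(directed, axis=0, return_counts=True)
    inconsistent = int((dcounts > 1).sum())
    inward = False
    if not boundary and not nonmanifold and inconsistent == 0:
        inward = bool(mesh.as_trimesh().volume < 0)
    return WatertightReport(
        boundary, nonmanifold, inconsistent, mesh.degenerate_dropped, inward
    )


def _require_closed(mesh: TriMesh) -> None:
    report = validate_watertight(mesh)
    if report.boundary_edges or report.nonmanifold_edges or report.inconsistent_edges:
        raise NonWatertightError(
            f"mesh {mesh.name!r} is not a closed oriented manifold: "
            f"{len(report.boundary_edges)} boundary edge(s) "
            f"{report.boundary_edges[:8]}, "
            f"{len(report.nonmanifold_edges)} non-manifold edge(s), "
            f"{report.inconsistent_edges} inconsistently wound edge pair(s)"
        )


def signed_volume(mesh: TriMesh) -> float:
    """Signed enclosed volume (cm^3); positive for outward orientation."""
    _require_closed(mesh)
    return float(mesh.as_trimesh().volume)


def centroid(mesh: TriMesh) -> np.ndarray:
    """Centre of volume of the enclosed solid (not the surface), cm."""
    _require_closed(mesh)
    return np.asarray(mesh.as_trimesh().center_mass, dtype=float)


def inertia_tensor(
    mesh: TriMesh,
    density: float | None = None,
    pivot: np.ndarray | None = None,
) -> InertiaResult:
    """Mass properties of the uniform solid bounded by ``mesh``.

    Parameters
    ----------
    density : g/cm^3; falls back to the mesh's own tag.
    pivot : point the vertical (*z*) axis passes through for
        ``izz_vertical``; defaults to the centroid.
    """
    if density is None:
        density = mesh.density
    if density is None or density <= 0:
        raise ValueError("positive density required (argument or mesh tag)")
    _require_closed(mesh)
    tm = mesh.as_trimesh()
    tm.density = float(density)
    mass = float(tm.mass)
    center = np.asarray(tm.center_mass, dtype=float)
    tensor = np.asarray(tm.moment_inertia, dtype=float)  # about center_mass
    tensor = 0.5 * (tensor + tensor.T)
    if pivot is None:
        pivot = center
    pivot = np.asarray(pivot, dtype=float)
    d = center[:2] - pivot[:2]
    izz = float(tensor[2, 2] + mass * (d @ d))
    return InertiaResult(mass=mass, center=center, tensor=tensor, izz_vertical=izz)


def load_mesh(path, name: str | None = None, density: float | None = None) -> TriMesh:
    """Read an STL/PLY/OBJ file into a :class:`TriMesh`."""
    path = Path(path)
    tm = _trimesh.load_mesh(str(path), process=False)
    if isinstance(tm, _trimesh.Scene):  # OBJ files may load as scenes
        tm = tm.to_mesh()
    tm.merge_vertices()  # STL stores a triangle soup
    return TriMesh.from_trimesh(tm, name=name or path.stem, density=density)


def save_mesh(mesh: TriMesh, path) -> None:
    """Write STL/PLY/OBJ, format chosen by extension."""
    mesh.as_trimesh().export(str(path))
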