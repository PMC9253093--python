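import dataclasses

import numpy as np
import pytest
import trimesh

from ectoswim.conch import ConchSpec, build_conch_model, demo_spec
from ectoswim.mesh import TriMesh


@pytest.fixture
def unit_cube() -> TriMesh:
    """Axis-aligned unit cube with corner at the origin."""
    box = trimesh.creation.box(extents=(1, 1, 1))
    m = TriMesh.from_trimesh(box, name="cube")
    m.vertices = m.vertices + 0.5
    return m


@pytest.fixture
def icosphere():
    def make(radius=1.0, subdivisions=4, center=(0, 0, 0)) -> TriMesh:
        s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        m = TriMesh.from_trimesh(s, name="sphere")
        m.vertices = m.vertices + np.asarray(center, dtype=float)
        return m

    return make


@pytest.fixture(scope="session")
def coarse_spec() -> ConchSpec:
    """A fast serpenticone-like spec for mesh-heavy tests."""
    return ConchSpec(
        expansion_per_rev=1.8,
        umbilical_exposure=0.7,
        inflation=0.9,
        total_revolutions=3.0,
        body_chamber_angle=280.0,
        step_deg=3.0,
        n_section_points=24,
        name="coarse_serp",
    )


@pytest.fixture(scope="session")
def coarse_model(coarse_spec):
    return build_conch_model(coarse_spec)


@pytest.fixture(scope="session")
def demo_serpenticone_model():
    return build_conch_model(demo_spec("serpenticone"))
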