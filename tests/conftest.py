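"""Shared fixtures: small grids, phantoms and a session-wide template set.

Everything is generated programmatically; expensive artifacts (the
sex-specific templates built by registration) are session-scoped so the
segmentation, pipeline and acceptance tests share one build.
"""

import numpy as np
import pytest

from rsnrspect import (
    CohortPopulation,
    Grid,
    PhantomSpec,
    Volume3D,
    build_templates,
    make_lv_phantom,
    simulate_template_normals,
)

GRID48 = Grid((48, 48, 48), (4.0, 4.0, 4.0))
GRID40 = Grid((40, 40, 40), (4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def grid48() -> Grid:
    return GRID48


@pytest.fixture(scope="session")
def base_spec48() -> PhantomSpec:
    return PhantomSpec(grid=GRID48)


@pytest.fixture(scope="session")
def population48(base_spec48) -> CohortPopulation:
    return CohortPopulation(base_spec=base_spec48)


@pytest.fixture(scope="session")
def study_templates(population48):
    """Sex-specific templates built from 10 separate normals per sex."""
    normals = simulate_template_normals(10, population48, seed=421)
    return build_templates(normals)


@pytest.fixture(scope="session")
def noisefree_phantom(base_spec48):
    """Canonical-pose phantom without counting noise (variance-0 mode)."""
    from dataclasses import replace

    spec = replace(base_spec48, noise="none", seed=7)
    return make_lv_phantom(spec, stress_pose=spec.pose)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def random_volume(rng) -> Volume3D:
    grid = Grid((12, 10, 8), (4.0, 4.0, 4.0), (-10.0, 0.0, 5.0))
    return Volume3D(rng.uniform(0.0, 50.0, size=grid.dims), grid)
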