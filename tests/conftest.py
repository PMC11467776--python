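"""Shared fixtures: a coarse desk-scale phantom, plan and fluence setup."""

from __future__ import annotations

import numpy as np
import pytest

from geodose import (
    BeamGeometry,
    FluenceGrid,
    OracleConfig,
    PhantomSpec,
    VolumeGrid,
    control_points_to_fluence_maps,
    generate_phantom,
    generate_plan,
)


@pytest.fixture(scope="session")
def toy_grid() -> VolumeGrid:
    """32x32x8 voxels at 20x20x10 mm: 640 mm transverse extent so the
    300 mm encoding ring fits inside the volume."""
    return VolumeGrid(origin=(-310.0, -310.0, -35.0),
                      spacing=(20.0, 20.0, 10.0), dims=(32, 32, 8))


@pytest.fixture(scope="session")
def geometry() -> BeamGeometry:
    return BeamGeometry(sad=1000.0, plane_distance=300.0, angular_spacing=10.0)


@pytest.fixture(scope="session")
def fm_grid() -> FluenceGrid:
    return FluenceGrid(pixel_spacing=5.0, fov=200.0)


@pytest.fixture(scope="session")
def oracle_cfg() -> OracleConfig:
    return OracleConfig(mu_eff=0.005, lateral_sigma=20.0, beamlet_spacing=5.0)


@pytest.fixture(scope="session")
def phantom(toy_grid):
    spec = PhantomSpec(grid=toy_grid, seed=42)
    red, masks = generate_phantom(spec)
    return spec, red, masks


@pytest.fixture(scope="session")
def toy_plan(phantom, toy_grid, geometry, fm_grid):
    _, _, masks = phantom
    return generate_plan(masks, geometry, n_arcs=1, seed=5,
                         grid=toy_grid, fm_grid=fm_grid)


@pytest.fixture(scope="session")
def toy_fms(toy_plan, geometry, fm_grid):
    return control_points_to_fluence_maps(toy_plan, geometry, fm_grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
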