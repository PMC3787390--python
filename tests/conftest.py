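"""Shared fixtures: expensive simulated frames are built once per session."""

import numpy as np
import pytest

from vesishape import (
    GridParams,
    PSFSpec,
    StructureSpec,
    image_structure,
    project,
    render_structure,
    vesicle,
)


@pytest.fixture(scope="session")
def grid200() -> GridParams:
    return GridParams(200, 5.0)


@pytest.fixture(scope="session")
def sted_psf() -> PSFSpec:
    return PSFSpec("lorentzian", 80.0)


@pytest.fixture(scope="session")
def point_source_frame(grid200, sted_psf):
    """Noise-free image of a single-voxel point source under the STED PSF."""
    spec = StructureSpec("vesicle", 0.0, None, 0.0)
    return image_structure(project(render_structure(spec, grid200)), sted_psf, None)


@pytest.fixture(scope="session")
def vesicle_frame(grid200, sted_psf):
    """Noise-free image of a surface-labeled 110 nm vesicle under the STED PSF."""
    return image_structure(project(render_structure(vesicle(110.0), grid200)), sted_psf, None)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
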