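"""Shared fixtures: all data are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from dualphase_pet.imaging_core import FrameSchedule, parse_frame_spec
from dualphase_pet.phantom_sim import (
    CohortConfig,
    build_phantom,
    default_phantom_spec,
    generate_cohort,
    parametric_input_function,
)

PAPER_FRAME_SPEC = "12x5,6x10,3x20,7x60,4x300,3x600"

# ROI-level regions used for group comparisons (the per-sector cortical
# labels enter through the composite cerebral cortex)
ROI_REGIONS = [
    "cerebral_cortex",
    "temporal_left", "temporal_right",
    "basal_ganglia_left", "basal_ganglia_right",
    "thalamus_left", "thalamus_right",
    "cerebellum_left", "cerebellum_right",
    "centrum_semiovale_left", "centrum_semiovale_right",
    "pons",
]

# coarse grid for rendering tests: same 192 x 192 x 160 mm field of view as
# the default 2-mm phantom, at 4 mm
COARSE_GRID = dict(grid_shape=(48, 48, 40), voxel_size_mm=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def paper_schedule() -> FrameSchedule:
    return parse_frame_spec(PAPER_FRAME_SPEC)


@pytest.fixture(scope="session")
def fine_input_function():
    return parametric_input_function(duration_s=3700.0, dt_s=0.1)


@pytest.fixture(scope="session")
def coarse_spec():
    return default_phantom_spec(**{
        "grid_shape": COARSE_GRID["grid_shape"],
        "voxel_size_mm": COARSE_GRID["voxel_size_mm"],
    })


@pytest.fixture(scope="session")
def coarse_labels(coarse_spec):
    return build_phantom(coarse_spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size (21 + 8) cohort at TAC level on the coarse grid."""
    config = CohortConfig(**COARSE_GRID)
    return generate_cohort(config, seed=20)


@pytest.fixture(scope="session")
def lesion_cohort():
    """Small unblocked cohort used for rendered lesion analyses."""
    config = CohortConfig(n_unblocked=6, n_blocked=0, **COARSE_GRID)
    return generate_cohort(config, seed=40)
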