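"""Shared fixtures: synthetic cohorts and phantom morphometry runs."""

import numpy as np
import pytest

from callothick import profile_pipeline
from callothick.simulate import (
    CohortSpec,
    PhantomParams,
    build_cohort,
    generate_mask,
    half_annulus_mask,
)

THICK_COLS = [f"thickness_{k + 1:03d}" for k in range(100)]
REL_THICK_COLS = ["rel_" + c for c in THICK_COLS]


@pytest.fixture(scope="session")
def cohort600():
    """Default-condition cohort, n = 600 (table, ground truth)."""
    return build_cohort(CohortSpec(n=600, seed=3))


@pytest.fixture(scope="session")
def half_annulus_run():
    """Half-annulus phantom (t = 6 mm, 0.7 mm pixels) through the pipeline."""
    mask, truth = half_annulus_mask()
    result = profile_pipeline(mask, landmark_override=truth["landmark_override"])
    return mask, truth, result


@pytest.fixture(scope="session")
def phantom_run():
    """Default callosum-like phantom through the pipeline."""
    mask, truth = generate_mask(PhantomParams())
    result = profile_pipeline(mask)
    return mask, truth, result
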