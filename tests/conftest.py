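import dataclasses

import numpy as np
import pytest

import abrscreen as abr
from abrscreen.pipeline import build_reference


@pytest.fixture(scope="session")
def noise_free_model():
    return dataclasses.replace(abr.DEFAULT_WAVE_MODEL, noise_sd_uv=0.0)


@pytest.fixture(scope="session")
def pop():
    return abr.DEFAULT_POP_PARAMS


@pytest.fixture(scope="session")
def normal_pop():
    """Pure-normal control population (no heavy tail), for closed-form checks."""
    return dataclasses.replace(abr.DEFAULT_POP_PARAMS, heavy_tail_frac=0.0)


@pytest.fixture(scope="session")
def control_reference(pop):
    """A large control cohort and its per-stimulus reference ranges."""
    controls = abr.generate_control_cohort(pop, 2000, seed=17)
    return controls, build_reference(controls)
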