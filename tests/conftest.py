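"""Shared fixtures.

Expensive artifacts (full-size phantom render, the 10-subject experiment)
are session-scoped and computed once; most tests run on small grids or
plain TACs.
"""

import numpy as np
import pytest

from pkpet.frames import FrameSchedule
from pkpet.phantom import default_phantom, render_noiseless
from pkpet.reference import library_from_phantom
from pkpet.reliability import phantom_masks, run_trt_experiment


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.brain_60min()


@pytest.fixture(scope="session")
def default_spec():
    return default_phantom()


@pytest.fixture(scope="session")
def noiseless_default(default_spec):
    return render_noiseless(default_spec)


@pytest.fixture(scope="session")
def default_masks(default_spec):
    return phantom_masks(default_spec)


@pytest.fixture(scope="session")
def default_library(default_spec):
    return library_from_phantom(default_spec)


@pytest.fixture(scope="session")
def small_spec():
    """Quarter-size phantom for fast structural tests."""
    return default_phantom(shape=(48, 48, 24), scale=0.5, n_lesions=2)


@pytest.fixture(scope="session")
def trt_result(default_spec):
    """The headline 10-subject experiment, shared by the acceptance tests."""
    return run_trt_experiment(default_spec, n_subjects=10, seed=7)
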