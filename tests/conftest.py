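import dataclasses

import numpy as np
import pytest

from afhdx import synthetic as syn
from afhdx.constructs import Condition


@pytest.fixture
def params():
    """Default ground-truth preset (79% folded baseline, weak binding)."""
    return syn.default_params()


@pytest.fixture
def noise_free_params():
    return syn.default_params(shift_noise_sd=0.0, intensity_noise_sd=0.0)


@pytest.fixture
def baseline():
    return Condition()


@pytest.fixture
def salt_230():
    return Condition(anion="ReO4", concentration_mM=230.0)


@pytest.fixture
def hdx_times():
    return np.array(syn.DEFAULT_HDX_TIMES)


def make_params(**overrides):
    return dataclasses.replace(syn.default_params(), **overrides)
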