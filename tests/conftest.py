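import numpy as np
import pytest

from lddnum import ObserverParams, PopulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unbiased_params():
    """A noise-free observer with every bias switched off."""
    return ObserverParams(
        weber_fraction=0.0,
        area_exponent=0.0,
        size_exponent=0.0,
        grouping_gains={f: 1.0 for f in ("spatial", "size", "color", "motion")},
        lapse_sd=0.0,
    )


@pytest.fixture
def unbiased_population():
    """A degenerate population of identical unbiased noise-free observers."""
    return PopulationParams(
        weber_fraction_mean=0.0,
        weber_fraction_logsd=0.0,
        area_exponent_mean=0.0,
        area_exponent_logsd=0.0,
        size_exponent_mean=0.0,
        size_exponent_logsd=0.0,
        grouping_gain_means={f: 1.0 for f in ("spatial", "size", "color", "motion")},
        grouping_gain_logsd=0.0,
        rho_color_motion=0.0,
        lapse_sd_mean=0.0,
        lapse_sd_logsd=0.0,
    )


def noise_free_population(alpha: float, beta: float) -> PopulationParams:
    """Deterministic observers with only the area/size power-law biases."""
    return PopulationParams(
        weber_fraction_mean=0.0,
        weber_fraction_logsd=0.0,
        area_exponent_mean=alpha,
        area_exponent_logsd=0.0,
        size_exponent_mean=beta,
        size_exponent_logsd=0.0,
        grouping_gain_means={f: 1.0 for f in ("spatial", "size", "color", "motion")},
        grouping_gain_logsd=0.0,
        rho_color_motion=0.0,
        lapse_sd_mean=0.0,
        lapse_sd_logsd=0.0,
    )
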