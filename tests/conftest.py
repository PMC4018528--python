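import numpy as np
import pytest

from capinit import (
    TABLE1_TOTALS,
    UNFERTILIZED_RATES,
    equilibrium_partition,
)
from capinit.fitting import (
    GridPredictor,
    baseline_parameters,
    fold_axis,
    ramp_axis,
)
from capinit.synthetic import DEFAULT_SAMPLE_TIMES_MIN


@pytest.fixture(scope="session")
def totals():
    return TABLE1_TOTALS


@pytest.fixture(scope="session")
def rates():
    return UNFERTILIZED_RATES


@pytest.fixture(scope="session")
def baseline():
    """Unfertilized rates with the synthesis constant set by flux balance."""
    return baseline_parameters(TABLE1_TOTALS, UNFERTILIZED_RATES)


@pytest.fixture(scope="session")
def partition(baseline):
    return equilibrium_partition(TABLE1_TOTALS, baseline.kd1, baseline.kd2)


@pytest.fixture(scope="session")
def fert_predictor(baseline):
    """Default fertilization search grid with predictions precomputed once."""
    return GridPredictor(
        DEFAULT_SAMPLE_TIMES_MIN,
        fold_axis(1.0, 100.0),
        fold_axis(1.0, 100.0),
        ramp_axis(1.0, 15.0),
        TABLE1_TOTALS,
        baseline,
    )


@pytest.fixture(scope="session")
def rap_predictor(baseline):
    """Default rapamycin search grid with predictions precomputed once."""
    return GridPredictor(
        DEFAULT_SAMPLE_TIMES_MIN,
        fold_axis(1.0, 8.0),
        fold_axis(1.0, 32.5),
        ramp_axis(1.0, 100.0),
        TABLE1_TOTALS,
        baseline,
    )
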