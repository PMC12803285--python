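import numpy as np
import pytest

import tftimer as tt
from tftimer.pipeline import quantify_disc


@pytest.fixture(scope="session")
def pair():
    """Calibrated tandem pair: half-times 3 h (fast) and 6 h (slow)."""
    return tt.FluorophorePair.from_half_times(3.0, 6.0)


@pytest.fixture(scope="session")
def curve(pair):
    """Default 1 h pulse calibration curve on the 15-min grid."""
    return tt.pulse_ratio_curve(pair)


@pytest.fixture(scope="session")
def wt():
    """One wild-type synthetic disc plus its full quantification (seed 1)."""
    scenario = tt.scenario_preset("wild_type", seed=1)
    image, truth = tt.generate_disc_image(scenario)
    quant = quantify_disc(image, truth, seed=1)
    return dict(scenario=scenario, image=image, truth=truth, quant=quant)


@pytest.fixture(scope="session")
def uniform():
    """Uniform-turnover null disc (all regions identical) plus measurements."""
    scenario = tt.scenario_preset("uniform_turnover", seed=3)
    image, truth = tt.generate_disc_image(scenario)
    quant = quantify_disc(image, truth, seed=3)
    return dict(scenario=scenario, image=image, truth=truth, quant=quant)


def equal_rate_pair(m: float = np.log(2) / 3) -> tt.FluorophorePair:
    """A degenerate pair with m_fast == m_slow, bypassing validation.

    Used only to check that the timer carries no information when the two
    chromophores mature at the same rate.
    """
    p = tt.FluorophorePair.__new__(tt.FluorophorePair)
    object.__setattr__(p, "m_fast", m)
    object.__setattr__(p, "m_slow", m)
    object.__setattr__(p, "q_fast_acidic", 1.0)
    object.__setattr__(p, "q_slow_acidic", 1.0)
    return p
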