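import numpy as np
import pytest

from concresp.baseline import CutoffSpec
from concresp.fitting import ConcRespSeries
from concresp.synth import SimConfig, simulate_series


@pytest.fixture
def pc20_cutoff():
    """Fixed 20-unit cutoff with unit baseline spread."""
    return CutoffSpec(bmad=1.0, onesd=1.0, coff=20.0, cutoff_methods=("pc20",))


@pytest.fixture
def clean_hill_series():
    """Low-noise hill series (tp=50, ga=1, p=2) on the default design."""
    return simulate_series(
        SimConfig(model="hill", params={"tp": 50.0, "ga": 1.0, "p": 2.0},
                  noise_scale=1.0, seed=7)
    )


def make_series(conc, resp, direction="bidirectional"):
    return ConcRespSeries("s", "e", np.asarray(conc, float), np.asarray(resp, float),
                          direction=direction)


@pytest.fixture
def series_factory():
    return make_series
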