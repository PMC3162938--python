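import numpy as np
import pytest

from lightgrn.dataset import ExpressionDataset, TimeSeriesExpression
from lightgrn.synthetic import DESIGN_TIMES, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small two-condition study: 10 targets, 7 TFs, default noise."""
    return generate_study(7, n_targets=10, n_tf=7)


@pytest.fixture
def design_times():
    return np.asarray(DESIGN_TIMES)


def make_profile(gene, times, values):
    return TimeSeriesExpression(gene, np.asarray(times, float), np.asarray(values, float))


@pytest.fixture
def tiny_dataset():
    """Five hand-constructed profiles on the design grid (single replicate)."""
    t = np.asarray(DESIGN_TIMES)
    profiles = [
        make_profile("G1", t, [1.0, 1.2, 1.8, 2.5, 2.6]),
        make_profile("G2", t, [2.0, 1.9, 1.4, 0.8, 0.7]),
        make_profile("TFA", t, [0.5, 0.8, 1.5, 2.0, 2.1]),
        make_profile("TFB", t, [3.0, 2.7, 2.0, 1.2, 1.1]),
        make_profile("FLAT", t, [1.0, 1.0, 1.0, 1.0, 1.0]),
    ]
    return ExpressionDataset("cond", profiles)
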