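import numpy as np
import pytest

from phenomod.growth import GrowthTrajectory


@pytest.fixture
def days():
    return np.arange(1.0, 51.0)


def logistic_curve(t, K=100.0, r=0.2, t0=25.0):
    return K / (1.0 + np.exp(-r * (t - t0)))


@pytest.fixture
def logistic_trajectory(days):
    return GrowthTrajectory("plant-1", days, logistic_curve(days))


# moderately saturated noise-free curves: the plant is still approaching
# its asymptote at the end of the experiment, as in a real imaging series
CONTROL_CURVES = {
    "linear": ({"a": 3.0, "b": 2.0}, lambda t: 3.0 + 2.0 * t),
    "exponential": ({"a": 2.0, "b": 0.1}, lambda t: 2.0 * np.exp(0.1 * t)),
    "monomolecular": ({"K": 100.0, "a": 0.8, "r": 0.06},
                      lambda t: 100.0 * (1 - 0.8 * np.exp(-0.06 * t))),
    "logistic": ({"K": 100.0, "r": 0.2, "t0": 25.0}, logistic_curve),
    "gompertz": ({"K": 100.0, "a": 5.0, "r": 0.15},
                 lambda t: 100.0 * np.exp(-5.0 * np.exp(-0.15 * t))),
    "weibull": ({"K": 100.0, "k": 2.5, "lam": 25.0},
                lambda t: 100.0 * (1 - np.exp(-((t / 25.0) ** 2.5)))),
}
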