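import numpy as np
import pytest
from hypothesis import settings

from methclock import fixtures
from methclock.clocks import ClockModel, MrsRule
from methclock.panel import TargetCytosine

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel161():
    """The full synthetic 161-marker fixture panel (plus lambda controls)."""
    return fixtures.fixture_panel()


@pytest.fixture(scope="session")
def clock_models():
    return fixtures.fixture_clocks()


def make_small_panel(n: int = 8) -> list[TargetCytosine]:
    """A cheap panel for simulation-heavy tests: n markers + 1 lambda."""
    markers = [
        TargetCytosine(f"cgS{i:02d}", "chr1", 1000 + 10 * i, "CG",
                       "both" if i % 3 else "W", "locusS",
                       frozenset({"HANNUM"}))
        for i in range(n)
    ]
    markers.append(TargetCytosine("lambda_s", "lambda", 500, "CG", "both",
                                  "lambda_amp", frozenset()))
    return markers


def make_small_clock(name: str = "small_clock") -> ClockModel:
    """4-marker linear age clock over the small panel, centered at 44 y."""
    weights = {"cgS00": 30.0, "cgS01": -25.0, "cgS02": 35.0, "cgS03": -40.0}
    means = {m: 0.5 for m in weights}
    intercept = 44.0 - sum(w * means[m] for m, w in weights.items())
    return ClockModel(name, intercept, weights, means, "years")


@pytest.fixture
def small_panel():
    return make_small_panel()


@pytest.fixture
def small_clock():
    return make_small_clock()


@pytest.fixture
def rng():
    return np.random.default_rng(20230810)
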