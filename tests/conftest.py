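import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial shared across tests (seed 7)."""
    from droughtsel import SimSpec, simulate_trial

    with pytest.warns(UserWarning, match="truncated"):
        return simulate_trial(SimSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_pairs(yp, ys, genotypes=None, entry_type=None):
    """Small paired-yield table builder used throughout the suite."""
    yp = np.atleast_1d(np.asarray(yp, dtype=float))
    genotypes = genotypes or [f"G{i + 1}" for i in range(len(yp))]
    frame = pd.DataFrame({"genotype": genotypes, "yp": yp, "ys": ys})
    if entry_type is not None:
        frame["entry_type"] = entry_type
    return frame
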