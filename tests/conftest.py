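import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import agoripseq as aq

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A 300-gene simulated experiment shared across read-only tests."""
    cfg = aq.SimConfig(n_genes=300, seed=7)
    counts, design, truth = aq.simulate_ripseq(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def fitted_pipeline(small_sim):
    _, counts, design, truth = small_sim
    pipe = aq.AgoRipTargetPipeline(dispersion="common")
    pipe.fit(counts.T, design)
    return pipe, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_counts():
    """Tiny deterministic genes x libraries matrix."""
    return pd.DataFrame(
        {
            "libA": [100, 200, 300, 50, 10, 340],
            "libB": [120, 180, 310, 40, 8, 5000],
        },
        index=[f"g{i}" for i in range(6)],
    )
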