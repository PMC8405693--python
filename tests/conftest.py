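import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study shared by read-only tests."""
    from lfqstab import SimulationParams, simulate_proteome
    params = SimulationParams(n_proteins=400, seed=42)
    matrix, design, truth = simulate_proteome(params)
    return matrix, design, truth


@pytest.fixture()
def tiny_matrix():
    """Two proteins x four samples, one missing cell."""
    return pd.DataFrame(
        [[1.0, 3.0, 5.0, 7.0], [2.0, np.nan, 6.0, 8.0]],
        index=pd.Index(["p1", "p2"], name="protein_id"),
        columns=["s1", "s2", "s3", "s4"])


@pytest.fixture()
def tiny_design():
    return pd.DataFrame({
        "sample": ["s1", "s2", "s3", "s4"],
        "group": ["DM", "DM", "NDM", "NDM"],
        "batch": ["B1", "B1", "B1", "B1"],
    })
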