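import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from rhizoasm.io import OtuTable
from rhizoasm.simulate import scenario_preset, emit_study, distinct_env_by_regime

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_table() -> OtuTable:
    """3 taxa x 3 samples with simple structure."""
    data = pd.DataFrame(
        {"s1": [2, 2, 0], "s2": [1, 1, 1], "s3": [0, 0, 7]},
        index=["t1", "t2", "t3"],
    )
    return OtuTable(data)


@pytest.fixture
def random_table() -> OtuTable:
    rng = np.random.default_rng(17)
    counts = rng.integers(0, 50, size=(50, 10))
    counts[0] += 1  # keep every column positive
    return OtuTable.from_arrays(
        counts, [f"t{i}" for i in range(50)], [f"s{j}" for j in range(10)]
    )


@pytest.fixture(scope="session")
def small_neutral_study():
    """Cheap 60-taxon neutral study shared across tests."""
    return emit_study(scenario_preset("neutral", seed=7, n_taxa=60, community_size=2000))


@pytest.fixture(scope="session")
def small_selection_study():
    """60-taxon variable-selection study (distinct optima per regime) --
    produces correlated taxa and therefore non-trivial networks."""
    return emit_study(
        scenario_preset(
            "selection", seed=8, n_taxa=60, env_by_cell=distinct_env_by_regime()
        )
    )
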