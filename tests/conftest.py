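import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from edna_cooccur import TransitionTable, default_standard_curve  # noqa: E402


@pytest.fixture
def paper_curve():
    """Reference assay curve with the printed coefficients and LOD=0.01."""
    return default_standard_curve()


def build_table(month_pair, species_states):
    """TransitionTable from {species_id: [state per site]}; sites S01, S02...

    Shared helper for hand-constructed tables in several test modules.
    """
    import pandas as pd

    n = len(next(iter(species_states.values())))
    sites = [f"S{i + 1:02d}" for i in range(n)]
    return TransitionTable(
        month_pair, pd.DataFrame(species_states, index=sites)
    )


@pytest.fixture
def make_table():
    return build_table
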