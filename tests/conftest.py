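import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from glycolda import CohortConfig, generate_cohort
from glycolda.io import build_features
from glycolda.quantify import PeakTable

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """The 18+19-sample synthetic cohort at the fixed study conditions."""
    table, truth = generate_cohort(CohortConfig(seed=42))
    return table, truth


@pytest.fixture(scope="session")
def default_features(default_cohort):
    table, _ = default_cohort
    return build_features(table)


@pytest.fixture()
def tiny_peak_table():
    """Two samples x three isomers with hand-computable areas."""
    rows = []
    for sample, cls, areas in [
        ("S1", "melanoma", [100.0, 300.0, 600.0]),
        ("S2", "control", [50.0, 50.0, 100.0]),
    ]:
        for (comp, iso, rt), area in zip(
            [("N4H5S2", 1, 70.5), ("N4H5S2", 2, 72.0), ("N5H6S2", 1, 74.0)], areas
        ):
            rows.append((sample, cls, comp, iso, rt, area))
    return PeakTable(
        pd.DataFrame(
            rows,
            columns=["sample_id", "class", "composition", "isomer_index", "rt_min", "area"],
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
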