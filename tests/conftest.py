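import warnings

import numpy as np
import pandas as pd
import pytest

from epitrain import CohortConfig, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A small spiked cohort shared across read-only tests."""
    cfg = CohortConfig(n_subjects=60, n_probes=300, n_snps=60, seed=123)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no spiked effects (shared, read-only)."""
    cfg = CohortConfig.null(n_subjects=50, n_probes=200, n_snps=40, seed=321)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_sheet(n_subjects, timepoints=("T0", "T14", "T90"), seed=0):
    """Minimal valid sample sheet for hand-built designs."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for tp in timepoints:
            rows.append({
                "sample_id": f"S{i:03d}_{tp}",
                "subject_id": f"S{i:03d}",
                "timepoint": tp,
                "age": 20 + (i % 30),
                "sex": "F" if i % 2 else "M",
                "plate": f"P{1 + i % 2}",
                "collection_date": pd.Timestamp("2020-01-01")
                + pd.Timedelta(days=int(rng.integers(0, 365))),
                "bmi": 22.0,
                "smoking": False,
            })
    return pd.DataFrame(rows)
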