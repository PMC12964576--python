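"""Shared fixtures: synthetic cohorts at the scales the checks need."""

import numpy as np
import pandas as pd
import pytest

from immunopanel.pipeline import _design
from immunopanel.synthetic import default_config, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cohort300():
    """Full-scale default cohort (n=300, 2000 genes) shared across tests."""
    return generate_cohort(default_config(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def design300(cohort300):
    """Samples-by-genes logistic design (z-scored log1p tumor expression)."""
    return _design(cohort300.tumor)


@pytest.fixture(scope="session")
def y300(cohort300):
    tumor_ids = cohort300.fractions.index
    return cohort300.clinical.loc[tumor_ids, "os_event"].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for interface and plumbing tests."""
    cfg = default_config(n_patients=60, n_genes=1500, seed=5)
    return generate_cohort(cfg)


def survival_from_death_prob(rng, death_prob, max_time=3650.0):
    """Simple survival triple (times, events) from per-sample death risk."""
    n = death_prob.shape[0]
    events = (rng.random(n) < death_prob).astype(int)
    times = np.where(events == 1,
                     rng.uniform(30, max_time * 0.8, n),
                     rng.uniform(max_time * 0.3, max_time, n))
    return times, events


def make_clinical(sample_ids, times, events):
    n = len(sample_ids)
    return pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "tissue": ["tumor"] * n,
        "os_time_days": times,
        "os_event": events,
    }).set_index("sample_id")
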