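import warnings

import numpy as np
import pytest

import survscreen as sv


def make_survival(time, event, ids=None):
    time = np.asarray(time, float)
    if ids is None:
        ids = np.array([f"s{i}" for i in range(len(time))], dtype=object)
    return sv.SurvivalData(ids, time, np.asarray(event))


@pytest.fixture(scope="session")
def small_cohort():
    """n=120, p=150 cohort with 8 causal genes and moderate censoring."""
    spec = sv.SimulationSpec(
        n_patients=120, n_genes=150, n_causal=8, sigma=0.6,
        target_censoring=0.3, seed=42,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, truth = sv.simulate_dataset(spec)
    return ds, truth, spec


@pytest.fixture(scope="session")
def standardized_small(small_cohort):
    """Standardized log2-CPM matrix of the small cohort (whole-cohort)."""
    ds, truth, spec = small_cohort
    log = sv.cpm_normalize(ds.counts, log2=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = sv.standardize(log, log, mode="train_params").train
    return std


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_survival_dataset(rng, n, p=0, censor_frac=0.3):
    """Small random dataset with ties possible; returns (X, SurvivalData)."""
    time = np.round(rng.exponential(1.0, n), 1) + 0.1
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    X = rng.standard_normal((n, p)) if p else np.zeros((n, 0))
    return X, make_survival(time, event)
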