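"""Shared fixtures: small synthetic datasets and reusable fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import spcurve as sp

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_spec(dataset, structure="1.3", n_knots=5, covariates=None, reference="CTR"):
    knots = sp.select_knots_quantile(dataset.times(), n_knots)
    return sp.ModelSpec(
        structure=structure,
        basis=sp.BasisSpec(degree=2, knots=knots),
        covariates=dataset.covariates if covariates is None else covariates,
        reference_level=reference,
    )


@pytest.fixture(scope="session")
def small_config():
    """Two groups, 8+10 subjects, 25 half-hourly points, no serial noise."""
    return sp.SimConfig(
        group_sizes=(8, 10),
        times=np.round(np.arange(0.0, 12.01, 0.5), 6),
        serial="none",
        sigma2_serial=0.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, truth = sp.simulate_dataset(small_config, seed=42)
    return dataset, truth


@pytest.fixture(scope="session")
def fit_13(small_dataset):
    """Structure-1.3 ML fit on the small dataset (reused across tests)."""
    dataset, _ = small_dataset
    spec = make_spec(dataset)
    return sp.fit(dataset, spec, sp.CovarianceSpec(serial="none"), method="ML")


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 subjects x 6 times, 2 groups, one covariate — for dense oracles."""
    rng = np.random.default_rng(0)
    rows = []
    for i, (s, g) in enumerate([("a", "A"), ("b", "A"), ("c", "B"), ("d", "B")]):
        for t in np.linspace(0.0, 10.0, 6):
            rows.append(
                {"subject": s, "group": g, "time": t,
                 "response": rng.normal(), "x1": i * 0.5}
            )
    return sp.LongitudinalDataset(pd.DataFrame(rows), covariates=("x1",))
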