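import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import camocc as co

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def enumeration_likelihood(history, psi, p):
    """Independent oracle: sum over the latent occupancy state."""
    total = 0.0
    for z in (0, 1):
        prior = psi if z else 1.0 - psi
        cond = 1.0
        for y, pj in zip(history, p):
            if np.isnan(y):
                continue
            if z:
                cond *= pj if y == 1 else 1.0 - pj
            elif y == 1:
                cond = 0.0
        total += prior * cond
    return total


@pytest.fixture(scope="session")
def tapir_dataset():
    """One reference-scenario survey at the study's full size."""
    return co.simulate(co.tapir_scenario(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced survey (150 sites) for fast model-set and assessment tests."""
    design = dataclasses.replace(co.tapir_scenario(seed=7), n_sites=150)
    return co.simulate(design)


@pytest.fixture(scope="session")
def small_full_fit(small_dataset):
    spec = co.ModelSpec(
        psi_terms=("forest_d", "d_streams"), p_terms=("forest_d", "past")
    )
    return co.fit_occupancy(spec, small_dataset.matrix, small_dataset.covariates)


@pytest.fixture(scope="session")
def intercept_fit(small_dataset):
    return co.fit_occupancy(co.ModelSpec(), small_dataset.matrix,
                            small_dataset.covariates)
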