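"""Shared fixtures: reference parameter sets and pre-fitted models.

Expensive fits are session-scoped so the estimation, diagnostic and
acceptance tests share one FOCE run instead of refitting per test.
"""

import numpy as np
import pytest

from remipk import (
    ModelSpec,
    PKParameters,
    Regimen,
    default_population,
    fit,
    simulate_cohort,
)

#: Final-model typical values used throughout (CL L/h, V1 L, Q L/h, V2 L).
TYPICAL = PKParameters(cl=58.2, v1=25.5, q=20.0, v2=34.5)


@pytest.fixture(scope="session")
def typical_params() -> PKParameters:
    return TYPICAL


@pytest.fixture(scope="session")
def study_cohort():
    """One 32-subject cohort under the full generating model (seed-fixed)."""
    return simulate_cohort(default_population(), n=32, seed=42)


@pytest.fixture(scope="session")
def study_fit(study_cohort):
    """FOCE-I fit of the base model on the study-design cohort."""
    res = fit(study_cohort, ModelSpec(), compute_rse=False)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def small_clean_cohort():
    """Small, low-noise cohort (no IIV, 5% proportional error) for recovery checks."""
    from remipk.cohort_sim import PopulationModel

    pop = PopulationModel(
        theta=TYPICAL,
        omega={"CL": 0.0, "V1": 0.0, "Q": 0.0, "V2": 0.0},
        sigma_prop=0.05,
    )
    return simulate_cohort(pop, n=16, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def infusion_12mgh():
    return Regimen.constant_infusion(12.0, 8.0)
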