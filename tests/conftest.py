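"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from tauspread import GeneratorConfig, generate_cohort
from tauspread.mixtures import build_tpi_table, fit_region_models


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject default-parameter cohort for module-level tests."""
    return generate_cohort(GeneratorConfig(n_subjects=60, seed=5))


@pytest.fixture(scope="session")
def small_models(small_cohort):
    return fit_region_models(small_cohort.suvr_baseline, seed=0)


@pytest.fixture(scope="session")
def small_tpi(small_cohort, small_models):
    return build_tpi_table(small_cohort.suvr_baseline, small_models)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
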