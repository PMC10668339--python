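"""Shared fixtures: synthetic cohorts with known ground truth.

Heavy artifacts (10k-record cohorts and their fitted model sets) are
session-scoped so estimation, GBM and acceptance tests reuse one fit.
"""

import numpy as np
import pytest

import bmimarkov as bm

UNIFORM_MIX = [0.25, 0.25, 0.25, 0.25]


@pytest.fixture(scope="session")
def covfree_cohort():
    """n=10,000, uniform origin mix, no covariate effects (seed 11)."""
    cfg = bm.SyntheticConfig(n=10_000, seed=11, baseline_mix=UNIFORM_MIX)
    return bm.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def covfree_models(covfree_cohort):
    cohort, _ = covfree_cohort
    return bm.fit_transition_models(cohort, seed=7)


@pytest.fixture(scope="session")
def covfree_empirical(covfree_cohort):
    cohort, _ = covfree_cohort
    return bm.estimate_from_cohort(cohort)


@pytest.fixture(scope="session")
def age_effect_cohort():
    """Planted positive age effect on the obese destination (seed 13)."""
    eff = bm.CovariateEffect(covariate="age", destination="obese", coefficient=0.8)
    cfg = bm.SyntheticConfig(n=10_000, seed=13, baseline_mix=UNIFORM_MIX, effects=[eff])
    return bm.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def age_effect_models(age_effect_cohort):
    cohort, _ = age_effect_cohort
    return bm.fit_transition_models(cohort, seed=7)


@pytest.fixture(scope="session")
def sex_effect_cohort():
    """Planted sex effect: females shifted toward the obese destination (seed 17)."""
    eff = bm.CovariateEffect(covariate="sex", destination="obese", coefficient=0.6, level="female")
    cfg = bm.SyntheticConfig(n=10_000, seed=17, baseline_mix=UNIFORM_MIX, effects=[eff])
    return bm.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def sex_effect_models(sex_effect_cohort):
    cohort, _ = sex_effect_cohort
    return bm.fit_transition_models(cohort, seed=7)


@pytest.fixture(scope="session")
def nhanes_cohort_2k():
    """NHANES-like marginals at n=2000 (seed 5) for bootstrap tests."""
    return bm.generate_cohort(bm.default_nhanes_config(n=2000, seed=5))


@pytest.fixture
def reference_raw():
    return bm.nhanes_reference_matrix(renormalize=False)


@pytest.fixture
def reference_renorm():
    return bm.nhanes_reference_matrix(renormalize=True)


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("default", derandomize=True)
_hyp_settings.load_profile("default")
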