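"""Covariate-dependent transition models: oracle equivalence, effects,
determinism, fallbacks, persistence, subgroup validation."""

import numpy as np
import pandas as pd
import pytest

import bmimarkov as bm

PROFILES = [
    bm.CovariateProfile(age=35, sex="female", race="black"),
    bm.CovariateProfile(age=65, sex="male", race="asian"),
    bm.CovariateProfile(age=50, sex="female", race="white"),
]


class TestOracleEquivalence:
    def test_rows_match_empirical_without_covariate_signal(self, covfree_models, covfree_empirical):
        """With no true covariate effect, every profile's predicted rows
        converge to the per-origin empirical MLE rows."""
        for profile in PROFILES:
            cm = bm.covariate_matrix(covfree_models, profile)
            assert cm.max_abs_diff(covfree_empirical) < 0.03

    def test_rows_sum_to_one(self, covfree_models):
        for profile in PROFILES:
            for origin in bm.STATE_LABELS:
                row = bm.predict_transition_row(covfree_models, origin, profile)
                assert row.sum() == pytest.approx(1.0, abs=1e-6)
                assert np.all(row >= 0)


class TestDeterminism:
    def test_identical_profiles_identical_rows(self, covfree_models):
        a = bm.predict_transition_row(covfree_models, "normal", PROFILES[0])
        b = bm.predict_transition_row(covfree_models, "normal", PROFILES[0])
        assert np.array_equal(a, b)

    def test_refit_same_seed_bit_identical(self):
        cfg = bm.SyntheticConfig(n=2000, seed=31, baseline_mix=[0.25] * 4)
        cohort = bm.generate_cohort(cfg)
        m1 = bm.fit_transition_models(cohort, seed=5)
        m2 = bm.fit_transition_models(cohort, seed=5)
        for profile in PROFILES:
            assert np.array_equal(
                bm.covariate_matrix(m1, profile).probs,
                bm.covariate_matrix(m2, profile).probs,
            )


class TestPlantedEffects:
    def test_age_effect_sign_recovered(self, age_effect_models):
        """Positive age coefficient on the obese destination: predicted
        obese probability from the normal origin rises with age."""
        young = bm.predict_transition_row(
            age_effect_models, "normal", bm.CovariateProfile(30, "female", "white"))
        old = bm.predict_transition_row(
            age_effect_models, "normal", bm.CovariateProfile(70, "female", "white"))
        assert old[3] > young[3]

    def test_profile_matrices_differ_in_effect_direction(self, age_effect_models):
        m_young = bm.covariate_matrix(age_effect_models, bm.CovariateProfile(35, "female", "black"))
        m_old = bm.covariate_matrix(age_effect_models, bm.CovariateProfile(65, "male", "asian"))
        assert m_old.probs[1, 3] > m_young.probs[1, 3]
        assert m_young.is_row_stochastic and m_old.is_row_stochastic


class TestContracts:
    def test_unseen_race_strict_mode_rejected(self, covfree_cohort):
        cohort, _ = covfree_cohort
        models = bm.fit_transition_models(
            cohort.__class__(cohort.data.head(500).copy()), seed=1, strict=True)
        with pytest.raises(bm.InvalidInputError):
            bm.predict_transition_row(models, "normal",
                                      bm.CovariateProfile(40, "female", "martian"))

    def test_unseen_race_maps_to_other_when_lenient(self, covfree_models):
        row = bm.predict_transition_row(covfree_models, "normal",
                                        bm.CovariateProfile(40, "female", "martian"))
        other = bm.predict_transition_row(covfree_models, "normal",
                                          bm.CovariateProfile(40, "female", "other"))
        assert np.array_equal(row, other)

    def test_missing_covariate_rejected(self, covfree_models):
        with pytest.raises(bm.InvalidInputError):
            bm.predict_transition_row(covfree_models, "normal", {"age": 40, "sex": "male"})

    def test_single_origin_cohort_falls_back_to_four_rows(self):
        rows = [{
            "id": f"p{i}", "age": 40 + i, "sex": "male", "race": "white",
            "weight_now_kg": (31 + (i % 3)) * 1.7**2,
            "weight_10y_ago_kg": 36.0 * 1.7**2, "height_m": 1.7,
        } for i in range(40)]
        models = bm.fit_transition_models(bm.Cohort(pd.DataFrame(rows)), seed=1)
        cm = bm.covariate_matrix(models, PROFILES[0])
        assert cm.probs.shape == (4, 4)
        assert cm.is_row_stochastic
        # unobserved origins use the self-absorbing empirical fallback
        assert cm.probs[0, 0] == 1.0
        assert cm.probs[1, 1] == 1.0

    def test_save_load_round_trip(self, tmp_path, covfree_models):
        covfree_models.save(tmp_path / "models")
        loaded = bm.TransitionModelSet.load(tmp_path / "models")
        for profile in PROFILES:
            assert np.allclose(
                bm.covariate_matrix(covfree_models, profile).probs,
                bm.covariate_matrix(loaded, profile).probs,
                atol=1e-7,
            )


class TestProfileProjection:
    def test_age_advances_by_default(self, age_effect_models):
        start = bm.StateDistribution([0, 1.0, 0, 0])
        profile = bm.CovariateProfile(40, "female", "white")
        aging = bm.project_profile(age_effect_models, profile, start, steps=3)
        static = bm.project_profile(age_effect_models, profile, start, steps=3,
                                    age_advances=False)
        assert len(aging) == 4
        assert np.allclose(aging.array.sum(axis=1), 1.0, atol=1e-9)
        # with a positive age effect, the aging projection ends more obese
        assert aging.array[-1, 3] > static.array[-1, 3]


class TestSubgroupValidation:
    def test_covariate_free_discrepancy_small(self, covfree_models, covfree_cohort):
        cohort, _ = covfree_cohort
        table = bm.validate_against_subgroups(covfree_models, cohort, ["sex"], B=100, seed=3)
        assert set(table["subgroup"]) == {"sex=female", "sex=male"}
        assert (table["max_abs_diff"] < 0.03).all()

    def test_empty_key_vars_single_row(self, covfree_models, covfree_cohort):
        cohort, _ = covfree_cohort
        table = bm.validate_against_subgroups(covfree_models, cohort, [], B=100, seed=3)
        assert len(table) == 1
        assert table.loc[0, "subgroup"] == "all"
        assert table.loc[0, "max_abs_diff"] < 0.02

    def test_sex_effect_within_bootstrap_bands(self, sex_effect_models, sex_effect_cohort):
        """Planted sex effect: the model, conditioning on sex, reproduces each
        sex's empirical matrix within its bootstrap bands."""
        cohort, _ = sex_effect_cohort
        table = bm.validate_against_subgroups(sex_effect_models, cohort, ["sex"], B=200, seed=5)
        assert table["within_bands"].all()
        assert (table["p_value"] > 0.05).all()

    def test_small_subgroups_skipped(self, covfree_models, covfree_cohort):
        cohort, _ = covfree_cohort
        tiny = bm.Cohort(cohort.data.head(30).copy())
        table = bm.validate_against_subgroups(covfree_models, tiny, ["sex"], min_size=50, B=10)
        assert table["skipped"].all()
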