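"""Markov projection: baseline, forward/backward iteration, stationarity."""

import numpy as np
import pandas as pd
import pytest

import bmimarkov as bm
from bmimarkov.projection import StateDistribution


def point_mass(state):
    v = np.zeros(4)
    v[int(bm.WeightState.from_label(state))] = 1.0
    return StateDistribution(v)


PUBLISHED_COUNTS = np.array([87, 2058, 1376, 2625])


class TestBaseline:
    def test_one_per_state_is_uniform(self):
        rows = []
        for i, bmi in enumerate([17.0, 22.0, 27.0, 35.0]):
            rows.append({
                "id": f"p{i}", "age": 40, "sex": "male", "race": "white",
                "weight_now_kg": bmi * 1.7**2, "weight_10y_ago_kg": 70.0, "height_m": 1.7,
            })
        base = bm.baseline_distribution(bm.Cohort(pd.DataFrame(rows)))
        assert np.allclose(base.probs, 0.25)

    def test_published_counts_give_published_shares(self):
        shares = PUBLISHED_COUNTS / PUBLISHED_COUNTS.sum()
        assert round(shares[1] * 100) == 33  # normal weight
        assert round(shares[0] * 100) == 1
        assert round(shares[2] * 100) == 22
        assert round(shares[3] * 100) == 43

    def test_all_obese_cohort_is_point_mass(self):
        rows = [{
            "id": f"p{i}", "age": 40, "sex": "male", "race": "white",
            "weight_now_kg": 100.0, "weight_10y_ago_kg": 100.0, "height_m": 1.7,
        } for i in range(3)]
        base = bm.baseline_distribution(bm.Cohort(pd.DataFrame(rows)))
        assert np.allclose(base.probs, [0, 0, 0, 1])

    def test_empty_cohort_rejected(self):
        empty = bm.Cohort(pd.DataFrame(columns=[
            "id", "age", "sex", "race", "weight_now_kg", "weight_10y_ago_kg", "height_m"]))
        with pytest.raises(bm.InvalidInputError):
            bm.baseline_distribution(empty)


class TestForward:
    def test_identity_matrix_is_constant(self):
        m = bm.TransitionMatrix(np.eye(4))
        start = StateDistribution([0.1, 0.2, 0.3, 0.4])
        traj = bm.project_forward(start, m, 10)
        assert len(traj) == 11
        assert np.allclose(traj.array, start.probs)

    @pytest.mark.parametrize("state, retained", [
        ("underweight", 0.65), ("normal", 0.78), ("overweight", 0.71), ("obese", 0.84),
    ])
    def test_one_step_raw_retention_matches_published(self, reference_raw, state, retained):
        with pytest.warns(UserWarning):
            traj = bm.project_forward(point_mass(state), reference_raw, 1, renormalize=False)
        assert traj.distributions[1][state] == pytest.approx(retained, abs=1e-12)

    def test_mass_conserved_over_horizon(self, reference_renorm):
        start = StateDistribution(PUBLISHED_COUNTS / PUBLISHED_COUNTS.sum())
        traj = bm.project_forward(start, reference_renorm, 10)
        assert np.allclose(traj.array.sum(axis=1), 1.0, atol=1e-9)

    def test_contraction_of_two_starts(self, reference_renorm):
        """A strictly positive chain pulls different starts together."""
        P = reference_renorm.probs * 0.9 + 0.025  # strictly positive mixture
        m = bm.TransitionMatrix(P / P.sum(axis=1, keepdims=True))
        a = bm.project_forward(point_mass("underweight"), m, 8).array
        b = bm.project_forward(point_mass("obese"), m, 8).array
        dist = np.abs(a - b).sum(axis=1)
        assert np.all(np.diff(dist) <= 1e-12)

    def test_negative_steps_rejected(self, reference_renorm):
        with pytest.raises(bm.InvalidInputError):
            bm.project_forward(point_mass("normal"), reference_renorm, -1)

    def test_tidy_frame_schema(self, reference_renorm):
        traj = bm.project_forward(point_mass("normal"), reference_renorm, 2)
        frame = traj.to_frame()
        assert list(frame.columns) == ["time_index", "state", "probability"]
        assert len(frame) == 3 * 4
        assert set(frame["state"]) == set(bm.STATE_LABELS)


class TestBackward:
    def test_identity_matrix_constant(self):
        m = bm.TransitionMatrix(np.eye(4))
        end = StateDistribution([0.1, 0.2, 0.3, 0.4])
        traj = bm.project_backward(end, m, 5)
        assert np.allclose(traj.array, end.probs)
        assert traj.time_indices == [-5, -4, -3, -2, -1, 0]

    def test_forward_then_backward_recovers_start(self, reference_renorm):
        start = StateDistribution(PUBLISHED_COUNTS / PUBLISHED_COUNTS.sum())
        fwd = bm.project_forward(start, reference_renorm, 3)
        back = bm.project_backward(fwd.distributions[-1], reference_renorm, 3)
        assert np.max(np.abs(back.distributions[0].probs - start.probs)) < 1e-6
        assert all(d == 0.0 for d in back.distortions)

    def test_single_step_matches_linear_solve_oracle(self, reference_renorm):
        """One decade back from the observed baseline = solving v P = base."""
        base = PUBLISHED_COUNTS / PUBLISHED_COUNTS.sum()
        traj = bm.project_backward(StateDistribution(base), reference_renorm, 1)
        oracle = np.linalg.solve(reference_renorm.probs.T, base)
        assert np.all(oracle >= -1e-12)  # no clipping fires here
        assert np.allclose(traj.distributions[0].probs, oracle / oracle.sum(), atol=1e-10)
        assert np.allclose(traj.distributions[0].probs @ reference_renorm.probs, base, atol=1e-10)

    def test_excessive_clipping_aborts_with_partial(self, reference_renorm):
        base = StateDistribution(PUBLISHED_COUNTS / PUBLISHED_COUNTS.sum())
        with pytest.raises(bm.BackwardDistortionError) as err:
            bm.project_backward(base, reference_renorm, 5, distortion_tolerance=0.05)
        partial = err.value.partial_trajectory
        assert partial is not None and len(partial) >= 1
        assert err.value.distortion > 0.05

    def test_singular_matrix_rejected(self):
        P = np.tile([0.25, 0.25, 0.25, 0.25], (4, 1))
        with pytest.raises(bm.ProjectionError):
            bm.project_backward(StateDistribution([0.25] * 4), bm.TransitionMatrix(P), 1)


class TestStationary:
    def test_reference_fixed_point(self, reference_renorm):
        res = bm.stationary_distribution(reference_renorm)
        v = res.distribution.probs
        assert res.unique
        assert res.residual < 1e-10
        assert np.max(np.abs(v @ reference_renorm.probs - v)) < 1e-10

    def test_matches_eigenvector_oracle(self, reference_renorm):
        res = bm.stationary_distribution(reference_renorm)
        vals, vecs = np.linalg.eig(reference_renorm.probs.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        stat = np.real(vecs[:, k])
        stat = stat / stat.sum()
        assert np.allclose(res.distribution.probs, stat, atol=1e-9)

    def test_identity_flags_non_uniqueness(self):
        res = bm.stationary_distribution(bm.TransitionMatrix(np.eye(4)))
        assert not res.unique

    def test_block_chain_absorbs_into_closed_class(self):
        """States 2/3 leak into the symmetric closed class {0, 1}."""
        P = np.array([
            [0.5, 0.5, 0.0, 0.0],
            [0.5, 0.5, 0.0, 0.0],
            [0.25, 0.25, 0.25, 0.25],
            [0.25, 0.25, 0.25, 0.25],
        ])
        res = bm.stationary_distribution(bm.TransitionMatrix(P))
        assert np.allclose(res.distribution.probs, [0.5, 0.5, 0.0, 0.0], atol=1e-9)


class TestStateDistribution:
    def test_sum_enforced_when_normalized(self):
        with pytest.raises(bm.InvalidInputError):
            StateDistribution([0.5, 0.5, 0.5, 0.5])

    def test_raw_vectors_allowed_when_flagged(self):
        d = StateDistribution([0.5, 0.5, 0.5, 0.5], normalized=False)
        assert d.probs.sum() == pytest.approx(2.0)

    def test_trajectory_requires_consecutive_indices(self):
        a = StateDistribution([1, 0, 0, 0], time_index=0)
        b = StateDistribution([1, 0, 0, 0], time_index=2)
        with pytest.raises(bm.InvalidInputError):
            bm.Trajectory([a, b])
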