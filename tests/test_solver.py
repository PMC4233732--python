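"""Recruitment solver: QP correctness on analytic toys, scheme masks,
and invariance properties of the full-model solve."""

import numpy as np
import pytest

from jawsim.anatomy import CLOSER_PARTS, build_model
from jawsim.mandible import JawPose
from jawsim.solver import (RecruitmentScheme, min_effort_qp, muscle_group,
                           solve_step)


class TestMinEffortQP:
    def test_zero_demand_gives_zero_activations(self):
        A = np.random.default_rng(0).normal(size=(6, 10))
        x, res = min_effort_qp(A, np.zeros(6), n_bounded=10)
        assert np.allclose(x, 0.0, atol=1e-12)

    def test_single_strand_linear_activation(self):
        """One strand collinear with a 5 N demand at 10 N capacity -> a = 0.5."""
        x, res = min_effort_qp(np.array([[10.0]]), np.array([5.0]), n_bounded=1)
        assert x[0] == pytest.approx(0.5, abs=1e-12)
        assert abs(res).max() < 1e-9

    def test_two_identical_strands_share_equally(self):
        """Minimum-norm KKT point of two parallel strands is the equal split."""
        A = np.array([[10.0, 10.0]])
        x, res = min_effort_qp(A, np.array([8.0]), n_bounded=2)
        assert np.allclose(x, [0.4, 0.4], atol=1e-10)

    def test_activation_upper_bound_is_respected(self):
        A = np.array([[10.0, 1.0]])
        x, res = min_effort_qp(A, np.array([10.5]), n_bounded=2)
        assert x[0] <= 1.0 + 1e-12
        assert abs(res).max() < 1e-9

    def test_doubling_capacity_halves_interior_activations(self):
        A = np.array([[10.0, 0.0, 5.0], [0.0, 10.0, 5.0]])
        b = np.array([3.0, 3.0])
        x1, _ = min_effort_qp(A, b, n_bounded=3)
        x2, _ = min_effort_qp(2 * A, b, n_bounded=3)
        assert np.allclose(x2, x1 / 2, atol=1e-10)

    def test_analytic_kkt_solution(self):
        """Interior optimum a = A^T (A A^T)^-1 b for an unconstrained-
        feasible problem."""
        A = np.array([[10.0, 0.0, 5.0], [0.0, 10.0, 5.0]])
        b = np.array([3.0, 3.0])
        x, res = min_effort_qp(A, b, n_bounded=3)
        expected = A.T @ np.linalg.solve(A @ A.T, b)
        assert np.allclose(x, expected, atol=1e-10)
        assert abs(res).max() < 1e-9

    def test_nonnegative_reaction_columns(self):
        """Reaction variables stay non-negative even when a negative value
        would fit the constraint better."""
        A = np.array([[5.0, -1.0]])  # one strand, one reaction direction
        x, res = min_effort_qp(A, np.array([2.0]), n_bounded=1)
        assert x[1] >= 0.0


class TestRecruitmentScheme:
    def test_opening_allows_digastric_only(self, default_model):
        scheme = RecruitmentScheme.for_mode("shearing")
        mask = scheme.allowed_mask(default_model, "opening")
        muscles = {default_model.strands[i].muscle for i in np.flatnonzero(mask)}
        assert muscles == {"digastric"}

    def test_fast_closing_allows_exactly_group_one(self, default_model):
        scheme = RecruitmentScheme.for_mode("crushing")
        mask = scheme.allowed_mask(default_model, "fast_closing")
        keys = {(default_model.strands[i].muscle, default_model.strands[i].side)
                for i in np.flatnonzero(mask)}
        assert keys == muscle_group(default_model, 1)

    def test_slow_closing_allows_both_groups(self, default_model):
        scheme = RecruitmentScheme.for_mode("crushing")
        mask = scheme.allowed_mask(default_model, "slow_closing")
        keys = {(default_model.strands[i].muscle, default_model.strands[i].side)
                for i in np.flatnonzero(mask)}
        assert keys == muscle_group(default_model, 1) | muscle_group(default_model, 2)

    def test_groups_are_mirror_images(self, default_model):
        flip = {"left": "right", "right": "left"}
        g1 = muscle_group(default_model, 1)
        g2 = muscle_group(default_model, 2)
        assert {(m, flip[s]) for m, s in g1} == g2

    def test_incisor_mode_allows_all_closers_and_ties_mirrors(self, default_model):
        scheme = RecruitmentScheme.for_mode("incisor")
        mask = scheme.allowed_mask(default_model, "slow_closing")
        muscles = {default_model.strands[i].muscle for i in np.flatnonzero(mask)}
        assert muscles == set(CLOSER_PARTS)
        pairs = scheme.tie_pairs(default_model)
        assert len(pairs) == 75  # one tie per right-side strand
        for i, j in pairs:
            si, sj = default_model.strands[i], default_model.strands[j]
            assert si.muscle == sj.muscle and {si.side, sj.side} == {"left", "right"}


class TestSolveStep:
    def test_no_load_means_no_activation(self, default_model):
        """Without gravity, passive tension or a bolus there is nothing to
        balance and the minimum-effort answer is zero everywhere."""
        scheme = RecruitmentScheme.for_mode("crushing")
        r = solve_step(default_model, JawPose(sagittal_deg=2.0), scheme,
                       "slow_closing", gravity_on=False, include_passive=False)
        assert r.feasible
        assert np.allclose(r.activations, 0.0, atol=1e-10)

    def test_solution_invariant_to_strand_enumeration_order(self, default_model):
        import copy
        scheme = RecruitmentScheme.for_mode("crushing")
        pose = JawPose(sagittal_deg=1.0, frontal_deg=4.0)
        # reaction of a 40 N vertical bite at the right molar (20, -5, -8)
        wrench = np.array([0.0, 0.0, -40.0, 200.0, 800.0, 0.0])
        r1 = solve_step(default_model, pose, scheme, "slow_closing",
                        bolus_wrench=wrench, gravity_on=False,
                        include_passive=False)
        shuffled = copy.copy(default_model)
        rng = np.random.default_rng(12)
        perm = rng.permutation(len(default_model.strands))
        shuffled.strands = [default_model.strands[i] for i in perm]
        r2 = solve_step(shuffled, pose, scheme, "slow_closing",
                        bolus_wrench=wrench, gravity_on=False,
                        include_passive=False)
        assert r1.feasible and r2.feasible
        assert np.allclose(r1.activations[perm], r2.activations, atol=1e-7)
        assert r1.objective == pytest.approx(r2.objective, rel=1e-9)

    def test_incisor_ties_give_identical_mirrored_activations(self, default_model):
        scheme = RecruitmentScheme.for_mode("incisor")
        pose = JawPose(sagittal_deg=2.0)
        # reaction of a 40 N vertical bite at the incisor point (55, 0, -14)
        wrench = np.array([0.0, 0.0, -40.0, 0.0, 2200.0, 0.0])
        r = solve_step(default_model, pose, scheme, "slow_closing",
                       bolus_wrench=wrench, gravity_on=False,
                       include_passive=False)
        for i, j in scheme.tie_pairs(default_model):
            assert r.activations[i] == pytest.approx(r.activations[j], abs=1e-12)

    def test_infeasible_demand_is_flagged_not_silent(self, default_model):
        scheme = RecruitmentScheme.for_mode("crushing")
        huge = np.array([0.0, 0.0, 5000.0, 0.0, -200000.0, 0.0])
        r = solve_step(default_model, JawPose(sagittal_deg=1.0), scheme,
                       "slow_closing", bolus_wrench=huge, gravity_on=False,
                       include_passive=False)
        assert not r.feasible
        assert r.force_residual > 1.0
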