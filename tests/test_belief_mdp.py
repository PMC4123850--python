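"""Belief grid, Bayes updating, rewards and the three solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eagleadapt as ea
from eagleadapt.belief_mdp import _Prepped, _improvement_sweep

BELIEF = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=3, max_size=3
).map(lambda v: np.array(v) / np.sum(v))


class TestBeliefGrid:
    def test_vertices_and_snap(self):
        grid = ea.BeliefGrid(10)
        assert grid.n_points == 66
        for i, vec in enumerate(np.eye(3)):
            vi = grid.vertex_index(i)
            np.testing.assert_allclose(grid.points[vi], vec)
            assert grid.snap(vec)[0] == vi
        # grid points snap to themselves
        np.testing.assert_array_equal(
            grid.snap(grid.points), np.arange(grid.n_points)
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(B=BELIEF)
    def test_barycentric_weights_reproduce_linear_functions(self, B):
        grid = ea.BeliefGrid(13)
        idx, w = grid.barycentric(B)
        assert w.min() >= 0 and w.sum() == pytest.approx(1.0, abs=1e-12)
        c = np.array([0.3, -1.2, 2.0])
        interp = float(w @ (grid.points[idx] @ c))
        assert interp == pytest.approx(float(B @ c), abs=1e-10)


@pytest.fixture(scope="module")
def small_kernels(small_params):
    case = ea.get_preset("pr_known")
    return ea.build_case_kernels(small_params, case, mode="full"), small_params


class TestBeliefUpdate:
    def test_hand_computed_posterior_single_site(self, base):
        # uniform prior, occupied unrestricted site succeeds and is
        # re-occupied: posterior proportional to p_u per model, since the
        # shared p_s cancels in the normalization
        params = base.with_(n_sites=1)
        kernels = ea.build_case_kernels(params, ea.get_preset("pr_known"), mode="full")
        post = ea.belief_update(
            np.full(3, 1 / 3), kernels, S=1, A=0, Y=(1, 0), S_next=1
        )
        np.testing.assert_allclose(post, [0.38737, 0.34556, 0.26706], atol=1e-3)

    def test_degenerate_prior_is_absorbing(self, small_kernels):
        kernels, _ = small_kernels
        for obs in [((0, 0), 3), ((1, 0), 2)]:
            post = ea.belief_update(
                np.array([0.0, 1.0, 0.0]), kernels, 3, 1, obs[0], obs[1]
            )
            np.testing.assert_array_equal(post, [0.0, 1.0, 0.0])

    def test_identical_kernels_leave_belief_unchanged(self, small_params):
        probs = ea.SuccessProbs(0.4, 0.5)
        k = ea.build_kernel(small_params, probs, mode="full")
        B = np.array([0.2, 0.5, 0.3])
        post = ea.belief_update(B, [k, k, k], 4, 2, (1, 1), 5)
        np.testing.assert_allclose(post, B, atol=1e-15)

    def test_impossible_observation_raises(self, small_kernels):
        kernels, _ = small_kernels
        with pytest.raises(ValueError, match="impossible"):
            # a restricted success cannot be seen when no site is restricted
            ea.belief_update(np.full(3, 1 / 3), kernels, 2, 0, (0, 1), 2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(B=BELIEF)
    def test_bayes_martingale(self, B, small_kernels):
        # averaging the posterior over the belief-mixture predictive
        # distribution returns the prior exactly
        kernels, _ = small_kernels
        for (S, A) in [(0, 0), (4, 2), (6, 6)]:
            flats = np.stack([k.flat(S, A).ravel() for k in kernels], axis=1)
            pred = flats @ B
            keep = pred > 0
            posts = flats[keep] * B / pred[keep, None]
            np.testing.assert_allclose(pred[keep] @ posts, B, atol=1e-12)


class TestExpectedReward:
    def test_boundary_cases(self, base):
        probs = ea.get_preset("pr_known").success_probs(base)
        spec = ea.RewardSpec()
        B = np.array([0.0, 1.0, 0.0])
        assert ea.expected_reward(0, 0, B, probs, spec, base) == 0.0
        assert ea.expected_reward(25, 25, B, probs, spec, base) == 0.0

    def test_arithmetic_oracle(self, base):
        probs = ea.get_preset("pr_known").success_probs(base)
        B = np.array([0.0, 1.0, 0.0])
        # S=25, A=10: 15 unrestricted sites
        ey = 10 * probs[1].p_r + 15 * probs[1].p_u
        expected = ey**0.85 * 15**0.15
        got = ea.expected_reward(25, 10, B, probs, ea.RewardSpec(), base)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_linear_form(self, base):
        probs = ea.get_preset("pr_known").success_probs(base)
        B = np.full(3, 1 / 3)
        spec = ea.RewardSpec(alpha=0.85, form="linear")
        ey = sum(b * (2 * p.p_r + 3 * p.p_u) for b, p in zip(B, probs))
        got = ea.expected_reward(5, 2, B, probs, spec, base)
        assert got == pytest.approx(0.85 * ey + 0.15 * 23, rel=1e-12)

    def test_infeasible_action_rejected(self, base):
        probs = ea.get_preset("pr_known").success_probs(base)
        with pytest.raises(ValueError):
            ea.expected_reward(2, 3, np.full(3, 1 / 3), probs, ea.RewardSpec(), base)


class TestSolveCertain:
    def test_no_disturbance_never_restricts(self, base):
        pol = ea.solve_certain(ea.get_preset("pr_known"), 0, base)
        assert np.all(pol.actions == 0)

    def test_myopic_limit_matches_reward_argmax(self, base):
        p0 = base.with_(discount=0.0)
        case = ea.get_preset("pu_known")
        pol = ea.solve_certain(case, 2, p0)
        probs = [case.models[2].success_probs(p0)]
        for S in range(p0.n_sites + 1):
            rewards = [
                ea.expected_reward(S, A, [1.0], probs, ea.RewardSpec(), p0)
                for A in range(S + 1)
            ]
            assert pol.actions[S] == int(np.argmax(rewards))

    def test_restrictions_decrease_with_hare_abundance(self, base):
        totals = [
            ea.solve_certain(ea.get_preset("pr_known"), 1, base, hare=h).actions.sum()
            for h in (2.5, 10.0, 17.5, 25.0, 32.5)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        assert totals[0] > totals[-1]


class TestActiveSolver:
    def test_bellman_sweeps_contract(self, small_params):
        case = ea.get_preset("pr_known")
        kernels = ea.build_case_kernels(small_params, case)
        probs = case.success_probs(small_params)
        grid = ea.BeliefGrid(8)
        prep = _Prepped(kernels, probs, grid, ea.RewardSpec(), small_params)
        V = np.zeros((small_params.n_sites + 1, grid.n_points))
        deltas = []
        for _ in range(8):
            V_new, _pol = _improvement_sweep(prep, V)
            deltas.append(np.max(np.abs(V_new - V)))
            V = V_new
        ratios = np.array(deltas[2:]) / np.array(deltas[1:-1])
        assert np.all(ratios <= small_params.discount + 1e-9)

    def test_mixed_signal_modes_rejected(self, small_params):
        case = ea.get_preset("pr_known")
        ks = ea.build_case_kernels(small_params, case, mode="full")
        ks[2] = ea.garble(ks[2], "none")
        with pytest.raises(ValueError, match="mode"):
            ea.solve_active(ks, case.success_probs(small_params),
                            ea.BeliefGrid(5), small_params)

    def test_active_dominates_passive_values(self, solved50):
        active = solved50("pr_known")
        passive = solved50("pr_known", strategy="passive")
        assert np.all(active.values >= passive.values - 1e-3 * active.values.mean())

    def test_policy_stable_under_grid_refinement(self, base, solved50):
        fine = solved50("pr_known")
        coarse = ea.solve_case(ea.get_preset("pr_known"), base, grid=25)
        idx = fine.grid.snap(coarse.grid.points)
        disagree = (coarse.actions != fine.actions[:, idx]).mean()
        assert disagree < 0.05

    def test_policy_frame_layout(self, base):
        pol = ea.solve_case(ea.get_preset("pr_known"), base, grid=3,
                            strategy="passive")
        frame = ea.policy_frame(pol)
        assert list(frame.columns) == ["S", "b1", "b2", "b3", "action", "value"]
        assert len(frame) == (base.n_sites + 1) * pol.grid.n_points
        assert (frame.action <= frame.S).all()


def test_value_gain_requires_common_grid():
    with pytest.raises(ValueError):
        ea.value_gain(np.zeros((3, 4)), np.zeros((3, 5)))
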