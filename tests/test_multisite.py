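"""Category-count kernels: enumeration, convolution, garbling."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

import eagleadapt as ea
from eagleadapt.model_core import EVENT_ROWS


def brute_force_kernel(params, probs, S, A):
    """Exhaustive per-site enumeration of the joint (Y1, Y2, S_next) law."""
    N = params.n_sites
    table = ea.site_event_table(probs, params)
    cols = [0] * (N - S) + [1] * (S - A) + [2] * A
    out = np.zeros((S - A + 1, A + 1, N + 1))
    for events in product(range(6), repeat=N):
        p = 1.0
        y1 = y2 = occ = 0
        for ev, c in zip(events, cols):
            p *= table[ev, c]
            r1, r2, ro = EVENT_ROWS[ev]
            y1 += r1
            y2 += r2
            occ += ro
        if (y1 <= S - A) and (y2 <= A):
            out[y1, y2, occ] += p
    return out


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_sites,n_cats,expected",
        [(2, 4, 10), (3, 4, 20), (0, 4, 1), (5, 2, 6)],
    )
    def test_composition_counts(self, n_sites, n_cats, expected):
        comps = ea.enumerate_assignments(n_sites, n_cats)
        assert comps.shape == (expected, n_cats)
        assert np.all(comps.sum(axis=1) == n_sites)

    def test_two_assignments_share_signal_state_pair(self):
        # with categories (NE, SE, NO, SO), both (0,1,1,0) and (1,0,0,1)
        # produce one success and one occupied site next year
        comps = ea.enumerate_assignments(2, 4)
        rows = {tuple(r) for r in comps}
        assert {(0, 1, 1, 0), (1, 0, 0, 1)} <= rows
        for r in ((0, 1, 1, 0), (1, 0, 0, 1)):
            y, s_next = r[1] + r[3], r[2] + r[3]
            assert (y, s_next) == (1, 1)

    def test_assignment_table_sums_to_kernel(self, base):
        params = base.with_(n_sites=2)
        probs = ea.SuccessProbs(0.405, 0.454)
        at = ea.assignment_table(params, probs, S=1, A=0)
        kern = ea.build_kernel(params, probs, mode="full")
        summed = at.groupby(["Y1", "Y2", "S_next"])["probability"].sum()
        for (y1, y2, sn), p in summed.items():
            assert kern.table(1, 0)[y1, y2, sn] == pytest.approx(p, abs=1e-12)
        assert at["probability"].sum() == pytest.approx(1.0, abs=1e-12)


class TestKernel:
    def test_matches_brute_force_enumeration(self, base):
        params = base.with_(n_sites=3)
        probs = ea.get_preset("pr_known").models[1].success_probs(params)
        kern = ea.build_kernel(params, probs, mode="full")
        for S in range(4):
            for A in range(S + 1):
                np.testing.assert_allclose(
                    kern.table(S, A),
                    brute_force_kernel(params, probs, S, A),
                    atol=1e-12,
                )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        pu=st.floats(0.0, 1.0), pr=st.floats(0.0, 1.0),
        pc=st.floats(0.0, 1.0), pn=st.floats(0.0, 1.0), ps=st.floats(0.0, 1.0),
    )
    def test_brute_force_equivalence_random_parameters(self, pu, pr, pc, pn, ps):
        params = ea.SiteParams().with_(n_sites=2, p_c=pc, p_n=pn, p_s=ps)
        probs = ea.SuccessProbs(pu, pr)
        kern = ea.build_kernel(params, probs, mode="full")
        for (S, A) in kern.pairs():
            np.testing.assert_allclose(
                kern.table(S, A), brute_force_kernel(params, probs, S, A),
                atol=1e-12,
            )

    def test_columns_sum_to_one_at_full_size(self, base):
        probs = ea.get_preset("pu_known").models[2].success_probs(base)
        kern = ea.build_kernel(base, probs, mode="full")
        for (S, A) in kern.pairs():
            assert kern.table(S, A).sum() == pytest.approx(1.0, abs=1e-12)
        assert len(kern.pairs()) == (base.n_sites + 1) * (base.n_sites + 2) // 2

    def test_infeasible_action_rejected(self, small_params):
        probs = ea.SuccessProbs(0.4, 0.5)
        kern = ea.build_kernel(small_params, probs)
        with pytest.raises(ValueError, match="restricted"):
            kern.table(2, 3)


@pytest.fixture(scope="module")
def full(small_params):
    probs = ea.SuccessProbs(0.405, 0.454)
    return ea.build_kernel(small_params, probs, mode="full"), small_params, probs


class TestGarble:
    def test_identity_and_refinement_rejection(self, full):
        kern, *_ = full
        same = ea.garble(kern, "full")
        np.testing.assert_array_equal(same.table(3, 1), kern.table(3, 1))
        y1 = ea.garble(kern, "unrestricted_only")
        with pytest.raises(ValueError, match="refine"):
            ea.garble(y1, "full")
        with pytest.raises(ValueError, match="refine"):
            ea.garble(y1, "total")

    def test_coarsenings_match_direct_construction(self, full):
        kern, params, probs = full
        direct = ea.build_kernel(params, probs, mode="unrestricted_only")
        garbled = ea.garble(kern, "unrestricted_only")
        for pair in kern.pairs():
            np.testing.assert_allclose(
                garbled.table(*pair), direct.table(*pair), atol=1e-14
            )

    def test_total_sums_antidiagonals(self, full):
        kern, *_ = full
        t = kern.table(4, 2)
        tot = ea.garble(kern, "total").table(4, 2)
        for y in range(t.shape[0] + t.shape[1] - 1):
            manual = sum(
                t[y1, y - y1]
                for y1 in range(max(0, y - t.shape[1] + 1), min(y, t.shape[0] - 1) + 1)
            )
            np.testing.assert_allclose(tot[y], manual, atol=1e-14)

    def test_no_signal_equals_binomial_transition(self, full):
        # marginal over signals must equal the N-site binomial convolution
        # of the single-site occupancy transition
        kern, params, probs = full
        tr = ea.state_transition(probs, params)
        nosig = ea.garble(kern, "none")
        N = params.n_sites
        for (S, A) in kern.pairs():
            groups = [
                binom.pmf(np.arange(N - S + 1), N - S, params.p_c),
                binom.pmf(np.arange(S - A + 1), S - A, tr[1, 1]),
                binom.pmf(np.arange(A + 1), A, tr[1, 2]),
            ]
            expect = np.convolve(np.convolve(groups[0], groups[1]), groups[2])
            np.testing.assert_allclose(nosig.table(S, A), expect, atol=1e-12)


def test_kernel_frame_is_tidy(small_params):
    kern = ea.build_kernel(small_params, ea.SuccessProbs(0.4, 0.5), mode="total")
    frame = ea.kernel_frame(kern)
    assert list(frame.columns) == ["S", "A", "Y1", "Y2", "S_next", "probability"]
    sums = frame.groupby(["S", "A"])["probability"].sum()
    np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)
    assert (frame["Y2"] == -1).all()  # total mode reports the sum in Y1
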