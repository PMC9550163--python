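"""Fuzzy layer: membership anchor identities, degree bounds, mean-of-maxima
against a brute-force loop oracle, and the 3C output contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usqrate.fuzzy import (
    MembershipParams,
    defuzzify_mom,
    fuzzy_forward,
    membership_gaussian,
    membership_s,
    membership_triangular,
)

from oracles import naive_fuzzy_forward

P = MembershipParams()  # p=3, q=4.5, r=6, sigma=1.5, r_max=6


class TestParams:
    def test_default_rule_ties_to_r_max(self):
        assert (P.p, P.q, P.r) == (3.0, 4.5, 6.0)
        q = MembershipParams.from_r_max(8.0)
        assert (q.p, q.q, q.r) == (4.0, 6.0, 8.0)

    @pytest.mark.parametrize("kwargs", [dict(p=4.5, q=3.0), dict(q=6.0, r=6.0), dict(sigma=0.0)])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MembershipParams(**{**dict(p=3.0, q=4.5, r=6.0, sigma=1.5), **kwargs})


class TestMembershipAnchors:
    def test_gaussian_peak_and_sigma_point(self):
        assert membership_gaussian(P.q, P) == 1.0
        assert membership_gaussian(P.q + P.sigma, P) == pytest.approx(np.exp(-0.5))
        assert membership_gaussian(P.q - P.sigma, P) == pytest.approx(np.exp(-0.5))

    def test_gaussian_monotone_tails(self):
        xs = np.linspace(P.q, P.q + 50, 200)
        vals = membership_gaussian(xs, P)
        assert np.all(np.diff(vals) <= 0)
        vals_left = membership_gaussian(P.q - (xs - P.q), P)
        assert np.all(np.diff(vals_left) <= 0)

    def test_triangle_vertex_and_feet(self):
        assert membership_triangular(P.q, P) == 1.0
        assert membership_triangular(P.p, P) == 0.0
        assert membership_triangular(P.r, P) == 0.0
        assert membership_triangular(-1000.0, P) == 0.0
        assert membership_triangular(1000.0, P) == 0.0

    def test_triangle_rising_edge_midpoint(self):
        prm = MembershipParams(p=3.0, q=4.5, r=6.0)
        assert membership_triangular(3.75, prm) == pytest.approx(0.5)

    def test_s_knots(self):
        assert membership_s(P.p, P) == 0.0
        assert membership_s(P.r, P) == 1.0
        assert membership_s(0.5 * (P.p + P.r), P) == pytest.approx(0.5)

    def test_s_lower_branch_value(self):
        prm = MembershipParams(p=3.0, q=4.5, r=6.0)
        assert membership_s(3.75, prm) == pytest.approx(2 * (0.75 / 3) ** 2)

    def test_s_continuity_at_midpoint(self):
        m = 0.5 * (P.p + P.r)
        for eps in (1e-3, 1e-6, 1e-9):
            assert abs(membership_s(m - eps, P) - membership_s(m + eps, P)) < 10 * eps

    @given(st.floats(min_value=-12.0, max_value=12.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_degrees_in_unit_interval(self, x):
        for fn in (membership_gaussian, membership_triangular, membership_s):
            d = fn(x, P)
            assert 0.0 <= d <= 1.0

    def test_degrees_in_unit_interval_on_dense_grid(self):
        xs = np.linspace(-2 * P.r_max, 2 * P.r_max, 4001)
        for fn in (membership_gaussian, membership_triangular, membership_s):
            d = fn(xs, P)
            assert d.min() >= 0.0 and d.max() <= 1.0


class TestDefuzzifyMom:
    def test_single_maximum(self):
        deg = np.array([[0.1, 0.9], [0.3, 0.2]])
        act = np.array([[5.0, 2.0], [1.0, 0.0]])
        assert defuzzify_mom(deg, act) == 2.0

    def test_tied_maxima_average_activations(self):
        deg = np.array([[0.9, 0.9], [0.1, 0.2]])
        act = np.array([[1.0, 3.0], [5.0, 6.0]])
        assert defuzzify_mom(deg, act) == pytest.approx(2.0)

    def test_constant_field_returns_constant(self):
        deg = np.full((3, 3), 0.5)
        act = np.full((3, 3), 4.2)
        assert defuzzify_mom(deg, act) == pytest.approx(4.2)

    def test_collapse_variant_returns_max_degree(self):
        deg = np.array([[0.1, 0.9], [0.3, 0.2]])
        act = np.array([[5.0, 2.0], [1.0, 0.0]])
        assert defuzzify_mom(deg, act, collapse_to_degree=True) == pytest.approx(0.9)

    def test_near_ties_within_relative_tolerance(self):
        deg = np.array([[0.9, 0.9 * (1 - 1e-8)], [0.0, 0.0]])
        act = np.array([[2.0, 4.0], [0.0, 0.0]])
        assert defuzzify_mom(deg, act) == pytest.approx(3.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            defuzzify_mom(np.zeros((0,)), np.zeros((0,)))
        with pytest.raises(ValueError, match="shape"):
            defuzzify_mom(np.zeros((2, 2)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="degrees"):
            defuzzify_mom(np.full((2, 2), 1.5), np.zeros((2, 2)))


class TestFuzzyForward:
    @pytest.mark.parametrize("c", [1, 8, 32, 512])
    def test_output_length_is_three_c(self, c, rng):
        fmap = rng.random((2, 2, c)) * P.r_max
        assert fuzzy_forward(fmap, P).shape == (3 * c,)

    def test_single_position_map_passes_through(self):
        fmap = np.full((1, 1, 1), 2.7)
        assert np.allclose(fuzzy_forward(fmap, P), [2.7, 2.7, 2.7])

    def test_matches_naive_double_loop_oracle(self, rng):
        fmap = rng.random((4, 4, 8)) * P.r_max
        got = fuzzy_forward(fmap, P)
        want = naive_fuzzy_forward(fmap, P.p, P.q, P.r, P.sigma)
        assert np.allclose(got, want, rtol=1e-12, atol=0)

    def test_crisp_values_stay_in_activation_range(self, rng):
        fmap = rng.random((5, 7, 16)) * P.r_max
        out = fuzzy_forward(fmap, P)
        assert out.min() >= 0.0 and out.max() <= P.r_max

    def test_permutation_equivariance(self, rng):
        c = 10
        fmap = rng.random((3, 3, c)) * P.r_max
        perm = rng.permutation(c)
        base = fuzzy_forward(fmap, P).reshape(3, c)
        permuted = fuzzy_forward(fmap[:, :, perm], P).reshape(3, c)
        assert np.allclose(permuted, base[:, perm])

    def test_rejects_activations_above_ceiling(self):
        with pytest.raises(ValueError, match="activations"):
            fuzzy_forward(np.full((2, 2, 1), 7.0), P)

    def test_rejects_wrong_rank(self, rng):
        with pytest.raises(ValueError, match="H x W x C"):
            fuzzy_forward(rng.random((4, 4)), P)
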