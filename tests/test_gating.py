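"""DYK subunit gating: rates, detailed balance, equilibrium, open probability."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
import scipy.linalg
import scipy.stats
from hypothesis import given, settings, strategies as st

import puffsim as ps
from puffsim.core import _generator_matrix, _site_rates


def make_params(K_act=0.25, K_inh_noip3=0.111, K_inh_ip3=20.0, K_ip3_inh=0.7,
                a_act=40.0, a_inh=0.1, a_ip3=0.15, b_inh_ip3=None):
    """Build a parameter set satisfying the loop constraint by construction."""
    K_ip3_noninh = K_ip3_inh * K_inh_noip3 / K_inh_ip3
    b_inh_ip3 = K_inh_ip3 * a_inh if b_inh_ip3 is None else b_inh_ip3
    return ps.GatingParameters(
        a_act=a_act, b_act=a_act * K_act,
        a_inh_ip3=a_inh, b_inh_ip3=b_inh_ip3,
        a_inh_noip3=a_inh, b_inh_noip3=a_inh * K_inh_noip3,
        a_ip3_noninh=a_ip3, b_ip3_noninh=a_ip3 * K_ip3_noninh,
        a_ip3_inh=a_ip3, b_ip3_inh=a_ip3 * K_ip3_inh,
    )


def equilibrium_product_form(c, ip3, params):
    """Independent closed-form stationary law, valid under detailed balance.

    Builds each state's Boltzmann-like weight as a product of occupancy
    ratios along a path from (0,0,0): activating site, then inhibiting site
    (IP3-free rate pair), then IP3 site (rate pair set by h).
    """
    w = np.zeros(8)
    for s in range(8):
        i, a, h = (s >> 2) & 1, (s >> 1) & 1, s & 1
        weight = (c / params.K_act) ** a
        weight *= (c / params.K_inh_noip3) ** h
        if i:
            weight *= ip3 / (params.K_ip3_inh if h else params.K_ip3_noninh)
        w[s] = weight
    return w / w.sum()


class TestTransitionRates:
    def test_exactly_three_transitions_one_per_site(self, gating):
        for code in range(8):
            out = ps.transition_rates(code, 0.3, 0.1, gating)
            assert len(out) == 3
            flipped = {t.code ^ code for t, _ in out}
            assert flipped == {1, 2, 4}

    def test_no_ip3_means_no_ip3_binding(self, gating):
        out = ps.transition_rates(ps.SubunitState(0, 0, 0), 0.1, 0.0, gating)
        ip3_rate = [r for t, r in out if t.i == 1][0]
        assert ip3_rate == 0.0

    def test_open_state_inhibition_rate_proportional_to_concentration(self, gating, domain):
        out = ps.transition_rates(ps.SubunitState(1, 1, 0), domain.c_high, 0.07, gating)
        inh_rate = [r for t, r in out if t.h == 1][0]
        assert inh_rate == pytest.approx(gating.a_inh_ip3 * domain.c_high)

    def test_total_unbinding_rate_from_fully_bound_state(self, gating):
        # at zero ligand only the three unbinding edges remain
        out = ps.transition_rates(ps.SubunitState(1, 1, 1), 0.0, 0.0, gating)
        assert sum(r for _, r in out) == pytest.approx(
            gating.b_act + gating.b_inh_ip3 + gating.b_ip3_inh
        )

    def test_rate_pair_selection_depends_on_other_sites(self, gating):
        # h off-rate switches with the IP3 site
        r_h_i1 = dict()
        for i in (0, 1):
            out = ps.transition_rates(ps.SubunitState(i, 0, 1), 0.0, 0.0, gating)
            r_h_i1[i] = [r for t, r in out if t.h == 0][0]
        assert r_h_i1[1] == gating.b_inh_ip3
        assert r_h_i1[0] == gating.b_inh_noip3
        # IP3 off-rate switches with the inhibiting site
        for h, expected in ((0, gating.b_ip3_noninh), (1, gating.b_ip3_inh)):
            out = ps.transition_rates(ps.SubunitState(1, 0, h), 0.0, 0.0, gating)
            assert [r for t, r in out if t.i == 0][0] == expected

    def test_negative_concentration_rejected(self, gating):
        with pytest.raises(ValueError):
            ps.transition_rates(0, -0.1, 0.07, gating)
        with pytest.raises(ValueError):
            ps.transition_rates(0, 0.1, -0.07, gating)


class TestDetailedBalance:
    def test_default_parameters_satisfy_loop_constraint(self, gating):
        assert ps.detailed_balance_residual(gating) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_loop_residual_zero(self):
        p = make_params(K_act=1.0, K_inh_noip3=1.0, K_inh_ip3=1.0 + 1e-9, K_ip3_inh=1.0)
        assert ps.detailed_balance_residual(p) == pytest.approx(0.0, abs=1e-8)

    def test_perturbed_constant_gives_log_residual(self, gating):
        p = dataclasses.replace(gating, b_inh_ip3=gating.b_inh_ip3 * 1.1)
        assert ps.detailed_balance_residual(p) == pytest.approx(math.log(1.1), rel=1e-9)

    def test_inhibition_weaker_at_high_ip3_enforced(self, gating):
        with pytest.raises(ValueError, match="K_inh_ip3"):
            dataclasses.replace(gating, b_inh_ip3=gating.a_inh_ip3 * 0.05)

    def test_rates_must_be_positive(self, gating):
        with pytest.raises(ValueError, match="a_act"):
            dataclasses.replace(gating, a_act=0.0)


class TestSubunitEquilibrium:
    def test_matches_nullspace_of_generator(self, gating):
        pi = ps.subunit_equilibrium(0.07, 0.07, gating)
        Q = _generator_matrix(0.07, 0.07, gating)
        ns = scipy.linalg.null_space(Q)
        assert ns.shape[1] == 1
        ref = ns[:, 0] / ns[:, 0].sum()
        np.testing.assert_allclose(pi, ref, atol=1e-10)
        np.testing.assert_allclose(Q @ pi, np.zeros(8), atol=1e-10)

    def test_matches_product_form_under_detailed_balance(self, gating):
        for c, ip3 in [(0.07, 0.07), (1.0, 0.02), (10.0, 1.0), (0.01, 5.0)]:
            pi = ps.subunit_equilibrium(c, ip3, gating)
            np.testing.assert_allclose(pi, equilibrium_product_form(c, ip3, gating), atol=1e-12)

    def test_no_ip3_empties_upper_plane(self, gating):
        pi = ps.subunit_equilibrium(0.5, 0.0, gating)
        assert pi[4:].sum() == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_half_occupancy_is_uniform(self):
        p = make_params(K_act=1.0, K_inh_noip3=1.0, K_inh_ip3=1.0 + 1e-12, K_ip3_inh=1.0)
        pi = ps.subunit_equilibrium(1.0, 1.0, p)
        np.testing.assert_allclose(pi, np.full(8, 1 / 8), rtol=1e-9)

    def test_normalized_and_nonnegative(self, gating):
        pi = ps.subunit_equilibrium(3.0, 0.2, gating)
        assert pi.min() >= 0
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_edgewise_flux_balance(self, gating):
        pi = ps.subunit_equilibrium(0.3, 0.1, gating)
        for s in range(8):
            for target, rate in ps.transition_rates(s, 0.3, 0.1, gating):
                back = [r for t, r in ps.transition_rates(target.code, 0.3, 0.1, gating) if t.code == s][0]
                if pi[s] > 1e-12:
                    assert pi[s] * rate == pytest.approx(pi[target.code] * back, rel=1e-8)

    def test_activating_occupancy_independent_of_ip3(self, gating):
        # activation rates do not depend on the other two sites
        for ip3 in (0.0, 0.07, 1.0):
            for c in (0.05, 0.25, 2.0):
                occ = ps.site_occupancy(c, ip3, gating, "activating")
                assert occ == pytest.approx(c / (c + gating.K_act), rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        c=st.floats(1e-3, 1e3), ip3=st.floats(1e-3, 1e2),
        K_inh_ip3=st.floats(1.0, 100.0), a_act=st.floats(1.0, 100.0),
        a_ip3=st.floats(0.01, 1.0),
    )
    def test_generator_annihilates_equilibrium(self, c, ip3, K_inh_ip3, a_act, a_ip3):
        p = make_params(K_inh_ip3=K_inh_ip3, a_act=a_act, a_ip3=a_ip3)
        pi = ps.subunit_equilibrium(c, ip3, p)
        Q = _generator_matrix(c, ip3, p)
        np.testing.assert_allclose(Q @ pi, np.zeros(8), atol=1e-9 * np.abs(Q).max())


class TestOpenProbability:
    def test_zero_without_ip3(self, gating):
        assert ps.channel_open_probability(0.1, 0.0, gating) == 0.0

    def test_three_of_four_binomial_form(self):
        # p = 1/2 per subunit gives 0.5**4 + 4 * 0.5**3 * 0.5 = 0.3125
        p = 0.5
        assert p**4 + 4 * p**3 * (1 - p) == pytest.approx(0.3125)
        # and the implementation reproduces the polynomial for its own p
        g = ps.GatingParameters()
        pi = ps.subunit_equilibrium(0.3, 0.5, g)
        po = ps.channel_open_probability(0.3, 0.5, g)
        q = pi[ps.OPEN_SUBSTATE]
        assert po == pytest.approx(q**4 + 4 * q**3 * (1 - q), rel=1e-12)

    def test_monotone_in_subunit_probability(self):
        f = lambda p: p**4 + 4 * p**3 * (1 - p)
        grid = np.linspace(0, 1, 101)
        assert np.all(np.diff([f(p) for p in grid]) >= 0)

    def test_bell_shape_and_rightward_shift_with_ip3(self, gating):
        # dose-response on a log grid spanning six decades
        c_grid = np.logspace(-3, 3, 200)
        argmaxes = []
        for ip3 in (0.02, 0.07, 0.2, 1.0):
            po = np.array([ps.channel_open_probability(c, ip3, gating) for c in c_grid])
            peak = int(np.argmax(po))
            assert 0 < peak < len(c_grid) - 1
            rising, falling = np.diff(po[: peak + 1]), np.diff(po[peak:])
            assert np.all(rising >= -1e-15)
            assert np.all(falling <= 1e-15)
            argmaxes.append(c_grid[peak])
        assert all(b >= a for a, b in zip(argmaxes, argmaxes[1:]))
        assert argmaxes[-1] > argmaxes[0]

    def test_curves_shift_upward_with_ip3(self, gating):
        c_grid = np.logspace(-2, 2, 50)
        lo = max(ps.channel_open_probability(c, 0.02, gating) for c in c_grid)
        hi = max(ps.channel_open_probability(c, 0.2, gating) for c in c_grid)
        assert hi > lo


class TestHalfOccupancy:
    def test_activating_site_half_occupancy_at_K_act(self, gating):
        c_half = ps.half_occupancy_concentration("activating", ip3=0.07)
        assert c_half == pytest.approx(gating.K_act, rel=1e-6)

    def test_inhibiting_site_half_occupancy_without_ip3(self, gating):
        c_half = ps.half_occupancy_concentration("inhibiting", ip3=0.0)
        assert c_half == pytest.approx(gating.K_inh_noip3, rel=1e-6)


class TestStochasticConsistency:
    def test_clamped_subunit_occupancy_matches_equilibrium(self, gating):
        """Long clamped single-subunit run reproduces the stationary law.

        States are subsampled at intervals long compared to the chain's
        mixing time so a chi-square test applies; rare states are pooled.
        """
        c, ip3 = 2.0, 2.0
        fractions, samples = ps.clamped_subunit_occupancy(
            c, ip3, gating, n_steps=9 * 10**8, dt=1e-5, seed=7, sample_stride=300_000
        )
        pi = ps.subunit_equilibrium(c, ip3, gating)
        counts = np.bincount(samples, minlength=8).astype(float)
        n = counts.sum()
        # pool states with small expected counts
        order = np.argsort(pi)
        pooled_obs, pooled_exp = [], []
        acc_o = acc_e = 0.0
        for s in order:
            acc_o += counts[s]
            acc_e += pi[s] * n
            if acc_e >= 10:
                pooled_obs.append(acc_o)
                pooled_exp.append(acc_e)
                acc_o = acc_e = 0.0
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
        stat, p = scipy.stats.chisquare(pooled_obs, f_exp=pooled_exp)
        assert p > 0.001
        # and the raw time fractions agree to a few percent
        np.testing.assert_allclose(fractions, pi, atol=0.02)
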