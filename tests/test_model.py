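"""Core model: grids, transport profiles, toy and full steady states."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from tolpal.errors import ValidationError
from tolpal.model import (
    SpeciesTotals,
    TolPalParams,
    TolPalState,
    ToyParams,
    ToyProfiles,
    make_grid,
    make_transport_profile,
    tolB_compartment_fractions,
    tolpal_rhs,
    tolpal_steady_state,
    toy_rhs,
    toy_steady_state,
)


class TestGrid:
    @pytest.mark.parametrize("L, n, first, last", [
        (4.0, 101, -2.0, 2.0),    # dividing-cell length
        (2.8, 101, -1.4, 1.4),    # non-dividing-cell length
    ])
    def test_spans_symmetric_domain(self, L, n, first, last):
        g = make_grid(L, n)
        assert g.x[0] == pytest.approx(first)
        assert g.x[-1] == pytest.approx(last)
        np.testing.assert_allclose(g.x, -g.x[::-1], atol=1e-12)

    def test_spacing_and_weights(self):
        g = make_grid(4.0, 17)
        assert g.dx == pytest.approx(0.25)
        assert g.weights.sum() == pytest.approx(4.0)

    @pytest.mark.parametrize("L, n", [(-1.0, 101), (0.0, 101), (4.0, 8)])
    def test_rejects_bad_arguments(self, L, n):
        with pytest.raises(ValidationError):
            make_grid(L, n)


class TestTransportProfile:
    @pytest.mark.parametrize("mode, sigma", [
        ("homogeneous", None),
        ("point_sink", None),
        ("truncated_normal", 0.08),
    ])
    def test_discrete_integral_equals_beta0(self, mode, sigma):
        g = make_grid(4.0, 101)
        tp = make_transport_profile(mode, 17.0, g, sigma=sigma)
        assert g.integrate(tp.beta) == pytest.approx(17.0, rel=1e-6)
        assert np.all(tp.beta >= 0)

    def test_homogeneous_is_beta0_over_L(self):
        g = make_grid(4.0, 101)
        tp = make_transport_profile("homogeneous", 17.0, g)
        np.testing.assert_allclose(tp.beta, 17.0 / 4.0)

    def test_point_sink_concentrates_at_centre(self):
        g = make_grid(4.0, 101)
        tp = make_transport_profile("point_sink", 5.0, g)
        assert tp.beta[50] > 0
        assert np.count_nonzero(tp.beta) == 1

    def test_unknown_mode_rejected(self):
        g = make_grid(4.0, 101)
        with pytest.raises(ValidationError):
            make_transport_profile("gaussian", 17.0, g)


class TestToyModel:
    def test_uniform_balance_is_steady(self):
        # alpha * B_in = (beta0/L) * B_out kills both time derivatives
        g = make_grid(1.0, 33)
        p = ToyParams(D_out=0.1, D_in=1.0, alpha=2.0, beta0=4.0, L=1.0)
        beta = p.transport_profile(g)
        prof = ToyProfiles(g, B_out=np.full(33, 2.0 * 1.0 / 4.0), B_in=np.ones(33))
        d_out, d_in = toy_rhs(prof, p, beta)
        assert np.max(np.abs(d_out)) < 1e-12
        assert np.max(np.abs(d_in)) < 1e-12

    def test_empty_inner_compartment_is_pure_diffusion(self):
        g = make_grid(1.0, 33)
        p = ToyParams(D_out=0.5, D_in=1.0, alpha=2.0, beta0=0.0, L=1.0)
        beta = p.transport_profile(g)
        B_out = 1.0 + np.cos(np.pi * g.x)
        prof = ToyProfiles(g, B_out=B_out, B_in=np.zeros(33))
        d_out, d_in = toy_rhs(prof, p, beta)
        assert np.max(np.abs(d_in)) == 0
        assert g.integrate(d_out) == pytest.approx(0.0, abs=1e-13)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mass_conserved_for_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        g = make_grid(2.0, 33)
        p = ToyParams.from_dimensionless(a=10, b=3, d=0.5,
                                         mode="truncated_normal", sigma=0.1)
        beta = p.transport_profile(g)
        prof = ToyProfiles(g, rng.random(33) + 0.1, rng.random(33) + 0.1)
        d_out, d_in = toy_rhs(prof, p, beta)
        assert abs(g.integrate(d_out + d_in)) < 1e-12

    def test_homogeneous_steady_state_matches_algebra(self):
        # closed form: B_out / B_in = 1/b uniformly, outer fraction 1/(1+b)
        for b in (0.5, 10.0, 100.0):
            p = ToyParams.from_dimensionless(a=20.0, b=b, d=0.3)
            ss = toy_steady_state(p, n=101)
            np.testing.assert_allclose(ss.B_out / ss.B_in, 1.0 / b, rtol=1e-6)
            assert ss.outer_fraction == pytest.approx(1 / (1 + b), rel=1e-6)

    def test_localised_transport_leaves_more_outside(self):
        a, b, d = 50.0, 100.0, 0.2
        hom = toy_steady_state(ToyParams.from_dimensionless(a, b, d), n=101)
        loc = toy_steady_state(
            ToyParams.from_dimensionless(a, b, d, mode="point_sink"), n=101)
        assert loc.outer_fraction > hom.outer_fraction

    def test_no_transport_limit_empties_inner_compartment(self):
        p = ToyParams(D_out=0.5, D_in=1.0, alpha=2.0, beta0=0.0, L=1.0)
        ss = toy_steady_state(p, n=101)
        assert np.max(np.abs(ss.B_in)) < 1e-9
        np.testing.assert_allclose(ss.B_out, ss.B_out.mean(), rtol=1e-9)

    def test_grid_convergence(self):
        p = ToyParams.from_dimensionless(50, 100, 0.2, mode="point_sink")
        c = toy_steady_state(p, n=101)
        f = toy_steady_state(p, n=201)
        coarse = np.interp(f.grid.x, c.grid.x, c.B_out)
        err = np.max(np.abs(coarse - f.B_out)) / np.max(f.B_out)
        assert err < 0.01

    def test_narrow_truncated_normal_approaches_point_sink(self):
        a, b, d = 20.0, 10.0, 0.5
        sink = toy_steady_state(
            ToyParams.from_dimensionless(a, b, d, mode="point_sink"), n=401)
        narrow = toy_steady_state(
            ToyParams.from_dimensionless(a, b, d, mode="truncated_normal",
                                         sigma=0.0025), n=401)
        assert narrow.outer_fraction == pytest.approx(sink.outer_fraction,
                                                      rel=0.02)


class TestTolPalModel:
    def test_zero_state_has_zero_derivatives(self, table_params):
        g = make_grid(4.0, 33)
        beta = table_params.transport_profile(g, "truncated_normal")
        z = np.zeros(33)
        state = TolPalState(g, z.copy(), z.copy(), z.copy(), z.copy())
        d = tolpal_rhs(state, table_params, beta)
        for arr in (d.C, d.B, d.P_f, d.P_b):
            assert np.max(np.abs(arr)) == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_both_masses_conserved(self, table_params, seed):
        rng = np.random.default_rng(seed)
        g = make_grid(4.0, 33)
        beta = table_params.transport_profile(g, "truncated_normal")
        state = TolPalState(g, *(rng.random(33) * 10 for _ in range(4)))
        d = tolpal_rhs(state, table_params, beta)
        assert abs(g.integrate(d.C + d.B)) < 1e-10
        assert abs(g.integrate(d.C + d.P_f + d.P_b)) < 1e-10

    def test_rejects_negative_concentrations(self, table_params):
        g = make_grid(4.0, 33)
        beta = table_params.transport_profile(g, "homogeneous")
        state = TolPalState(g, np.full(33, -1.0), np.ones(33), np.ones(33),
                            np.ones(33))
        with pytest.raises(ValidationError):
            tolpal_rhs(state, table_params, beta)

    def test_homogeneous_steady_state_matches_algebraic_oracle(
            self, table_params, totals, nondividing_steady):
        # independent oracle: uniform 4-variable algebraic balance
        p, tt = table_params, totals
        beta_h = p.beta0 / 2.8

        def balance(v):
            C, B, Pf, Pb = v
            return [
                p.alpha * B * Pf - (beta_h + p.gamma) * C,
                p.k_on * Pf * (p.T - Pb) - p.k_off * Pb,
                C + B - tt.tolB_total,
                C + Pf + Pb - tt.pal_total,
            ]

        sol = optimize.root(balance, [1.0, 25.0, 40.0, 250.0])
        assert sol.success
        _, state = nondividing_steady
        for uniform, field in zip(sol.x,
                                  (state.C, state.B, state.P_f, state.P_b)):
            np.testing.assert_allclose(field, uniform, rtol=1e-5)

    def test_steady_state_masses_match_requested_totals(
            self, dividing_steady, totals):
        _, state = dividing_steady
        L = state.grid.L
        assert state.tolB_mass == pytest.approx(totals.tolB_total * L,
                                                rel=1e-6)
        assert state.pal_mass == pytest.approx(totals.pal_total * L, rel=1e-6)
        assert np.all(state.P_b <= state.grid.n * 0 + 320.0 + 1e-9)

    def test_dividing_pal_accumulates_at_septum(self, table_params, totals):
        grid = make_grid(4.0, 81)
        beta = table_params.transport_profile(grid, "truncated_normal")
        state = tolpal_steady_state(table_params, beta, totals)
        pal = state.total_pal_profile()
        assert np.argmax(pal) == grid.n // 2

    @pytest.mark.parametrize("D_c, D_b, peaked", [
        (0.0068, 0.0036, True),
        (0.0068, 0.0063, True),
        (0.0050, 0.0020, True),
        (0.0036, 0.0068, False),
        (0.0060, 0.0066, False),
        (0.0020, 0.0050, False),
    ])
    def test_tolB_septal_peak_requires_faster_complex(self, D_c, D_b, peaked,
                                                      totals):
        # total TolB peaks at the septum iff the complex outdiffuses free TolB
        params = TolPalParams(D_c=D_c, D_b=D_b)
        grid = make_grid(4.0, 81)
        beta = params.transport_profile(grid, "truncated_normal")
        state = tolpal_steady_state(params, beta, totals)
        prof = state.total_tolB_profile()
        centre, flank = prof[grid.n // 2], prof[grid.n // 8]
        assert (centre > flank) == peaked

    def test_compartment_fractions(self, dividing_steady, nondividing_steady):
        _, div = dividing_steady
        _, nondiv = nondividing_steady
        inner_n, outer_n = tolB_compartment_fractions(nondiv)
        inner_d, outer_d = tolB_compartment_fractions(div)
        assert inner_n + outer_n == pytest.approx(1.0)
        assert inner_n > 0.5          # non-dividing: TolB mostly inner
        assert outer_d > inner_d      # dividing: TolB mostly outer

    def test_fractions_undefined_without_tolB(self):
        g = make_grid(4.0, 33)
        z = np.zeros(33)
        state = TolPalState(g, z.copy(), z.copy(), np.ones(33), np.ones(33))
        with pytest.raises(ValidationError):
            tolB_compartment_fractions(state)


class TestLocalisedVsHomogeneous:
    def test_outer_mass_never_lower_for_localised_transport(self):
        # the central claim: localised transport is less efficient, so the
        # outer compartment holds at least as much protein, across decades
        # of the dimensionless parameters
        for a in np.logspace(0, 2, 5):
            for b in np.logspace(-1, 2, 5):
                for d in np.logspace(np.log10(0.02), np.log10(5), 5):
                    hom = toy_steady_state(
                        ToyParams.from_dimensionless(a, b, d), n=61)
                    loc = toy_steady_state(
                        ToyParams.from_dimensionless(a, b, d,
                                                     mode="point_sink"), n=61)
                    assert (loc.outer_fraction
                            >= hom.outer_fraction - 1e-9), (a, b, d)
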