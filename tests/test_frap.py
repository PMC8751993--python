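"""FRAP simulation: bleach functions, visible/total coupling, kymographs."""

import numpy as np
import pytest

from tolpal.errors import ValidationError
from tolpal.frap import (
    BleachFunction,
    FrapProtocol,
    bleach_function_from_profiles,
    frap_solution,
    simulate_frap,
    synthetic_bleach_function,
    toy_simulate_frap,
)
from tolpal.model import (
    ToyParams,
    make_grid,
    make_transport_profile,
    toy_steady_state,
)


class TestBleachFunctions:
    def test_ratio_of_profiles(self):
        bf = bleach_function_from_profiles(np.array([2.0, 2.0, 2.0]),
                                           np.array([2.0, 1.0, 2.0]))
        np.testing.assert_allclose(bf.factor, [1.0, 0.5, 1.0])

    def test_identical_profiles_mean_no_bleach(self):
        pre = np.linspace(1, 2, 20)
        bf = bleach_function_from_profiles(pre, pre.copy())
        np.testing.assert_allclose(bf.factor, 1.0)

    def test_zero_prebleach_rejected(self):
        with pytest.raises(ValidationError):
            bleach_function_from_profiles(np.array([1.0, 0.0]),
                                          np.array([1.0, 1.0]))

    def test_synthetic_box_shape(self):
        g = make_grid(4.0, 81)
        prot = FrapProtocol(bleach_width=1.5, bleach_depth=1.0)
        bf = synthetic_bleach_function(prot, g)
        inside = np.abs(g.x) <= 0.75
        assert np.all(bf.factor[inside] == 0.0)
        assert np.all(bf.factor[~inside] == 1.0)

    def test_zero_depth_is_identity(self):
        g = make_grid(4.0, 81)
        with pytest.raises(ValidationError):
            FrapProtocol(bleach_depth=0.0)  # depth 0 means no experiment
        bf = BleachFunction(g, np.ones(g.n))
        assert np.all(bf.factor == 1.0)

    def test_smooth_edges_are_monotone(self):
        g = make_grid(4.0, 161)
        prot = FrapProtocol(bleach_width=1.5, bleach_depth=0.9)
        bf = synthetic_bleach_function(prot, g, edge_sigma=0.1)
        left = bf.factor[(g.x > -1.3) & (g.x < -0.2)]
        assert np.all(np.diff(left) <= 1e-12)  # descending into the ROI

    def test_roi_outside_domain_rejected(self):
        g = make_grid(2.8, 81)
        prot = FrapProtocol(bleach_width=1.5, bleach_centre=1.0)
        with pytest.raises(ValidationError):
            synthetic_bleach_function(prot, g)


@pytest.fixture(scope="module")
def solution(table_params, totals, dividing_steady):
    beta, steady = dividing_steady
    protocol = FrapProtocol.pal_default()
    bleach = synthetic_bleach_function(protocol, beta.grid, edge_sigma=0.05)
    sol = frap_solution(table_params, beta, totals, protocol, bleach,
                        steady=steady)
    return beta, protocol, bleach, sol


class TestSimulateFrap:
    def test_visible_never_exceeds_total(self, solution):
        _, _, _, sol = solution
        tot_pal = sol["total"][0] + sol["total"][2] + sol["total"][3]
        vis_pal = sol["visible"].sum(axis=0)
        assert np.all(vis_pal <= tot_pal * (1 + 1e-9) + 1e-12)

    def test_visible_mass_conserved_after_bleach(self, solution):
        beta, _, _, sol = solution
        w = beta.grid.weights
        mass = sol["visible"].sum(axis=0) @ w
        assert np.ptp(mass) / mass.mean() < 1e-7

    def test_total_population_stays_at_steady_state(self, solution):
        beta, _, _, sol = solution
        pal0 = sol["total"][0, 0] + sol["total"][2, 0] + sol["total"][3, 0]
        palT = sol["total"][0, -1] + sol["total"][2, -1] + sol["total"][3, -1]
        np.testing.assert_allclose(palT, pal0, rtol=1e-6)

    def test_no_bleach_reproduces_steady_state(self, table_params, totals,
                                               dividing_steady):
        beta, steady = dividing_steady
        protocol = FrapProtocol.pal_default(n_postbleach=5)
        bleach = BleachFunction(beta.grid, np.ones(beta.grid.n))
        kymo = simulate_frap(table_params, beta, totals, protocol, bleach,
                             steady=steady)
        pre = steady.total_pal_profile()
        np.testing.assert_allclose(
            kymo.values, np.tile(pre, (kymo.n_frames, 1)), rtol=1e-6)

    def test_long_time_limit_is_scaled_steady_state(self, table_params,
                                                    totals, dividing_steady):
        beta, steady = dividing_steady
        grid = beta.grid
        protocol = FrapProtocol.pal_default(n_postbleach=8, dt=2000.0)
        bleach = synthetic_bleach_function(protocol, grid, edge_sigma=0.05)
        kymo = simulate_frap(table_params, beta, totals, protocol, bleach,
                             steady=steady)
        pre = steady.total_pal_profile()
        surviving = grid.integrate(kymo.values[1]) / grid.integrate(pre)
        np.testing.assert_allclose(kymo.values[-1], pre * surviving,
                                   rtol=5e-3)

    def test_pal_and_tolb_share_total_trajectories(self, table_params,
                                                   totals, dividing_steady):
        beta, steady = dividing_steady
        protb = FrapProtocol.tolb_default(n_postbleach=10)
        protp = FrapProtocol(n_prebleach=2, n_postbleach=10, dt=2.0,
                             labelled="pal")
        bleach = synthetic_bleach_function(protb, beta.grid, edge_sigma=0.05)
        solb = frap_solution(table_params, beta, totals, protb, bleach,
                             steady=steady)
        solp = frap_solution(table_params, beta, totals, protp, bleach,
                             steady=steady)
        np.testing.assert_allclose(solb["total"], solp["total"], rtol=1e-6)

    def test_positivity_for_nonnegative_initial_data(self, solution):
        _, _, _, sol = solution
        assert sol["visible"].min() >= -1e-12
        assert sol["total"].min() >= -1e-12


class TestToyFrap:
    def test_transport_speeds_recovery(self):
        # same steady state with and without exchange between compartments;
        # the exchanging system refills the bleached region sooner
        g = make_grid(1.0, 101)
        p_with = ToyParams.from_dimensionless(a=50, b=1, d=0.02)
        ss = toy_steady_state(p_with, n=101)
        protocol = FrapProtocol(n_prebleach=1, n_postbleach=80, dt=0.05,
                                bleach_width=0.375, bleach_depth=0.9)
        bleach = synthetic_bleach_function(protocol, g, edge_sigma=0.02)
        k_with = toy_simulate_frap(p_with, p_with.transport_profile(g),
                                   protocol, bleach, steady=ss)
        p_wo = ToyParams(D_out=0.02, D_in=1.0, alpha=1e-12, beta0=0.0, L=1.0)
        k_wo = toy_simulate_frap(p_wo, make_transport_profile(
            "homogeneous", 0.0, g), protocol, bleach, steady=ss)

        pre = ss.B_out + ss.B_in
        roi = np.abs(g.x) <= protocol.bleach_width / 2

        def frames_to_90pct(kymo):
            surviving = g.integrate(kymo.values[1]) / g.integrate(pre)
            target = 0.9 * surviving * pre[roi].sum()
            signal = kymo.values[1:, roi].sum(axis=1)
            hit = np.nonzero(signal >= target)[0]
            return hit[0] if hit.size else np.inf

        assert frames_to_90pct(k_with) < frames_to_90pct(k_wo)

    def test_flat_bleach_gives_flat_kymograph(self):
        g = make_grid(1.0, 33)
        p = ToyParams.from_dimensionless(a=5, b=2, d=0.5)
        ss = toy_steady_state(p, n=33)
        protocol = FrapProtocol(n_prebleach=1, n_postbleach=5, dt=0.05)
        k = toy_simulate_frap(p, p.transport_profile(g), protocol,
                              BleachFunction(g, np.ones(33)), steady=ss)
        pre = ss.B_out + ss.B_in
        np.testing.assert_allclose(k.values, np.tile(pre, (k.n_frames, 1)),
                                   rtol=1e-7)

    def test_unexchanging_system_recovers_fully_eventually(self):
        g = make_grid(1.0, 33)
        p_ss = ToyParams.from_dimensionless(a=50, b=1, d=0.02)
        ss = toy_steady_state(p_ss, n=33)
        p = ToyParams(D_out=0.02, D_in=1.0, alpha=1e-12, beta0=0.0, L=1.0)
        protocol = FrapProtocol(n_prebleach=1, n_postbleach=4, dt=30.0,
                                bleach_width=0.375, bleach_depth=0.9)
        bleach = synthetic_bleach_function(protocol, g, edge_sigma=0.02)
        k = toy_simulate_frap(p, make_transport_profile("homogeneous", 0.0, g),
                              protocol, bleach, steady=ss)
        pre = ss.B_out + ss.B_in
        surviving = g.integrate(k.values[1]) / g.integrate(pre)
        np.testing.assert_allclose(k.values[-1], pre * surviving, rtol=1e-3)


class TestKymographIO:
    def test_text_round_trip(self, pal_dividing_kymo, tmp_path):
        path = tmp_path / "kymo.tsv"
        pal_dividing_kymo.save(path)
        from tolpal.kymo import Kymograph
        back = Kymograph.load(path)
        assert back.n_prebleach == pal_dividing_kymo.n_prebleach
        assert back.labelled == pal_dividing_kymo.labelled
        np.testing.assert_allclose(back.times, pal_dividing_kymo.times)
        np.testing.assert_allclose(back.values, pal_dividing_kymo.values,
                                   rtol=1e-8)
        # writing the loaded kymograph again is bit-identical
        path2 = tmp_path / "kymo2.tsv"
        back.save(path2)
        assert path.read_text() == path2.read_text()

    def test_resampling_preserves_shape(self, pal_dividing_kymo):
        rel = np.linspace(0, 1, 40)
        r = pal_dividing_kymo.resampled(rel)
        assert r.values.shape == (pal_dividing_kymo.n_frames, 40)
        mid = pal_dividing_kymo.values[0, pal_dividing_kymo.width // 2]
        assert r.values[0, 20] == pytest.approx(mid, rel=0.01)
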