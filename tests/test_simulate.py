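"""Equilibrium solver, synthetic spectra, and end-to-end parameter recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nativekd import (
    SimulationConfig,
    adduct_weights,
    simulate_spectrum,
    simulate_titration,
    solve_equilibrium,
    solve_equilibrium_nonspecific,
)
from nativekd.pipeline import analyze_titration
from nativekd.simulate import EquilibriumState

P0 = 40.9e-6


class TestSolveEquilibrium:
    def test_no_binding_limit(self):
        # Kd >> P0, L0: PL approaches the weak-binding asymptote P0*L0/Kd -> 0
        state = solve_equilibrium(P0, 40e-6, Kd=1.0)
        assert state.PL < 1e-4 * P0
        assert state.PL == pytest.approx(P0 * 40e-6 / 1.0, rel=1e-3)

    def test_stoichiometric_limit(self):
        state = solve_equilibrium(P0, 5e-6, Kd=0.0)
        assert state.PL == pytest.approx(5e-6, rel=1e-12)
        assert state.L_free == pytest.approx(0.0, abs=1e-18)

    def test_matches_bisection_oracle(self):
        # independent root-bracketing solve of PL*Kd = (P0-PL)(L0-PL)
        P0_, L0, Kd = 40.9e-6, 5e-6, 2e-6
        lo, hi = 0.0, min(P0_, L0)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mid * Kd - (P0_ - mid) * (L0 - mid) < 0:
                lo = mid
            else:
                hi = mid
        oracle = 0.5 * (lo + hi)
        state = solve_equilibrium(P0_, L0, Kd)
        assert state.PL == pytest.approx(oracle, rel=1e-10)
        assert state.PL == pytest.approx(4.738e-6, rel=1e-3)

    def test_negative_inputs_rejected(self):
        for bad in [(-1e-6, 1e-6, 1e-6), (1e-6, -1e-6, 1e-6), (1e-6, 1e-6, -1e-6)]:
            with pytest.raises(ValueError):
                solve_equilibrium(*bad)

    @given(
        P0_=st.floats(1e-7, 1e-3),
        L0=st.floats(0.0, 1e-3),
        Kd=st.floats(1e-9, 1e-3),
    )
    def test_mass_balance_and_residual(self, P0_, L0, Kd):
        s = solve_equilibrium(P0_, L0, Kd)
        assert s.PL >= 0 and s.P_free >= 0 and s.L_free >= 0
        assert s.PL + s.P_free == pytest.approx(P0_, rel=1e-12)
        assert s.PL + s.L_free == pytest.approx(L0, rel=1e-12, abs=1e-18)
        assert abs(s.PL * Kd - s.P_free * s.L_free) < 1e-12 * P0_


class TestNonspecificEquilibrium:
    def test_mass_balances(self):
        s = solve_equilibrium_nonspecific(P0, 40e-6, 2.2e-6, 20e-6)
        assert s.P_free + s.PL + s.PL2 == pytest.approx(P0, rel=1e-10)
        assert s.L_free + s.PL + 2 * s.PL2 == pytest.approx(40e-6, rel=1e-10)

    def test_weak_second_site_reduces_to_1to1(self):
        one_site = solve_equilibrium(P0, 20e-6, 2.2e-6)
        two_site = solve_equilibrium_nonspecific(P0, 20e-6, 2.2e-6, 1.0)
        assert two_site.PL == pytest.approx(one_site.PL, rel=1e-4)
        # PL2 ~ PL * L_free / Kd2, vanishingly small for Kd2 = 1 M
        assert two_site.PL2 < 1e-5 * P0


class TestAdductWeights:
    def test_normalized_and_monotone(self):
        w = adduct_weights(0.45, 8)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(w) <= 0).all()

    def test_geometric_shape(self):
        w = adduct_weights(0.5, 2)
        np.testing.assert_allclose(w, np.array([1, 0.5, 0.25]) / 1.75, rtol=1e-12)

    def test_zero_decay_concentrates_at_zero_adducts(self):
        w = adduct_weights(0.0, 5)
        assert w[0] == 1.0 and w[1:].sum() == 0.0

    @pytest.mark.parametrize("decay", [-0.1, 1.0, 1.5])
    def test_out_of_range_decay_rejected(self, decay):
        with pytest.raises(ValueError):
            adduct_weights(decay, 5)

    @given(decay=st.floats(0.0, 0.99), n=st.integers(0, 12))
    def test_sum_is_one(self, decay, n):
        assert adduct_weights(decay, n).sum() == pytest.approx(1.0, abs=1e-12)


class TestSimulateSpectrum:
    def test_zero_concentrations_give_baseline_only(self):
        cfg = SimulationConfig(noise_cv=0.0, baseline=7.0, n_scans=1)
        empty = EquilibriumState(PL=0.0, P_free=0.0, L_free=0.0)
        (scan,) = simulate_spectrum(empty, cfg)
        np.testing.assert_array_equal(scan.intensity, 7.0)

    def test_same_seed_reproducible(self):
        cfg = SimulationConfig(noise_cv=0.2, n_scans=2, seed=11)
        state = solve_equilibrium(P0, 20e-6, 2.2e-6)
        a = simulate_spectrum(state, cfg)
        b = simulate_spectrum(state, cfg)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_single_peak_window_area_matches_analytic(self):
        """Integrated window abundance equals concentration x response x
        weights x Gaussian mass / grid step, within grid-resolution error."""
        from nativekd.ladder import IntegrationWindow
        from nativekd.spectra import AveragedSpectrum, integrate_window

        cfg = SimulationConfig(
            noise_cv=0.0, n_scans=1, adduct_decay=0.0, peak_sigma=0.8,
        )
        conc = 10e-6
        state = EquilibriumState(PL=0.0, P_free=conc, L_free=0.0)
        (scan,) = simulate_spectrum(state, cfg)
        mu = 1711.1698  # free-protein +8, no adducts
        w = IntegrationWindow("free", 8, mu - 8 * 0.8, mu + 8 * 0.8)
        spec = AveragedSpectrum(mz=scan.mz, intensity=scan.intensity, n_scans=1)
        got = integrate_window(spec, w).total_abundance
        expected = conc * cfg.counts_per_molar  # area / step, all weights 1
        assert got == pytest.approx(expected, rel=5e-3)

    def test_coarse_grid_warns(self):
        cfg = SimulationConfig(grid=(1500.0, 1950.0, 5.0), peak_sigma=1.5,
                               noise_cv=0.0, n_scans=1)
        state = solve_equilibrium(P0, 20e-6, 2.2e-6)
        with pytest.warns(UserWarning, match="under-sampled"):
            simulate_spectrum(state, cfg)


class TestEndToEndRecovery:
    def test_ideal_settings_recover_kd_everywhere(self):
        cfg = SimulationConfig(noise_cv=0.0, response_bias=1.0, n_scans=1, seed=1)
        res = analyze_titration(simulate_titration(cfg))
        grp = res.by_concentration()
        assert len(grp) == 4
        np.testing.assert_allclose(grp["Kd_mean"], cfg.Kd_true, rtol=1e-6)

    def test_response_bias_drives_apparent_kd_negative(self):
        cfg = SimulationConfig(
            noise_cv=0.0, response_bias=3.0, n_scans=1, seed=1,
            design=((P0, 5e-6, 1),),
        )
        res = analyze_titration(simulate_titration(cfg))
        est = res.estimates.iloc[0]
        assert est["Kd"] < 0 and not est["valid"]

    def test_noisy_replicates_give_plausible_rsd(self):
        # many replicates so the RSD estimate concentrates near noise_cv
        cfg = SimulationConfig(noise_cv=0.15, seed=3, n_scans=2,
                               design=((P0, 20e-6, 30),))
        res = analyze_titration(simulate_titration(cfg))
        stats = res.abundance_stats()
        assert ((stats["rsd_pct"] > 5) & (stats["rsd_pct"] < 20)).all()

    def test_noisy_recovery_within_band_at_high_ligand(self):
        cfg = SimulationConfig(noise_cv=0.15, seed=7, n_scans=2,
                               design=((P0, 40e-6, 3),))
        res = analyze_titration(simulate_titration(cfg))
        kd = res.average_kd("dC5", 40e-6)
        assert abs(kd - cfg.Kd_true) / cfg.Kd_true < 0.25

    def test_monotone_R_under_ideal_simulation(self):
        cfg = SimulationConfig(noise_cv=0.0, n_scans=1)
        res = analyze_titration(simulate_titration(cfg))
        grp = res.estimates.sort_values("L0")
        ratios = grp.groupby("L0")["R"].mean()
        assert ratios.is_monotonic_increasing

    def test_charge_leakage_lowers_measured_abundance_not_ratio(self):
        base = SimulationConfig(noise_cv=0.0, n_scans=1, design=((P0, 20e-6, 1),))
        leaky = SimulationConfig(
            noise_cv=0.0, n_scans=1, design=((P0, 20e-6, 1),),
            charge_weights={8: 0.6, 7: 0.25, 6: 0.15},
        )
        r_base = analyze_titration(simulate_titration(base)).estimates.iloc[0]
        r_leak = analyze_titration(simulate_titration(leaky)).estimates.iloc[0]
        assert r_leak["ab_free"] < 0.7 * r_base["ab_free"]
        assert r_leak["R"] == pytest.approx(r_base["R"], rel=1e-6)

    def test_nonspecific_binding_produces_hook_effect(self):
        # with a weak second site, bound-window abundance dips at the top
        # concentration relative to the one-site run
        one = SimulationConfig(noise_cv=0.0, n_scans=1)
        two = SimulationConfig(noise_cv=0.0, n_scans=1, nonspecific_kd=10e-6)
        ab_one = analyze_titration(simulate_titration(one)).estimates
        ab_two = analyze_titration(simulate_titration(two)).estimates
        top_one = ab_one[np.isclose(ab_one["L0"], 40e-6)]["ab_bound"].iloc[0]
        top_two = ab_two[np.isclose(ab_two["L0"], 40e-6)]["ab_bound"].iloc[0]
        assert top_two < 0.8 * top_one

    @given(rho=st.floats(0.2, 5.0), L0=st.sampled_from([5e-6, 10e-6, 20e-6, 40e-6]))
    def test_bias_sign_threshold_matches_bruteforce(self, rho, L0):
        """Apparent Ka is negative exactly when rho*R_true/(1+rho*R_true)*P0
        exceeds L0."""
        from nativekd import association_constant

        state = solve_equilibrium(P0, L0, 2.2e-6)
        r_obs = rho * state.PL / state.P_free
        predicted_negative = (r_obs / (1 + r_obs)) * P0 > L0
        ka = association_constant(r_obs, L0, P0)
        assert (ka < 0) == predicted_negative

    def test_manifest_records_ground_truth(self):
        cfg = SimulationConfig(noise_cv=0.0, n_scans=1, seed=5)
        sim = simulate_titration(cfg)
        m = sim.manifest
        assert len(m) == 6 + 4 * 3
        assert (m["Kd_true"] == cfg.Kd_true).all()
        assert (m["seed"] == 5).all()
        blank = m[m["L0"] == 0]
        assert (blank["PL_eq"] == 0).all()
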