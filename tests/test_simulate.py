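import math

import numpy as np
import pytest
from scipy.stats import kstest

from tweezefold.dumbbell import separation_for_force
from tweezefold.simulate import (
    quasistatic_pull,
    scenario_from_landscape,
    simulate_bead_noise,
    simulate_constant_separation,
    simulate_pull,
)


class TestScenarioCalibration:
    def test_ground_truth_reproduced_by_model(self, wt_scenario):
        d_eq = wt_scenario.equilibrium_separation()
        obs = wt_scenario.state_observables(d_eq)
        assert 0.5 * (obs["force_folded_pn"] + obs["force_unfolded_pn"]) \
            == pytest.approx(5.1, abs=1e-6)
        assert obs["extension_unfolded_nm"] - obs["extension_folded_nm"] \
            == pytest.approx(5.42, abs=1e-6)
        assert wt_scenario.delta_g(d_eq) == pytest.approx(0.0, abs=1e-6)
        assert wt_scenario.unfolding_energy_kbt == pytest.approx(5.2)

    def test_calibrated_structure_matches_published_picture(self, wt_scenario):
        # ~90 residues sequestered, hard core larger by ~3 nm in the folded state
        truth = wt_scenario.ground_truth
        assert 80 <= truth["contour_change_nm"] / 0.365 <= 100
        assert 2.0 <= truth["hard_core_change_nm"] <= 3.5

    def test_detailed_balance_of_rates(self, wt_scenario):
        for f in (4.0, 5.1, 6.3):
            d = separation_for_force(
                wt_scenario.traps, wt_scenario.folded, wt_scenario.handle, f
            )
            k_f, k_u = wt_scenario.rates(d)
            assert math.log(k_f / k_u) == pytest.approx(
                wt_scenario.delta_g(d), abs=1e-9
            )

    def test_zero_force_rates(self, wt_scenario):
        assert wt_scenario.unfolding_rate_zero_force_per_s == pytest.approx(0.7)
        assert wt_scenario.folding_rate_zero_force_per_s == pytest.approx(
            0.7 * math.exp(5.2)
        )


class TestConstantSeparation:
    def test_same_seed_identical_output(self, wt_scenario, wt_separations):
        a = simulate_constant_separation(wt_scenario, wt_separations[3], 5.0, seed=42)
        b = simulate_constant_separation(wt_scenario, wt_separations[3], 5.0, seed=42)
        assert np.array_equal(a.extension_nm, b.extension_nm)
        assert np.array_equal(a.force_pn, b.force_pn)

    def test_occupancy_matches_boltzmann(self, wt_scenario):
        # find a separation where ΔG ≈ +2 kBT: occupancy 1/(1+e²) ≈ 0.119
        from scipy.optimize import brentq

        d_eq = wt_scenario.equilibrium_separation()
        d2 = brentq(lambda d: wt_scenario.delta_g(d) - 2.0, d_eq - 40.0, d_eq)
        traj = simulate_constant_separation(wt_scenario, d2, 150.0, seed=3)
        occ = traj.metadata["true_states"].mean()
        p = 1.0 / (1.0 + math.exp(2.0))
        n_trans = np.sum(np.diff(traj.metadata["true_states"]) != 0)
        se = math.sqrt(p * (1 - p) / max(n_trans, 1)) * 2  # generous dwell-level SE
        assert abs(occ - p) < 3 * se + 0.02

    def test_detailed_balance_of_dwell_ratio(self, wt_scenario):
        d_eq = wt_scenario.equilibrium_separation()
        traj = simulate_constant_separation(wt_scenario, d_eq - 10.0, 200.0, seed=8)
        states = traj.metadata["true_states"]
        dg = wt_scenario.delta_g(d_eq - 10.0)
        # occupancy ratio estimates exp(-ΔG); SE from the transition count
        change = np.flatnonzero(np.diff(states)) + 1
        runs = np.diff(np.concatenate(([0], change, [states.size])))
        run_states = states[np.concatenate(([0], change))]
        t_u = runs[run_states == 1].sum()
        t_f = runs[run_states == 0].sum()
        n = min((run_states == 1).sum(), (run_states == 0).sum())
        log_ratio = math.log(t_u / t_f)
        se = math.sqrt(2.0 / n)
        assert abs(log_ratio + dg) < 3 * se

    def test_dwell_times_are_exponential(self, wt_scenario):
        d_eq = wt_scenario.equilibrium_separation()
        passed = 0
        for seed in range(10):
            traj = simulate_constant_separation(wt_scenario, d_eq, 60.0, seed=20 + seed)
            states = traj.metadata["true_states"]
            change = np.flatnonzero(np.diff(states)) + 1
            runs = np.diff(np.concatenate(([0], change, [states.size])))
            run_states = states[np.concatenate(([0], change))]
            ok = True
            for s in (0, 1):
                durs = runs[1:-1][run_states[1:-1] == s] / traj.sampling_rate_hz
                if durs.size < 20:
                    ok = False
                    continue
                p = kstest(durs, "expon", args=(0, durs.mean())).pvalue
                ok = ok and p > 0.01
            passed += ok
        assert passed >= 9

    def test_noise_sigma_applied(self, wt_scenario, wt_separations):
        traj = simulate_constant_separation(wt_scenario, wt_separations[0], 20.0, seed=5)
        states = traj.metadata["true_states"]
        resid = traj.extension_nm - np.where(
            states == 1,
            traj.metadata["extension_unfolded_nm"],
            traj.metadata["extension_folded_nm"],
        )
        assert resid.std() == pytest.approx(1.5, rel=0.05)


class TestPulls:
    def test_quasistatic_midpoint_matches_constant_separation(self, wt_scenario):
        d_eq = wt_scenario.equilibrium_separation()
        seps = np.linspace(d_eq - 15, d_eq + 15, 61)
        fec = quasistatic_pull(wt_scenario, seps)
        # occupancy crosses 0.5 at the same separation/force as ΔG = 0
        d_half = np.interp(0.5, fec["occupancy_unfolded"], fec["separation_nm"])
        obs = wt_scenario.state_observables(d_half)
        f_half = 0.5 * (obs["force_folded_pn"] + obs["force_unfolded_pn"])
        assert f_half == pytest.approx(5.1, abs=0.1)

    def test_flickering_in_transition_window(self, wt_scenario):
        d_eq = wt_scenario.equilibrium_separation()
        pull = simulate_pull(wt_scenario, d_eq - 25, d_eq + 25, seed=6, speed_nm_s=10.0)
        mid = (pull["separation_nm"] > d_eq - 8) & (pull["separation_nm"] < d_eq + 8)
        assert np.sum(np.diff(pull["state"][mid]) != 0) > 5
        forces_mid = pull["force_pn"][mid]
        assert 3.0 < forces_mid.mean() < 7.0

    def test_irreversible_rip_force_increases_with_speed(self, wt_scenario):
        def irreversible(grid, kf, ku):
            return np.zeros_like(kf), ku

        d_eq = wt_scenario.equilibrium_separation()
        rips = {}
        for speed in (5.0, 200.0):
            forces = []
            for seed in range(12):
                pull = simulate_pull(
                    wt_scenario, d_eq - 30, d_eq + 30, seed=seed,
                    speed_nm_s=speed, rate_override=irreversible,
                )
                idx = np.flatnonzero(pull["state"] == 1)
                if idx.size:
                    # state force just before the rip (noise-free channel mean)
                    forces.append(pull["separation_nm"][idx[0]])
            rips[speed] = np.mean(forces)
        assert rips[200.0] > rips[5.0]

    def test_pull_reproducible(self, wt_scenario):
        d_eq = wt_scenario.equilibrium_separation()
        a = simulate_pull(wt_scenario, d_eq - 10, d_eq + 10, seed=1)
        b = simulate_pull(wt_scenario, d_eq - 10, d_eq + 10, seed=1)
        assert np.array_equal(a["extension_nm"], b["extension_nm"])


class TestBeadNoise:
    def test_equipartition_variance(self):
        _, x = simulate_bead_noise(0.2, 9.42e-6, 100000, 100.0, seed=1)
        assert x.var() == pytest.approx(4.1143 / 0.2, rel=0.03)

    def test_determinism(self):
        _, a = simulate_bead_noise(0.2, 9.42e-6, 50000, 1.0, seed=7)
        _, b = simulate_bead_noise(0.2, 9.42e-6, 50000, 1.0, seed=7)
        assert np.array_equal(a, b)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_bead_noise(-0.2, 9.42e-6, 1000, 1.0, seed=0)


class TestVariantScenario:
    def test_variant_keeps_structure_changes_landscape(self, wt_scenario):
        var = scenario_from_landscape(3.0, 2.0, template=wt_scenario)
        assert var.unfolding_energy_kbt == pytest.approx(3.0)
        assert var.unfolding_rate_zero_force_per_s == 2.0
        assert var.folded.unfolded_contour_nm == wt_scenario.folded.unfolded_contour_nm
        # weaker complex: midpoint at lower force
        d_eq_var = var.equilibrium_separation((0.5, 12.0))
        f_var = var.state_observables(d_eq_var)["force_folded_pn"]
        assert f_var < 5.1
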