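import math

import numpy as np
import pytest

from tweezefold.dumbbell import separation_for_force
from tweezefold.landscape import (
    BoltzmannEnergyModel,
    KramersRateModel,
    LandscapeResult,
    MoleculeEnsemble,
    aggregate_molecules,
    lifetime,
    unfolding_work_estimate,
)


def binomial_occupancies(scenario, separations, n_obs, seed, dv=None):
    """Occupancy data straight from the Boltzmann model + binomial sampling."""
    rng = np.random.default_rng(seed)
    model = BoltzmannEnergyModel(
        scenario.folded, scenario.unfolded, scenario.traps, scenario.handle
    )
    dmech = model._delta_mech(separations)
    dv = scenario.unfolding_energy_kbt if dv is None else dv
    p = 1.0 / (1.0 + np.exp(dv + dmech))
    occ = rng.binomial(n_obs, p) / n_obs
    return np.clip(occ, 1e-4, 1 - 1e-4)


@pytest.fixture(scope="module")
def scan_separations(wt_scenario):
    return np.array(
        [
            separation_for_force(
                wt_scenario.traps, wt_scenario.folded, wt_scenario.handle, f
            )
            for f in np.linspace(4.0, 6.5, 8)
        ]
    )


class TestBoltzmannFit:
    def test_recovers_generating_energy(self, wt_scenario, scan_separations):
        occ = binomial_occupancies(wt_scenario, scan_separations, n_obs=1000, seed=1)
        model = BoltzmannEnergyModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps, wt_scenario.handle
        ).fit(scan_separations, occ, counts=np.full(8, 1000))
        assert model.unfolding_energy_kbt_ == pytest.approx(5.2, abs=0.3)

    def test_exact_midpoint_gives_mechanical_energy(self, wt_scenario):
        # occupancy exactly 0.5 at one separation pins ΔV to Δmech there
        d_eq = wt_scenario.equilibrium_separation()
        seps = [d_eq - 5.0, d_eq, d_eq + 5.0]
        model = BoltzmannEnergyModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps, wt_scenario.handle
        )
        occ = 1.0 / (1.0 + np.exp(5.2 + model._delta_mech(seps)))
        model.fit(seps, occ)
        assert model.unfolding_energy_kbt_ == pytest.approx(5.2, abs=1e-3)
        assert model.unfolding_energy_kbt_ == pytest.approx(
            -model._delta_mech([d_eq])[0], abs=1e-3
        )

    def test_sem_scales_with_observations(self, wt_scenario, scan_separations):
        occ = binomial_occupancies(wt_scenario, scan_separations, n_obs=400, seed=2)
        kw = dict(separations_nm=scan_separations, occupancies=occ)
        m1 = BoltzmannEnergyModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps, wt_scenario.handle
        ).fit(counts=np.full(8, 400), **kw)
        m2 = BoltzmannEnergyModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps, wt_scenario.handle
        ).fit(counts=np.full(8, 800), **kw)
        assert m2.unfolding_energy_kbt_ == pytest.approx(m1.unfolding_energy_kbt_)
        assert m2.unfolding_energy_sem_kbt_ == pytest.approx(
            m1.unfolding_energy_sem_kbt_ / math.sqrt(2), rel=1e-6
        )

    def test_saturated_occupancies_unidentifiable(self, wt_scenario, scan_separations):
        model = BoltzmannEnergyModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps, wt_scenario.handle
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            model.fit(scan_separations, np.full(8, 0.999))

    def test_fitted_energy_monotone_in_generating_energy(self, wt_scenario, scan_separations):
        fitted = []
        for dv in [1.5, 2.8, 4.1, 5.4, 6.7]:
            occ = binomial_occupancies(
                wt_scenario, scan_separations, n_obs=2000, seed=3, dv=dv
            )
            m = BoltzmannEnergyModel(
                wt_scenario.folded, wt_scenario.unfolded,
                wt_scenario.traps, wt_scenario.handle,
            ).fit(scan_separations, occ, counts=np.full(8, 2000))
            fitted.append(m.unfolding_energy_kbt_)
        assert np.all(np.diff(fitted) > 0)

    def test_joint_recovery_bias_and_coverage(self, wt_scenario, scan_separations):
        # small bias and calibrated confidence intervals across the
        # experimentally relevant energy range
        rng_dvs = np.linspace(1.5, 6.7, 20)
        errors, covered = [], 0
        for i, dv in enumerate(rng_dvs):
            occ = binomial_occupancies(
                wt_scenario, scan_separations, n_obs=500, seed=100 + i, dv=dv
            )
            m = BoltzmannEnergyModel(
                wt_scenario.folded, wt_scenario.unfolded,
                wt_scenario.traps, wt_scenario.handle,
            ).fit(scan_separations, occ, counts=np.full(8, 500))
            err = m.unfolding_energy_kbt_ - dv
            errors.append(err)
            covered += abs(err) < 1.96 * m.unfolding_energy_sem_kbt_
        assert abs(np.mean(errors)) < 0.3
        assert covered >= 18  # ≥90% of 20


class TestKramersFit:
    def test_recovers_zero_force_rates(self, wt_scenario, scan_separations):
        rng = np.random.default_rng(5)
        kf, ku = zip(*(wt_scenario.rates(d) for d in scan_separations))
        kf = np.array(kf) * rng.lognormal(0.0, 0.1, 8)
        ku = np.array(ku) * rng.lognormal(0.0, 0.1, 8)
        model = KramersRateModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps,
            wt_scenario.handle, unfolding_energy_kbt=5.2,
        ).fit(scan_separations, kf, ku)
        assert model.folding_rate_zero_force_per_s_ == pytest.approx(
            wt_scenario.folding_rate_zero_force_per_s, rel=0.3
        )
        assert model.unfolding_rate_zero_force_per_s_ == pytest.approx(0.7, rel=0.3)
        assert model.ts_fraction_ == pytest.approx(0.5, abs=0.1)

    def test_rates_cross_at_equilibrium_separation(self, wt_scenario, scan_separations):
        kf, ku = zip(*(wt_scenario.rates(d) for d in scan_separations))
        model = KramersRateModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps,
            wt_scenario.handle, unfolding_energy_kbt=5.2,
        ).fit(scan_separations, kf, ku)
        d_eq = wt_scenario.equilibrium_separation()
        pf, pu = model.predict([d_eq])
        assert pf[0] == pytest.approx(pu[0], rel=1e-6)

    def test_thermodynamic_closure_with_boltzmann_fit(self, wt_scenario, scan_separations):
        # ln(k_f/k_u) at zero force must agree with the fitted ΔV
        rng = np.random.default_rng(6)
        occ = binomial_occupancies(wt_scenario, scan_separations, n_obs=1000, seed=6)
        bolt = BoltzmannEnergyModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps, wt_scenario.handle
        ).fit(scan_separations, occ, counts=np.full(8, 1000))
        kf, ku = zip(*(wt_scenario.rates(d) for d in scan_separations))
        kf = np.array(kf) * rng.lognormal(0.0, 0.1, 8)
        ku = np.array(ku) * rng.lognormal(0.0, 0.1, 8)
        kram = KramersRateModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps,
            wt_scenario.handle, bolt.unfolding_energy_kbt_,
        ).fit(scan_separations, kf, ku)
        closure = math.log(
            kram.folding_rate_zero_force_per_s_ / kram.unfolding_rate_zero_force_per_s_
        )
        assert abs(closure - bolt.unfolding_energy_kbt_) < 0.5

    def test_pinned_transition_state(self, wt_scenario, scan_separations):
        kf, ku = zip(*(wt_scenario.rates(d) for d in scan_separations))
        model = KramersRateModel(
            wt_scenario.folded, wt_scenario.unfolded, wt_scenario.traps,
            wt_scenario.handle, 5.2, ts_fraction=0.5,
        ).fit(scan_separations, kf, ku)
        assert model.ts_fraction_ == 0.5
        assert model.unfolding_rate_zero_force_per_s_ == pytest.approx(0.7, rel=1e-3)


class TestScalars:
    @pytest.mark.parametrize("ku,expected", [(0.7, 1.4286), (1.0, 1.0), (0.2, 5.0)])
    def test_lifetime(self, ku, expected):
        assert lifetime(ku) == pytest.approx(expected, abs=0.01)

    def test_work_estimate_from_published_midpoint(self):
        w = unfolding_work_estimate(5.1, 5.42)
        assert w == pytest.approx(27.64 / 4.1143, abs=0.05)  # ≈ 6.7 kBT
        assert w == pytest.approx(6.7, abs=0.05)

    def test_zero_extension_change(self):
        assert unfolding_work_estimate(5.1, 0.0) == 0.0

    def test_kcal_per_mol_conversion(self):
        r = LandscapeResult(unfolding_energy_kbt=5.2)
        assert r.unfolding_energy_kcal_mol == pytest.approx(3.1, abs=0.05)


class TestAggregation:
    def test_three_molecule_mean_and_sem(self):
        mols = [LandscapeResult(unfolding_energy_kbt=v) for v in (5.0, 5.2, 5.4)]
        agg = aggregate_molecules(MoleculeEnsemble(mols))
        assert agg.unfolding_energy_kbt == pytest.approx(5.2)
        assert agg.unfolding_energy_sem_kbt == pytest.approx(0.1155, abs=1e-3)

    def test_single_molecule_has_no_sem(self):
        agg = aggregate_molecules(MoleculeEnsemble([LandscapeResult(5.2)]))
        assert agg.unfolding_energy_kbt == 5.2
        assert agg.unfolding_energy_sem_kbt is None

    def test_permutation_invariance(self):
        vals = [4.8, 5.1, 5.9, 6.2]
        a = aggregate_molecules(
            MoleculeEnsemble([LandscapeResult(v) for v in vals])
        )
        b = aggregate_molecules(
            MoleculeEnsemble([LandscapeResult(v) for v in reversed(vals)])
        )
        assert a.unfolding_energy_kbt == pytest.approx(b.unfolding_energy_kbt, rel=1e-12)
        assert a.unfolding_energy_sem_kbt == pytest.approx(b.unfolding_energy_sem_kbt, rel=1e-12)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            aggregate_molecules(MoleculeEnsemble([]))
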