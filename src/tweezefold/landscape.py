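"""Zero-force energies and rates from force-dependent occupancies and rates.

Occupancy fit.  With the folded-state zero-force energy as reference, the
unfolded-state occupancy at trap separation D follows the Boltzmann
distribution on the dumbbell free energy,

    P_u(D) = 1 / (1 + exp(ΔG(D))),     ΔG(D) = ΔV + Δmech(D),

where Δmech(D) collects the trap, DNA and polypeptide terms of the two states
(fixed by the structural model) and ΔV, the zero-force unfolding energy, is
the single fitted parameter.  The fit is a binomial maximum-likelihood fit
weighted by the observed transition counts.

Rate fit.  A Kramers-type barrier on the contour-length coordinate: the
transition state is a construct state with contour length between the folded
and unfolded values, and

    k_unfold(D) = exp(a) · exp(-(mech‡(D) - mech_f(D))),
    k_fold(D)   = exp(a + ΔV) · exp(-(mech‡(D) - mech_u(D))),

so detailed balance k_f/k_u = exp(ΔG) holds identically and exp(a) is the
zero-force unfolding rate.  The attempt prefactor and the transition-state
zero-force energy enter only through exp(a) and are not separately
identifiable, as expected for a minimal one-dimensional barrier model; the
fitted parameters are a and the transition-state contour fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .constants import KCAL_PER_MOL_PER_KBT, thermal_energy
from .dumbbell import ConstructState, TrapPair, system_free_energy
from .hmm import TransitionStats
from .polymer import PolymerSegment

__all__ = [
    "LandscapeResult",
    "MoleculeEnsemble",
    "BoltzmannEnergyModel",
    "KramersRateModel",
    "boltzmann_fit",
    "kramers_fit",
    "fit_landscape",
    "lifetime",
    "unfolding_work_estimate",
    "aggregate_molecules",
]


@dataclass
class LandscapeResult:
    """Zero-force landscape of a two-state transition for one molecule."""

    unfolding_energy_kbt: float
    unfolding_energy_sem_kbt: float | None = None
    folding_rate_per_s: float | None = None
    unfolding_rate_per_s: float | None = None
    equilibrium_force_pn: float | None = None
    extension_change_nm: float | None = None
    transition_state_contour_nm: float | None = None
    transition_state_energy_kbt: float | None = None
    molecule_id: str | None = None

    @property
    def lifetime_s(self) -> float | None:
        return None if not self.unfolding_rate_per_s else 1.0 / self.unfolding_rate_per_s

    @property
    def unfolding_energy_kcal_mol(self) -> float:
        return self.unfolding_energy_kbt * KCAL_PER_MOL_PER_KBT


@dataclass
class MoleculeEnsemble:
    """Per-molecule results plus which fits are complete enough to aggregate."""

    molecules: list[LandscapeResult] = field(default_factory=list)

    def complete(self) -> list[LandscapeResult]:
        return [
            m for m in self.molecules
            if np.isfinite(m.unfolding_energy_kbt)
        ]


def _mech_energy(traps, state, handle, d):
    return system_free_energy(traps, replace(state, energy_kbt=0.0), handle, d)


class BoltzmannEnergyModel(BaseEstimator):
    """One-parameter fit of the zero-force unfolding energy ΔV.

    The mechanical parameters (contour lengths, hard cores, traps, handle) of
    the two construct states are fixed from the structural model; only ΔV is
    fitted, by binomial maximum likelihood over the observed unfolded-state
    occupancies.  ``counts`` (transition counts per record) act as effective
    numbers of independent dwell observations.
    """

    def __init__(
        self,
        folded: ConstructState,
        unfolded: ConstructState,
        traps: TrapPair,
        handle: PolymerSegment,
        max_energy_kbt: float = 30.0,
    ) -> None:
        self.folded = folded
        self.unfolded = unfolded
        self.traps = traps
        self.handle = handle
        self.max_energy_kbt = max_energy_kbt

    def _delta_mech(self, separations) -> np.ndarray:
        return np.array(
            [
                _mech_energy(self.traps, self.unfolded, self.handle, d)
                - _mech_energy(self.traps, self.folded, self.handle, d)
                for d in separations
            ]
        )

    def fit(self, separations_nm, occupancies, counts=None) -> "BoltzmannEnergyModel":
        d = np.asarray(separations_nm, dtype=float)
        p_obs = np.asarray(occupancies, dtype=float)
        if d.size < 3:
            raise ValueError("need at least three separations to fit")
        if np.all(p_obs < 0.02) or np.all(p_obs > 0.98):
            raise ValueError(
                "occupancies are all near 0 or 1; the unfolding energy is "
                "unidentifiable — scan separations through the transition"
            )
        n = np.ones_like(p_obs) if counts is None else np.asarray(counts, dtype=float)
        dmech = self._delta_mech(d)

        def nll(dv: float) -> float:
            dg = dv + dmech
            # log P_u = -log(1+e^dg); log P_f = dg - log(1+e^dg)
            log1p = np.logaddexp(0.0, dg)
            return -float(np.sum(n * (p_obs * (-log1p) + (1 - p_obs) * (dg - log1p))))

        res = minimize_scalar(
            nll, bounds=(-self.max_energy_kbt, self.max_energy_kbt), method="bounded",
            options={"xatol": 1e-10},
        )
        dv = float(res.x)
        # SEM from the observed Fisher information
        h = 1e-4
        curv = (nll(dv + h) - 2 * nll(dv) + nll(dv - h)) / h**2
        self.unfolding_energy_kbt_ = dv
        self.unfolding_energy_sem_kbt_ = (
            1.0 / math.sqrt(curv) if curv > 0 else float("nan")
        )
        self.delta_mech_ = dmech
        self.separations_nm_ = d
        self.nll_ = float(res.fun)
        return self

    def predict(self, separations_nm) -> np.ndarray:
        """Predicted unfolded-state occupancy at the given separations."""
        dg = self.unfolding_energy_kbt_ + self._delta_mech(
            np.atleast_1d(np.asarray(separations_nm, dtype=float))
        )
        return 1.0 / (1.0 + np.exp(dg))


class KramersRateModel(BaseEstimator):
    """Two-parameter Kramers fit of force-dependent folding/unfolding rates.

    Fits the log zero-force unfolding rate ``a`` and the transition-state
    contour fraction, minimizing squared log-rate residuals, with the
    unfolding energy ΔV supplied (from the occupancy fit).  Zero-force rates
    follow by evaluating the model in the zero-tension limit:
    k_u(0) = exp(a), k_f(0) = exp(a + ΔV).  If requested, the contour
    fraction can be pinned (``ts_fraction``), leaving a one-parameter fit.
    """

    def __init__(
        self,
        folded: ConstructState,
        unfolded: ConstructState,
        traps: TrapPair,
        handle: PolymerSegment,
        unfolding_energy_kbt: float,
        ts_fraction: float | None = None,
        attempt_rate_per_s: float = 1.0e4,
    ) -> None:
        self.folded = folded
        self.unfolded = unfolded
        self.traps = traps
        self.handle = handle
        self.unfolding_energy_kbt = unfolding_energy_kbt
        self.ts_fraction = ts_fraction
        self.attempt_rate_per_s = attempt_rate_per_s

    def _ts_state(self, fraction: float) -> ConstructState:
        return ConstructState(
            "transition_state",
            self.folded.unfolded_contour_nm
            + fraction
            * (self.unfolded.unfolded_contour_nm - self.folded.unfolded_contour_nm),
            self.folded.hard_core_nm
            + fraction * (self.unfolded.hard_core_nm - self.folded.hard_core_nm),
            0.0,
        )

    def _mech_profiles(self, separations, fraction: float):
        ts = self._ts_state(fraction)
        m_ts = np.array(
            [_mech_energy(self.traps, ts, self.handle, d) for d in separations]
        )
        return m_ts

    def _log_rates(self, separations, a: float, fraction: float):
        m_ts = self._mech_profiles(separations, fraction)
        m_f = np.array(
            [_mech_energy(self.traps, self.folded, self.handle, d) for d in separations]
        )
        m_u = np.array(
            [_mech_energy(self.traps, self.unfolded, self.handle, d) for d in separations]
        )
        log_ku = a - (m_ts - m_f)
        log_kf = a + self.unfolding_energy_kbt - (m_ts - m_u)
        return log_kf, log_ku

    def fit(self, separations_nm, folding_rates, unfolding_rates) -> "KramersRateModel":
        d = np.asarray(separations_nm, dtype=float)
        if d.size < 3:
            raise ValueError("need rates at three or more separations")
        lkf_obs = np.log(np.asarray(folding_rates, dtype=float))
        lku_obs = np.log(np.asarray(unfolding_rates, dtype=float))
        m_f = np.array(
            [_mech_energy(self.traps, self.folded, self.handle, di) for di in d]
        )
        m_u = np.array(
            [_mech_energy(self.traps, self.unfolded, self.handle, di) for di in d]
        )

        # For a given transition-state position the log prefactor enters
        # linearly, so it is profiled out in closed form.
        def profiled(frac: float) -> tuple[float, float]:
            m_ts = self._mech_profiles(d, frac)
            centered = np.concatenate(
                [
                    lku_obs + (m_ts - m_f),
                    lkf_obs - self.unfolding_energy_kbt + (m_ts - m_u),
                ]
            )
            a = float(centered.mean())
            return float(np.sum((centered - a) ** 2)), a

        if self.ts_fraction is not None:
            frac = self.ts_fraction
            fun, a = profiled(frac)
        else:
            res = minimize_scalar(
                lambda fr: profiled(fr)[0],
                bounds=(0.05, 0.95), method="bounded", options={"xatol": 1e-6},
            )
            frac = float(res.x)
            fun, a = profiled(frac)

        self.log_unfolding_rate_zero_force_ = a
        self.unfolding_rate_zero_force_per_s_ = math.exp(a)
        self.folding_rate_zero_force_per_s_ = math.exp(a + self.unfolding_energy_kbt)
        self.ts_fraction_ = frac
        self.transition_state_contour_nm_ = self._ts_state(frac).unfolded_contour_nm
        # Barrier height relative to the folded state for the configured
        # attempt rate (prefactor and barrier are degenerate; see module doc).
        self.transition_state_energy_kbt_ = math.log(self.attempt_rate_per_s) - a
        self.residual_ = fun
        return self

    def predict(self, separations_nm) -> tuple[np.ndarray, np.ndarray]:
        """(k_fold, k_unfold) arrays at the given separations."""
        lkf, lku = self._log_rates(
            np.atleast_1d(np.asarray(separations_nm, dtype=float)),
            self.log_unfolding_rate_zero_force_,
            self.ts_fraction_,
        )
        return np.exp(lkf), np.exp(lku)


def boltzmann_fit(
    stats_by_separation: list[TransitionStats],
    folded: ConstructState,
    unfolded: ConstructState,
    traps: TrapPair,
    handle: PolymerSegment,
) -> BoltzmannEnergyModel:
    """Fit ΔV from per-record occupancies (records carry their separations)."""
    usable = [s for s in stats_by_separation if not s.no_transition]
    seps = [s.trap_separation_nm for s in usable]
    occ = [s.occupancy_unfolded for s in usable]
    counts = [max(s.n_transitions, 1) for s in usable]
    return BoltzmannEnergyModel(folded, unfolded, traps, handle).fit(seps, occ, counts)


def kramers_fit(
    stats_by_separation: list[TransitionStats],
    folded: ConstructState,
    unfolded: ConstructState,
    traps: TrapPair,
    handle: PolymerSegment,
    unfolding_energy_kbt: float,
    ts_fraction: float | None = None,
) -> KramersRateModel:
    """Fit zero-force rates and the transition state from per-record rates."""
    usable = [
        s
        for s in stats_by_separation
        if s.folding_rate_per_s and s.unfolding_rate_per_s and not s.no_transition
    ]
    model = KramersRateModel(
        folded, unfolded, traps, handle, unfolding_energy_kbt, ts_fraction
    )
    return model.fit(
        [s.trap_separation_nm for s in usable],
        [s.folding_rate_per_s for s in usable],
        [s.unfolding_rate_per_s for s in usable],
    )


def fit_landscape(
    stats_by_separation: list[TransitionStats],
    folded: ConstructState,
    unfolded: ConstructState,
    traps: TrapPair,
    handle: PolymerSegment,
    molecule_id: str | None = None,
) -> LandscapeResult:
    """Occupancy fit + rate fit + midpoint interpolation for one molecule."""
    from .hmm import equilibrium_force

    bolt = boltzmann_fit(stats_by_separation, folded, unfolded, traps, handle)
    kram = kramers_fit(
        stats_by_separation, folded, unfolded, traps, handle,
        bolt.unfolding_energy_kbt_,
    )
    try:
        f_eq = equilibrium_force(stats_by_separation)
    except ValueError:
        f_eq = None
    usable = [s for s in stats_by_separation if not s.no_transition]
    occ = np.array([s.occupancy_unfolded for s in usable])
    dx = np.array([s.extension_change_nm for s in usable])
    # extension change at the midpoint: weight records by proximity to 0.5
    w = np.exp(-(((occ - 0.5) / 0.15) ** 2))
    dx_mid = float(np.sum(w * dx) / np.sum(w)) if np.sum(w) > 0 else float(np.mean(dx))
    return LandscapeResult(
        unfolding_energy_kbt=bolt.unfolding_energy_kbt_,
        unfolding_energy_sem_kbt=bolt.unfolding_energy_sem_kbt_,
        folding_rate_per_s=kram.folding_rate_zero_force_per_s_,
        unfolding_rate_per_s=kram.unfolding_rate_zero_force_per_s_,
        equilibrium_force_pn=f_eq,
        extension_change_nm=dx_mid,
        transition_state_contour_nm=kram.transition_state_contour_nm_,
        transition_state_energy_kbt=kram.transition_state_energy_kbt_,
        molecule_id=molecule_id,
    )


def lifetime(result_or_rate) -> float:
    """Zero-force lifetime 1/k_u in seconds."""
    k_u = (
        result_or_rate.unfolding_rate_per_s
        if isinstance(result_or_rate, LandscapeResult)
        else float(result_or_rate)
    )
    if not k_u or k_u <= 0:
        raise ValueError("unfolding rate must be positive")
    return 1.0 / k_u


def unfolding_work_estimate(
    equilibrium_force_pn: float,
    extension_change_nm: float,
    temperature_k: float = 298.0,
) -> float:
    """Reversible work F_eq × Δx at the midpoint, in kBT.

    This mechanical work exceeds the zero-force unfolding energy by the
    entropic stretching energy of the released polypeptide; report it
    alongside ΔV, never in its place.
    """
    if equilibrium_force_pn < 0 or extension_change_nm < 0:
        raise ValueError("force and extension change must be non-negative")
    return equilibrium_force_pn * extension_change_nm / thermal_energy(temperature_k)


def aggregate_molecules(ensemble: MoleculeEnsemble) -> LandscapeResult:
    """Unweighted mean and SEM across molecules for each scalar."""
    mols = ensemble.complete()
    if not mols:
        raise ValueError("no complete per-molecule fits to aggregate")

    def mean_sem(values):
        vals = np.array([v for v in values if v is not None], dtype=float)
        if vals.size == 0:
            return None, None
        sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
        return float(vals.mean()), sem

    dv, dv_sem = mean_sem(m.unfolding_energy_kbt for m in mols)
    kf, _ = mean_sem(m.folding_rate_per_s for m in mols)
    ku, _ = mean_sem(m.unfolding_rate_per_s for m in mols)
    feq, _ = mean_sem(m.equilibrium_force_pn for m in mols)
    dx, _ = mean_sem(m.extension_change_nm for m in mols)
    return LandscapeResult(
        unfolding_energy_kbt=dv,
        unfolding_energy_sem_kbt=dv_sem,
        folding_rate_per_s=kf,
        unfolding_rate_per_s=ku,
        equilibrium_force_pn=feq,
        extension_change_nm=dx,
        molecule_id=f"aggregate(n={len(mols)})",
    )
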