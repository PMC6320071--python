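"""Synthetic instrument data with known ground truth.

Generates the two record types a dual-trap dumbbell experiment produces:

* constant-trap-separation extension/force trajectories of a two-state folding
  transition (continuous-time Markov jumps + WLC state extensions + Gaussian
  or Ornstein-Uhlenbeck measurement noise), and
* constant-speed pulling/relaxation force-extension curves with rips.

State-switching rates derive from the dumbbell free energy through a minimal
Kramers barrier: a transition state parameterized on the contour-length
coordinate, so that detailed balance k_f/k_u = exp(ΔG(D)) holds exactly at
every separation and recovery tests downstream are exact inversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, thermal_energy
from .dumbbell import (
    ConstructState,
    TrapPair,
    default_dna_handle,
    equilibrium_separation,
    predicted_extension_change,
    separation_for_force,
    solve_equilibrium,
    system_free_energy,
)
from .polymer import PolymerSegment
from .trajectory import Trajectory

__all__ = [
    "SimulationScenario",
    "wt_template_scenario",
    "scenario_from_landscape",
    "simulate_constant_separation",
    "simulate_pull",
    "quasistatic_pull",
    "simulate_bead_noise",
    "generate_benchmark_suite",
]


def _mechanical_energy(
    traps: TrapPair, state: ConstructState, handle: PolymerSegment, d: float
) -> float:
    """Dumbbell free energy of ``state`` at D with the zero-force term removed."""
    bare = replace(state, energy_kbt=0.0)
    return system_free_energy(traps, bare, handle, d)


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to simulate a two-state dumbbell record.

    The transition state sits at ``ts_fraction`` of the way from the folded to
    the unfolded state along the contour-length coordinate (hard core
    interpolated likewise); ``unfolding_rate_zero_force_per_s`` anchors the
    absolute rate scale.  Noise is white Gaussian of ``noise_sigma_nm`` unless
    ``noise_corner_hz`` is set, in which case an Ornstein-Uhlenbeck process
    with the same stationary standard deviation is used.
    """

    folded: ConstructState
    unfolded: ConstructState
    traps: TrapPair
    handle: PolymerSegment
    unfolding_rate_zero_force_per_s: float
    ts_fraction: float = 0.5
    noise_sigma_nm: float = 1.5
    sampling_rate_hz: float = 1000.0
    pulling_speed_nm_s: float = 10.0
    noise_corner_hz: float | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unfolding_rate_zero_force_per_s <= 0:
            raise ValueError("zero-force unfolding rate must be positive")
        if not 0.0 < self.ts_fraction < 1.0:
            raise ValueError("ts_fraction must lie strictly between 0 and 1")
        if self.noise_sigma_nm < 0 or self.sampling_rate_hz <= 0:
            raise ValueError("invalid noise/sampling parameters")

    @property
    def unfolding_energy_kbt(self) -> float:
        """ΔV = V_unfolded - V_folded."""
        return self.unfolded.energy_kbt - self.folded.energy_kbt

    @property
    def folding_rate_zero_force_per_s(self) -> float:
        """k_f(0) = k_u(0) · exp(ΔV) by detailed balance."""
        return self.unfolding_rate_zero_force_per_s * math.exp(self.unfolding_energy_kbt)

    @property
    def transition_state(self) -> ConstructState:
        f = self.ts_fraction
        return ConstructState(
            "transition_state",
            self.folded.unfolded_contour_nm
            + f * (self.unfolded.unfolded_contour_nm - self.folded.unfolded_contour_nm),
            self.folded.hard_core_nm
            + f * (self.unfolded.hard_core_nm - self.folded.hard_core_nm),
            0.0,
        )

    def delta_g(self, separation_nm: float) -> float:
        """ΔG(D) = G_unfolded - G_folded in kBT."""
        return (
            system_free_energy(self.traps, self.unfolded, self.handle, separation_nm)
            - system_free_energy(self.traps, self.folded, self.handle, separation_nm)
        )

    def occupancy_unfolded(self, separation_nm: float) -> float:
        """Boltzmann occupancy of the unfolded state at separation D."""
        return 1.0 / (1.0 + math.exp(self.delta_g(separation_nm)))

    def rates(self, separation_nm: float) -> tuple[float, float]:
        """(k_fold, k_unfold) in 1/s at separation D; detailed-balanced."""
        m_ts = _mechanical_energy(self.traps, self.transition_state, self.handle, separation_nm)
        m_f = _mechanical_energy(self.traps, self.folded, self.handle, separation_nm)
        m_u = _mechanical_energy(self.traps, self.unfolded, self.handle, separation_nm)
        k_u = self.unfolding_rate_zero_force_per_s * math.exp(-(m_ts - m_f))
        k_f = self.folding_rate_zero_force_per_s * math.exp(-(m_ts - m_u))
        return k_f, k_u

    def equilibrium_separation(self, force_bracket_pn=(1.0, 15.0)) -> float:
        return equilibrium_separation(
            self.traps, self.folded, self.unfolded, self.handle, force_bracket_pn
        )

    def state_observables(self, separation_nm: float) -> dict:
        """Equilibrium extension and force of each state at D."""
        eq_f = solve_equilibrium(self.traps, self.folded, self.handle, separation_nm)
        eq_u = solve_equilibrium(self.traps, self.unfolded, self.handle, separation_nm)
        return {
            "extension_folded_nm": eq_f.extension_nm,
            "extension_unfolded_nm": eq_u.extension_nm,
            "force_folded_pn": eq_f.force_pn,
            "force_unfolded_pn": eq_u.force_pn,
        }


_WT_CALIBRATION_CACHE: dict = {}


def wt_template_scenario(
    unfolding_energy_kbt: float = 5.2,
    unfolding_rate_zero_force_per_s: float = 0.7,
    midpoint_force_pn: float = 5.1,
    extension_change_nm: float = 5.42,
    trap_stiffness_pn_nm: float = 0.2,
    folded_contour_nm: float = 35.0,
    folded_hard_core_nm: float = 5.0,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    **kwargs,
) -> SimulationScenario:
    """Scenario reproducing the wild-type template-complex transition.

    With the unfolding energy fixed, the contour-length change ΔL and
    hard-core change ΔH of the transition are calibrated so that the model's
    two states are equally populated at exactly ``midpoint_force_pn`` with a
    measured extension change of exactly ``extension_change_nm`` there.  The
    calibrated ΔL comes out near 34 nm (about 93 residues) and the folded hard
    core larger by about 2.8 nm, consistent with the structural picture of a
    compact folded complex sequestering ~90 residues.
    """
    from scipy.optimize import least_squares

    key = (
        unfolding_energy_kbt, midpoint_force_pn, extension_change_nm,
        trap_stiffness_pn_nm, folded_contour_nm, folded_hard_core_nm, temperature_k,
    )
    traps = TrapPair(trap_stiffness_pn_nm, trap_stiffness_pn_nm)
    handle = default_dna_handle(temperature_k)

    def make_states(d_contour: float, d_core: float):
        folded = ConstructState(
            "template_complex", folded_contour_nm, folded_hard_core_nm, 0.0
        )
        unfolded = ConstructState(
            "partially_closed_syntaxin",
            folded_contour_nm + d_contour,
            folded_hard_core_nm + d_core,
            unfolding_energy_kbt,
        )
        return folded, unfolded

    if key not in _WT_CALIBRATION_CACHE:

        def residuals(params):
            folded, unfolded = make_states(*params)
            d_eq = equilibrium_separation(traps, folded, unfolded, handle, (1.0, 12.0))
            dx, _ = predicted_extension_change(traps, folded, unfolded, handle, d_eq)
            f_f = solve_equilibrium(traps, folded, handle, d_eq).force_pn
            f_u = solve_equilibrium(traps, unfolded, handle, d_eq).force_pn
            return [dx - extension_change_nm, 0.5 * (f_f + f_u) - midpoint_force_pn]

        fit = least_squares(
            residuals,
            x0=[extension_change_nm * 6.0, -2.5],
            bounds=([1.0, -folded_hard_core_nm + 0.1], [60.0, 10.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if not fit.success or np.max(np.abs(fit.fun)) > 1e-6:
            raise RuntimeError("WT scenario calibration failed to converge")
        _WT_CALIBRATION_CACHE[key] = tuple(fit.x)

    d_contour, d_core = _WT_CALIBRATION_CACHE[key]
    folded, unfolded = make_states(d_contour, d_core)
    scenario = SimulationScenario(
        folded=folded,
        unfolded=unfolded,
        traps=traps,
        handle=handle,
        unfolding_rate_zero_force_per_s=unfolding_rate_zero_force_per_s,
        ground_truth={
            "unfolding_energy_kbt": unfolding_energy_kbt,
            "midpoint_force_pn": midpoint_force_pn,
            "extension_change_nm": extension_change_nm,
            "unfolding_rate_zero_force_per_s": unfolding_rate_zero_force_per_s,
            "folding_rate_zero_force_per_s": unfolding_rate_zero_force_per_s
            * math.exp(unfolding_energy_kbt),
            "contour_change_nm": d_contour,
            "hard_core_change_nm": -d_core,
        },
        **kwargs,
    )
    return scenario


def scenario_from_landscape(
    unfolding_energy_kbt: float,
    unfolding_rate_zero_force_per_s: float,
    template: SimulationScenario | None = None,
    **kwargs,
) -> SimulationScenario:
    """Scenario for a variant landscape on the WT structural model.

    Keeps the calibrated contour and hard-core changes of ``template`` (the WT
    scenario by default) and swaps in a different unfolding energy and
    zero-force unfolding rate, emulating a mutant whose mechanics are WT-like
    but whose stability and kinetics differ.
    """
    if template is None:
        template = wt_template_scenario()
    unfolded = replace(template.unfolded, energy_kbt=unfolding_energy_kbt)
    truth = dict(template.ground_truth)
    truth.update(
        unfolding_energy_kbt=unfolding_energy_kbt,
        unfolding_rate_zero_force_per_s=unfolding_rate_zero_force_per_s,
        folding_rate_zero_force_per_s=unfolding_rate_zero_force_per_s
        * math.exp(unfolding_energy_kbt),
    )
    truth.pop("midpoint_force_pn", None)
    truth.pop("extension_change_nm", None)
    return replace(
        template,
        unfolded=unfolded,
        unfolding_rate_zero_force_per_s=unfolding_rate_zero_force_per_s,
        ground_truth=truth,
        **kwargs,
    )


def _gillespie_states(
    k_fold: float,
    k_unfold: float,
    duration_s: float,
    rng: np.random.Generator,
    initial_state: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact continuous-time jump times for a two-state chain.

    Returns (jump_times, state_sequence); state_sequence[i] holds between
    jump_times[i-1] and jump_times[i] (state_sequence[0] from t=0).
    """
    out_rates = (k_unfold, k_fold)  # rate out of folded(0) / unfolded(1)
    t = 0.0
    state = initial_state
    times = [0.0]
    states = [state]
    while True:
        t += rng.exponential(1.0 / out_rates[state])
        if t >= duration_s:
            break
        state = 1 - state
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=np.int8)


def _ou_noise(
    n: int, dt: float, sigma: float, corner_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact-discretization OU noise with stationary sd ``sigma``."""
    theta = 2.0 * np.pi * corner_hz
    alpha = math.exp(-theta * dt)
    innov = sigma * math.sqrt(1.0 - alpha**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    shocks = rng.normal(0.0, innov, size=n - 1)
    for i in range(1, n):
        x[i] = alpha * x[i - 1] + shocks[i - 1]
    return x


def simulate_constant_separation(
    scenario: SimulationScenario,
    separation_nm: float,
    duration_s: float,
    seed: int,
    initial_state: int | None = None,
) -> Trajectory:
    """Simulate an extension/force record at constant trap separation.

    Exact continuous-time Markov jumps (no per-sample discretization bias),
    WLC equilibrium extensions per state, and measurement noise on top.  The
    force channel carries the anti-correlated bead response
    F = F_state - k_traps · δX.  Ground truth (state rates, extensions,
    occupancy) is echoed into ``metadata``.
    """
    rng = np.random.default_rng(seed)
    k_f, k_u = scenario.rates(separation_nm)
    obs = scenario.state_observables(separation_nm)
    p_u = scenario.occupancy_unfolded(separation_nm)
    if initial_state is None:
        initial_state = int(rng.random() < p_u)

    jump_times, state_seq = _gillespie_states(k_f, k_u, duration_s, rng, initial_state)
    n = int(round(duration_s * scenario.sampling_rate_hz))
    t = np.arange(n) / scenario.sampling_rate_hz
    idx = np.searchsorted(jump_times, t, side="right") - 1
    states = state_seq[idx]

    x_state = np.where(
        states == 1, obs["extension_unfolded_nm"], obs["extension_folded_nm"]
    )
    f_state = np.where(states == 1, obs["force_unfolded_pn"], obs["force_folded_pn"])
    if scenario.noise_corner_hz is None:
        noise = rng.normal(0.0, scenario.noise_sigma_nm, size=n)
    else:
        noise = _ou_noise(
            n, 1.0 / scenario.sampling_rate_hz, scenario.noise_sigma_nm,
            scenario.noise_corner_hz, rng,
        )
    extension = x_state + noise
    force = f_state - scenario.traps.effective_stiffness * noise

    metadata = {
        "seed": int(seed),
        "separation_nm": float(separation_nm),
        "true_folding_rate_per_s": k_f,
        "true_unfolding_rate_per_s": k_u,
        "true_occupancy_unfolded": p_u,
        "true_extension_change_nm": obs["extension_unfolded_nm"]
        - obs["extension_folded_nm"],
        "noise_sigma_nm": scenario.noise_sigma_nm,
        **obs,
        "true_states": states,
    }
    return Trajectory(t, extension, force, separation_nm, metadata)


def quasistatic_pull(scenario: SimulationScenario, separations_nm) -> dict:
    """Equilibrium (infinitely slow ramp) force-extension curve.

    Returns Boltzmann-averaged extension/force and the unfolded-state
    occupancy at each separation — the limit of a vanishing pulling speed.
    """
    seps = np.atleast_1d(np.asarray(separations_nm, dtype=float))
    occ = np.array([scenario.occupancy_unfolded(d) for d in seps])
    ext = np.empty_like(occ)
    force = np.empty_like(occ)
    for i, d in enumerate(seps):
        obs = scenario.state_observables(d)
        ext[i] = (1 - occ[i]) * obs["extension_folded_nm"] + occ[i] * obs[
            "extension_unfolded_nm"
        ]
        force[i] = (1 - occ[i]) * obs["force_folded_pn"] + occ[i] * obs[
            "force_unfolded_pn"
        ]
    return {
        "separation_nm": seps,
        "occupancy_unfolded": occ,
        "extension_nm": ext,
        "force_pn": force,
    }


def simulate_pull(
    scenario: SimulationScenario,
    start_separation_nm: float,
    end_separation_nm: float,
    seed: int,
    speed_nm_s: float | None = None,
    initial_state: int = 0,
    rate_override=None,
    grid_step_nm: float = 0.5,
) -> dict:
    """Constant-speed trap ramp producing a force-extension curve with rips.

    The trap separation moves linearly at ``speed_nm_s`` (scenario default
    10 nm/s); state switching is sampled per time step from the local rates
    (interpolated off a precomputed separation grid).  ``rate_override`` may
    map a callable (k_fold, k_unfold) = f(D) over the model rates, e.g. to
    make unfolding irreversible.  Returns arrays time/separation/extension/
    force/state.
    """
    if speed_nm_s is None:
        speed_nm_s = scenario.pulling_speed_nm_s
    if speed_nm_s <= 0:
        raise ValueError("pulling speed must be positive")
    rng = np.random.default_rng(seed)
    fs = scenario.sampling_rate_hz
    dt = 1.0 / fs
    sign = 1.0 if end_separation_nm >= start_separation_nm else -1.0
    n = int(abs(end_separation_nm - start_separation_nm) / speed_nm_s * fs)
    if n < 2:
        raise ValueError("ramp too short for the sampling rate")
    t = np.arange(n) * dt
    d_of_t = start_separation_nm + sign * speed_nm_s * t

    lo, hi = min(start_separation_nm, end_separation_nm), max(
        start_separation_nm, end_separation_nm
    )
    grid = np.arange(lo, hi + grid_step_nm, grid_step_nm)
    xf = np.empty_like(grid); xu = np.empty_like(grid)
    ff = np.empty_like(grid); fu = np.empty_like(grid)
    kf = np.empty_like(grid); ku = np.empty_like(grid)
    for i, d in enumerate(grid):
        obs = scenario.state_observables(d)
        xf[i], xu[i] = obs["extension_folded_nm"], obs["extension_unfolded_nm"]
        ff[i], fu[i] = obs["force_folded_pn"], obs["force_unfolded_pn"]
        kf[i], ku[i] = scenario.rates(d)
    if rate_override is not None:
        kf, ku = rate_override(grid, kf, ku)

    k_fold_t = np.interp(d_of_t, grid, kf)
    k_unfold_t = np.interp(d_of_t, grid, ku)
    states = np.empty(n, dtype=np.int8)
    state = initial_state
    u = rng.random(n)
    for i in range(n):
        rate = k_unfold_t[i] if state == 0 else k_fold_t[i]
        if u[i] < -math.expm1(-rate * dt):
            state = 1 - state
        states[i] = state

    x_state = np.where(states == 1, np.interp(d_of_t, grid, xu), np.interp(d_of_t, grid, xf))
    f_state = np.where(states == 1, np.interp(d_of_t, grid, fu), np.interp(d_of_t, grid, ff))
    noise = rng.normal(0.0, scenario.noise_sigma_nm, size=n)
    return {
        "time_s": t,
        "separation_nm": d_of_t,
        "extension_nm": x_state + noise,
        "force_pn": f_state - scenario.traps.effective_stiffness * noise,
        "state": states,
    }


def simulate_bead_noise(
    stiffness_pn_nm: float,
    drag_pn_s_nm: float,
    sampling_rate_hz: float,
    duration_s: float,
    seed: int,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> tuple[np.ndarray, np.ndarray]:
    """Brownian motion of a trapped bead: exact-discretization OU process.

    Stationary variance kBT/k (equipartition) and corner frequency
    f_c = k / (2π γ); the standard fixture for power-spectrum trap
    calibration.  Returns (time_s, position_nm).
    """
    if min(stiffness_pn_nm, drag_pn_s_nm, sampling_rate_hz, duration_s) <= 0:
        raise ValueError("all parameters must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    dt = 1.0 / sampling_rate_hz
    sigma = math.sqrt(thermal_energy(temperature_k) / stiffness_pn_nm)
    corner_hz = stiffness_pn_nm / (2.0 * np.pi * drag_pn_s_nm)
    x = _ou_noise(n, dt, sigma, corner_hz, rng)
    return np.arange(n) * dt, x


def generate_benchmark_suite(
    table,
    out_dir,
    seed: int,
    duration_s: float = 20.0,
    max_rows: int | None = None,
) -> dict:
    """Build a fixture library from a variant parameter table.

    One scenario per table row with a numeric unfolding energy and unfolding
    rate (rows outside the two-state regime are skipped with a warning); each
    scenario gets a constant-separation record at its own midpoint plus a
    ground-truth manifest.  The manifest is written deterministically (sorted
    keys), so a fixed seed gives byte-identical output.
    """
    import json
    import warnings
    from pathlib import Path

    import pandas as pd

    from .io import write_trajectory

    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    template = wt_template_scenario()
    manifest: dict = {"seed": int(seed), "records": {}}
    n_done = 0
    for _, row in table.iterrows():
        if max_rows is not None and n_done >= max_rows:
            break
        label = str(row.get("mutation", f"row{_}"))
        try:
            dv = float(row["unfolding_energy_kbt"])
            ku = float(row["unfolding_rate_per_s"])
        except (TypeError, ValueError, KeyError):
            warnings.warn(f"skipping row {label!r}: not a two-state data set")
            continue
        if not (np.isfinite(dv) and np.isfinite(ku)) or ku <= 0:
            warnings.warn(f"skipping row {label!r}: not a two-state data set")
            continue
        scenario = scenario_from_landscape(dv, ku, template=template)
        d_eq = scenario.equilibrium_separation((0.5, 15.0))
        record_seed = (seed * 100003 + n_done * 101) % (2**31 - 1)
        traj = simulate_constant_separation(scenario, d_eq, duration_s, record_seed)
        fname = f"{label.replace('/', '_').replace(' ', '')}.tsv"
        traj.metadata.pop("true_states", None)
        write_trajectory(traj, out_dir / fname)
        manifest["records"][label] = {
            "file": fname,
            "seed": record_seed,
            "separation_nm": d_eq,
            "unfolding_energy_kbt": dv,
            "unfolding_rate_zero_force_per_s": ku,
            "folding_rate_zero_force_per_s": ku * math.exp(dv),
            "true_folding_rate_per_s": traj.metadata["true_folding_rate_per_s"],
            "true_unfolding_rate_per_s": traj.metadata["true_unfolding_rate_per_s"],
            "true_occupancy_unfolded": traj.metadata["true_occupancy_unfolded"],
            "true_extension_change_nm": traj.metadata["true_extension_change_nm"],
        }
        n_done += 1
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
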