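"""Two-state hidden-Markov idealization of constant-separation trajectories.

A record of a reversible folding transition dwells alternately in a folded and
an unfolded extension level.  The idealizer fits a two-state HMM with Gaussian
emissions (bead noise in harmonic traps) by EM, decodes the most probable
state path, and run-length encodes it into dwells.  Dwell statistics yield the
unfolding probability (time-weighted occupancy), folding/unfolding rates
(reciprocal mean interior dwell time), the extension change (emission-mean
separation), and per-state mean forces, which feed the landscape fits.

Trap stiffness calibration from the Brownian motion of a trapped bead is also
here: the one-sided power spectrum of an overdamped bead in a harmonic trap is
a Lorentzian with corner frequency f_c = k / (2 pi gamma), so k = 2 pi gamma f_c.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import curve_fit
from scipy.signal import welch
from sklearn.base import BaseEstimator

from .trajectory import Trajectory

__all__ = [
    "Dwell",
    "IdealizedTrace",
    "TransitionStats",
    "TwoStateHMM",
    "LorentzianTrapCalibrator",
    "CalibrationError",
    "idealize_two_state",
    "dwell_statistics",
    "rates_from_transition_matrix",
    "equilibrium_force",
    "calibrate_trap_stiffness",
]


@dataclass(frozen=True)
class Dwell:
    """A maximal run of consecutive samples in one state."""

    state: int            # 0 folded, 1 unfolded
    start_index: int
    n_samples: int
    duration_s: float
    censored: bool        # first/last dwell: true duration unknown


@dataclass
class IdealizedTrace:
    """Decoded state path of a trajectory plus the fitted emission model."""

    states: np.ndarray
    dwells: list[Dwell]
    emission_means_nm: np.ndarray    # [folded, unfolded]; unfolded is higher
    emission_sds_nm: np.ndarray
    transition_counts: np.ndarray    # 2x2 decoded-path transition counts
    dt_s: float
    no_transition: bool = False
    log_likelihood: float = float("nan")

    @property
    def extension_change_nm(self) -> float:
        return float(self.emission_means_nm[1] - self.emission_means_nm[0])

    @property
    def n_transitions(self) -> int:
        return len(self.dwells) - 1


@dataclass
class TransitionStats:
    """Per-record summary consumed by the landscape fits."""

    occupancy_unfolded: float
    folding_rate_per_s: float | None
    unfolding_rate_per_s: float | None
    extension_change_nm: float
    mean_force_folded_pn: float | None
    mean_force_unfolded_pn: float | None
    mean_force_pn: float | None      # mean of the two per-state averages
    trap_separation_nm: float | None
    n_transitions: int
    n_dwells_folded: int
    n_dwells_unfolded: int
    duration_s: float
    no_transition: bool = False


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, start, length) runs tiling the state sequence exactly."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


class TwoStateHMM(BaseEstimator):
    """Two-state Gaussian-emission HMM idealizer (sklearn-style estimator).

    EM is initialized deterministically from a median split of the extension
    signal, so fitting is reproducible from the data alone.  After fitting,
    states are ordered by emission mean and the higher-extension state is
    labelled unfolded (state 1): unfolding lengthens the tether.

    Parameters
    ----------
    n_iter, tol : EM iteration cap and log-likelihood convergence tolerance.
    min_covar : floor on emission variances (nm^2), guards noiseless input.
    filter_window : optional moving-average width in samples applied before
        fitting (published traces are often displayed filtered; none by default).
    degenerate_sd_ratio : flag "no transition" when the emission means are
        closer than this multiple of the mean emission sd.
    max_occupancy : flag "no transition" when one state holds more than this
        fraction of samples.
    """

    def __init__(
        self,
        n_iter: int = 100,
        tol: float = 1e-4,
        min_covar: float = 1e-6,
        filter_window: int | None = None,
        degenerate_sd_ratio: float = 0.5,
        max_occupancy: float = 0.995,
    ) -> None:
        self.n_iter = n_iter
        self.tol = tol
        self.min_covar = min_covar
        self.filter_window = filter_window
        self.degenerate_sd_ratio = degenerate_sd_ratio
        self.max_occupancy = max_occupancy

    # -- helpers ----------------------------------------------------------
    def _prepare(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        if x.size < 2:
            raise ValueError("need at least two samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        if self.filter_window is not None and self.filter_window > 1:
            kernel = np.ones(self.filter_window) / self.filter_window
            x = np.convolve(x, kernel, mode="same")
        return x

    def fit(self, X, y=None) -> "TwoStateHMM":
        x = self._prepare(X)
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        if hi.size == 0 or lo.size == 0:
            # skewed occupancy: split at the half-maximum instead
            mid = 0.5 * (x.min() + x.max())
            lo, hi = x[x <= mid], x[x > mid]
        if hi.size == 0 or lo.size == 0:  # constant signal
            lo, hi = x, x
        means = np.array([[lo.mean()], [hi.mean()]])
        variances = np.array(
            [[max(lo.var(), self.min_covar)], [max(hi.var(), self.min_covar)]]
        )
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            init_params="",
            params="stmc",
            n_iter=self.n_iter,
            tol=self.tol,
            min_covar=self.min_covar,
        )
        model.startprob_ = np.array([0.5, 0.5])
        model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
        model.means_ = means
        model.covars_ = variances
        hmm_logger = logging.getLogger("hmmlearn.base")
        previous_level = hmm_logger.level
        hmm_logger.setLevel(logging.ERROR)  # EM deltas of ~1e-7 are noise, not failures
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x.reshape(-1, 1))
        finally:
            hmm_logger.setLevel(previous_level)
        order = np.argsort(model.means_.ravel())
        self.means_ = model.means_.ravel()[order]
        self.sds_ = np.sqrt(np.array(model.covars_).reshape(2)[order])
        self.transmat_ = model.transmat_[np.ix_(order, order)]
        self.startprob_ = model.startprob_[order]
        self._order = order
        self._model = model
        self.log_likelihood_ = float(model.score(x.reshape(-1, 1)))
        states = self.predict(x)
        occ = states.mean()
        separation = self.means_[1] - self.means_[0]
        self.no_transition_ = bool(
            separation < self.degenerate_sd_ratio * self.sds_.mean()
            or occ > self.max_occupancy
            or occ < 1.0 - self.max_occupancy
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Most probable (Viterbi) state path, 0 = folded, 1 = unfolded."""
        x = self._prepare(X)
        raw = self._model.predict(x.reshape(-1, 1))
        remap = np.empty(2, dtype=np.int8)
        remap[self._order] = np.arange(2, dtype=np.int8)
        return remap[raw]


def idealize_two_state(
    traj: Trajectory,
    seed: int = 0,
    filter_window: int | None = None,
    **kwargs,
) -> IdealizedTrace:
    """Idealize a constant-separation record into a two-state path.

    Maximum-likelihood two-state segmentation (Gaussian emissions, first-order
    Markov transitions, EM-fitted, Viterbi-decoded).  The fit is deterministic
    given the data (deterministic EM initialization); ``seed`` is accepted for
    interface uniformity with the stochastic stages.  Degenerate records —
    one state holding >99.5% of samples, or emission means closer than half an
    emission sd — are returned flagged ``no_transition`` rather than raising.
    """
    del seed  # deterministic: EM initialized from a median split
    x = np.asarray(traj.extension_nm, dtype=float)
    # sign-flip equivariance: analyze -x if the signal is inverted is the
    # caller's choice; the HMM itself is symmetric, only the state labels
    # follow the higher-extension-is-unfolded rule.
    est = TwoStateHMM(filter_window=filter_window, **kwargs).fit(x)
    states = est.predict(x)
    runs = _runs(states)
    dt = traj.dt_s
    dwells = [
        Dwell(s, start, n, n * dt, censored=(i == 0 or i == len(runs) - 1))
        for i, (s, start, n) in enumerate(runs)
    ]
    counts = np.zeros((2, 2))
    a, b = states[:-1], states[1:]
    for i in range(2):
        for j in range(2):
            counts[i, j] = np.sum((a == i) & (b == j))
    return IdealizedTrace(
        states=states,
        dwells=dwells,
        emission_means_nm=est.means_.copy(),
        emission_sds_nm=est.sds_.copy(),
        transition_counts=counts,
        dt_s=dt,
        no_transition=est.no_transition_,
        log_likelihood=est.log_likelihood_,
    )


def dwell_statistics(ideal: IdealizedTrace, traj: Trajectory) -> TransitionStats:
    """Summarize an idealized record into occupancy, rates, Δx and forces.

    The rate out of a state is the reciprocal mean dwell time in that state;
    censored boundary dwells are excluded from the means.  The unfolding
    probability is the time-weighted occupancy of the unfolded state.  With no
    interior dwells in a state the corresponding rate is reported as ``None``
    (occupancy is still reported).
    """
    states = ideal.states
    occ = float(states.mean())
    interior = [d for d in ideal.dwells if not d.censored]
    rates: dict[int, float | None] = {}
    n_dwells = {0: 0, 1: 0}
    for s in (0, 1):
        durs = [d.duration_s for d in interior if d.state == s]
        n_dwells[s] = len(durs)
        rates[s] = 1.0 / float(np.mean(durs)) if durs else None

    mff = mfu = mf = None
    if traj.force_pn is not None:
        folded_mask = states == 0
        if folded_mask.any() and (~folded_mask).any():
            mff = float(traj.force_pn[folded_mask].mean())
            mfu = float(traj.force_pn[~folded_mask].mean())
            mf = 0.5 * (mff + mfu)
        else:
            mf = float(traj.force_pn.mean())
            if folded_mask.all():
                mff = mf
            else:
                mfu = mf

    return TransitionStats(
        occupancy_unfolded=occ,
        folding_rate_per_s=rates[1],     # rate out of the unfolded state
        unfolding_rate_per_s=rates[0],   # rate out of the folded state
        extension_change_nm=ideal.extension_change_nm,
        mean_force_folded_pn=mff,
        mean_force_unfolded_pn=mfu,
        mean_force_pn=mf,
        trap_separation_nm=traj.trap_separation_nm,
        n_transitions=ideal.n_transitions,
        n_dwells_folded=n_dwells[0],
        n_dwells_unfolded=n_dwells[1],
        duration_s=traj.duration_s,
        no_transition=ideal.no_transition,
    )


def rates_from_transition_matrix(
    ideal: IdealizedTrace, sampling_rate_hz: float
) -> tuple[float, float]:
    """(k_fold, k_unfold) from decoded-path transition frequencies.

    k = a_ij × sampling rate, the small-Δt limit of the discrete chain; a
    cross-check for the dwell-mean estimator (they agree on well-sampled
    records).
    """
    counts = ideal.transition_counts
    row = counts.sum(axis=1)
    if row[0] == 0 or row[1] == 0:
        raise ValueError("both states must be visited to estimate rates")
    a_fu = counts[0, 1] / row[0]
    a_uf = counts[1, 0] / row[1]
    return a_uf * sampling_rate_hz, a_fu * sampling_rate_hz


def equilibrium_force(stats_by_separation: list[TransitionStats]) -> float:
    """Midpoint (equilibrium) force from a force scan of records.

    Interpolates unfolded-state occupancy to 0.5 across records and returns
    the mean of the two per-state average forces there — the operational
    definition of the equilibrium force.  Records must bracket occupancy 0.5.
    """
    usable = [
        s
        for s in stats_by_separation
        if s.mean_force_folded_pn is not None and s.mean_force_unfolded_pn is not None
    ]
    if len(usable) < 2:
        raise ValueError("need at least two records with per-state forces")
    usable.sort(key=lambda s: s.occupancy_unfolded)
    occ = np.array([s.occupancy_unfolded for s in usable])
    if occ[0] > 0.5 or occ[-1] < 0.5:
        raise ValueError(
            "occupancies do not bracket 0.5; scan a wider force range"
        )
    f_folded = np.interp(0.5, occ, [s.mean_force_folded_pn for s in usable])
    f_unfolded = np.interp(0.5, occ, [s.mean_force_unfolded_pn for s in usable])
    return float(0.5 * (f_folded + f_unfolded))


class CalibrationError(RuntimeError):
    """Trap calibration failure; carries the diagnostic PSD."""

    def __init__(self, message: str, frequencies=None, psd=None) -> None:
        super().__init__(message)
        self.frequencies = frequencies
        self.psd = psd


class LorentzianTrapCalibrator(BaseEstimator):
    """Trap stiffness from the Lorentzian power spectrum of bead motion.

    Fits the one-sided PSD of a stationary bead position record to
    S(f) = A / (f_c^2 + f^2) in log space; the trap stiffness follows from
    the corner frequency as k = 2 pi gamma f_c, with gamma the bead drag
    coefficient (pN s/nm).
    """

    def __init__(
        self,
        sampling_rate_hz: float,
        drag_pn_s_nm: float,
        nperseg: int | None = None,
        min_rolloff: float = 3.0,
        fit_fmax_hz: float | None = None,
    ) -> None:
        self.sampling_rate_hz = sampling_rate_hz
        self.drag_pn_s_nm = drag_pn_s_nm
        self.nperseg = nperseg
        self.min_rolloff = min_rolloff
        self.fit_fmax_hz = fit_fmax_hz

    def fit(self, X, y=None) -> "LorentzianTrapCalibrator":
        x = np.asarray(X, dtype=float).reshape(-1)
        nperseg = self.nperseg or min(4096, x.size // 8)
        f, pxx = welch(x, fs=self.sampling_rate_hz, nperseg=nperseg)
        f, pxx = f[1:], pxx[1:]  # drop DC
        # keep the fit away from the Nyquist band, where sampling aliases
        # the f^-2 tail and distorts the Lorentzian shape
        fmax = self.fit_fmax_hz or self.sampling_rate_hz / 8.0
        keep = f <= fmax
        if keep.sum() >= 16:
            f, pxx = f[keep], pxx[keep]

        # A flat spectrum has no corner to fit.
        n = f.size
        low, high = pxx[: n // 8].mean(), pxx[-n // 8 :].mean()
        if not high > 0 or low / high < self.min_rolloff:
            raise CalibrationError(
                "power spectrum shows no Lorentzian roll-off "
                f"(low/high power ratio {low / max(high, 1e-300):.2f})",
                frequencies=f, psd=pxx,
            )

        def log_lorentzian(freq, log_a, log_fc):
            return log_a - np.log(np.exp(2 * log_fc) + freq**2)

        # p0: corner near the half-power frequency
        half = np.argmin(np.abs(pxx - low / 2.0))
        p0 = [np.log(low * f[half] ** 2), np.log(f[half])]
        try:
            popt, _ = curve_fit(log_lorentzian, f, np.log(pxx), p0=p0, maxfev=10000)
        except RuntimeError as err:
            raise CalibrationError(
                f"Lorentzian fit did not converge: {err}", frequencies=f, psd=pxx
            ) from err
        fc = float(np.exp(popt[1]))
        if not 0 < fc < 0.9 * self.sampling_rate_hz / 2:
            raise CalibrationError(
                f"corner frequency {fc:.3g} Hz outside the resolvable band",
                frequencies=f, psd=pxx,
            )
        self.corner_frequency_hz_ = fc
        self.stiffness_pn_nm_ = 2.0 * np.pi * self.drag_pn_s_nm * fc
        self.psd_frequencies_ = f
        self.psd_ = pxx
        return self


def calibrate_trap_stiffness(
    position_nm,
    sampling_rate_hz: float,
    drag_pn_s_nm: float,
) -> float:
    """Trap stiffness (pN/nm) from a stationary bead position record."""
    cal = LorentzianTrapCalibrator(sampling_rate_hz, drag_pn_s_nm).fit(position_nm)
    return cal.stiffness_pn_nm_
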