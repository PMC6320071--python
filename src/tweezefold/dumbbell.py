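"""Mechanics and thermodynamics of the dual-trap dumbbell.

A protein construct is held between two optically trapped beads through a DNA
handle; traps, handle, unfolded polypeptide, and the folded "hard core" are in
mechanical series.  With the relative trap separation convention (bead
diameters excluded), the tether extension and tension obey

    X = D - x1 - x2,          F = (F1 + F2) / 2,

where x_i = F / k_i are the bead displacements.  The series force balance

    D = F/k1 + F/k2 + x_DNA(F) + x_p(F) + H

has a unique root because every component extension is monotone in F.  The
total free energy of the dumbbell at that equilibrium is

    G = F^2 / (2 k_traps) + E_DNA + E_p + V,        k_traps = k1 k2/(k1+k2),

with E the WLC entropic energies and V the zero-force free energy of the
protein state.  Boltzmann statistics on G(D) between two construct states
drive everything downstream (occupancy fits, rate models, simulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import (
    DEFAULT_TEMPERATURE_K,
    DNA_HANDLE_BP,
    DNA_PERSISTENCE_NM,
    DNA_RISE_PER_BP_NM,
    PEPTIDE_PERSISTENCE_NM,
    thermal_energy,
)
from .polymer import PolymerSegment, wlc_entropic_energy, wlc_extension

__all__ = [
    "TrapPair",
    "ConstructState",
    "SystemEquilibrium",
    "default_dna_handle",
    "solve_equilibrium",
    "system_free_energy",
    "free_energy_difference",
    "predicted_extension_change",
    "separation_for_force",
    "equilibrium_separation",
]

#: Force-balance residual tolerance, pN.
FORCE_TOLERANCE_PN = 1e-9


@dataclass(frozen=True)
class TrapPair:
    """Two optical traps with stiffnesses k1, k2 (pN/nm)."""

    stiffness_1_pn_nm: float
    stiffness_2_pn_nm: float

    def __post_init__(self) -> None:
        if self.stiffness_1_pn_nm <= 0 or self.stiffness_2_pn_nm <= 0:
            raise ValueError("trap stiffnesses must be positive")

    @property
    def effective_stiffness(self) -> float:
        """Series stiffness k1 k2 / (k1 + k2), pN/nm."""
        k1, k2 = self.stiffness_1_pn_nm, self.stiffness_2_pn_nm
        return k1 * k2 / (k1 + k2)

    @property
    def compliance(self) -> float:
        """1/k1 + 1/k2, nm/pN."""
        return 1.0 / self.stiffness_1_pn_nm + 1.0 / self.stiffness_2_pn_nm


@dataclass(frozen=True)
class ConstructState:
    """One conformational state of the protein construct.

    ``unfolded_contour_nm`` is the contour length of the disordered
    polypeptide between the pulling sites in this state; ``hard_core_nm`` the
    force-independent size of the folded portion defined by its two pulling
    points; ``energy_kbt`` the zero-force free energy V relative to a declared
    reference state.
    """

    label: str
    unfolded_contour_nm: float
    hard_core_nm: float
    energy_kbt: float = 0.0

    def __post_init__(self) -> None:
        if self.unfolded_contour_nm < 0:
            raise ValueError("unfolded contour length must be non-negative")
        if self.hard_core_nm < 0:
            raise ValueError("hard core size must be non-negative")

    def peptide(self, temperature_k: float = DEFAULT_TEMPERATURE_K) -> PolymerSegment:
        return PolymerSegment(
            PEPTIDE_PERSISTENCE_NM, self.unfolded_contour_nm, temperature_k
        )


@dataclass(frozen=True)
class SystemEquilibrium:
    """Mechanical equilibrium of the dumbbell at one trap separation and state."""

    separation_nm: float
    force_pn: float
    extension_nm: float          # tether extension X = D - x1 - x2
    dna_extension_nm: float
    peptide_extension_nm: float
    hard_core_nm: float
    bead_displacement_1_nm: float
    bead_displacement_2_nm: float
    residual_pn: float

    @property
    def mean_bead_force_pn(self) -> float:
        """(F1 + F2)/2; tension is uniform along the series, so equals force_pn."""
        return self.force_pn


def default_dna_handle(temperature_k: float = DEFAULT_TEMPERATURE_K) -> PolymerSegment:
    """The 2,260-bp dsDNA handle as a WLC (P = 40 nm, 0.34 nm/bp)."""
    return PolymerSegment(
        DNA_PERSISTENCE_NM, DNA_HANDLE_BP * DNA_RISE_PER_BP_NM, temperature_k
    )


def _series_length(
    traps: TrapPair,
    state: ConstructState,
    handle: PolymerSegment,
    force_pn: float,
) -> tuple[float, float, float]:
    """Total series length at tension F and its (DNA, peptide) components."""
    x_dna = wlc_extension(handle, force_pn)
    x_p = wlc_extension(state.peptide(handle.temperature_k), force_pn)
    total = force_pn * traps.compliance + x_dna + x_p + state.hard_core_nm
    return total, x_dna, x_p


def solve_equilibrium(
    traps: TrapPair,
    state: ConstructState,
    handle: PolymerSegment,
    separation_nm: float,
) -> SystemEquilibrium:
    """Unique tension F >= 0 satisfying the series force balance at separation D.

    A slack tether (D <= hard core) carries no tension: F = 0 and X = D.
    """
    if separation_nm < 0:
        raise ValueError("trap separation must be non-negative")
    if separation_nm <= state.hard_core_nm:
        return SystemEquilibrium(
            separation_nm, 0.0, separation_nm, 0.0, 0.0,
            state.hard_core_nm, 0.0, 0.0, 0.0,
        )

    def resid(f: float) -> float:
        return _series_length(traps, state, handle, f)[0] - separation_nm

    f_hi = 1.0
    while resid(f_hi) < 0:
        f_hi *= 2.0
        if f_hi > 1e6:  # pragma: no cover - monotone components cannot get here
            raise RuntimeError("force balance failed to bracket")
    if resid(0.0) >= 0:
        force = 0.0
    else:
        force = brentq(resid, 0.0, f_hi, xtol=1e-12, rtol=8.9e-16)
    total, x_dna, x_p = _series_length(traps, state, handle, force)
    residual = total - separation_nm
    if abs(residual) > 1e-6:  # pragma: no cover - solver tolerance guard
        raise RuntimeError(f"force balance residual {residual:.3g} pN exceeds tolerance")
    x1 = force / traps.stiffness_1_pn_nm
    x2 = force / traps.stiffness_2_pn_nm
    return SystemEquilibrium(
        separation_nm, force, separation_nm - x1 - x2,
        x_dna, x_p, state.hard_core_nm, x1, x2, residual,
    )


def system_free_energy(
    traps: TrapPair,
    state: ConstructState,
    handle: PolymerSegment,
    separation_nm: float,
) -> float:
    """Total dumbbell free energy G (kBT) of ``state`` at separation D.

    G = F^2/(2 k_traps) + E_DNA + E_p + V, each term at the state's own
    mechanical equilibrium.  When the tether is slack, G = V.
    """
    eq = solve_equilibrium(traps, state, handle, separation_nm)
    kbt = thermal_energy(handle.temperature_k)
    if eq.force_pn == 0.0:
        return state.energy_kbt
    trap_energy = eq.force_pn**2 / (2.0 * traps.effective_stiffness)
    e_dna = wlc_entropic_energy(handle, eq.dna_extension_nm)
    e_p = wlc_entropic_energy(
        state.peptide(handle.temperature_k), eq.peptide_extension_nm
    )
    return (trap_energy + e_dna + e_p) / kbt + state.energy_kbt


def free_energy_difference(
    traps: TrapPair,
    state_a: ConstructState,
    state_b: ConstructState,
    handle: PolymerSegment,
    separation_nm: float,
) -> float:
    """G_B(D) - G_A(D) in kBT, each state at its own equilibrium."""
    return system_free_energy(traps, state_b, handle, separation_nm) - \
        system_free_energy(traps, state_a, handle, separation_nm)


def predicted_extension_change(
    traps: TrapPair,
    state_a: ConstructState,
    state_b: ConstructState,
    handle: PolymerSegment,
    separation_nm: float,
) -> tuple[float, float]:
    """(X_B - X_A, F_B - F_A) at fixed trap separation.

    Extension and force move out of phase: a transition that lengthens the
    tether relaxes the beads and lowers the tension.
    """
    eq_a = solve_equilibrium(traps, state_a, handle, separation_nm)
    eq_b = solve_equilibrium(traps, state_b, handle, separation_nm)
    return eq_b.extension_nm - eq_a.extension_nm, eq_b.force_pn - eq_a.force_pn


def separation_for_force(
    traps: TrapPair,
    state: ConstructState,
    handle: PolymerSegment,
    force_pn: float,
) -> float:
    """Trap separation at which ``state`` carries tension ``force_pn`` (forward map)."""
    if force_pn < 0:
        raise ValueError("force must be non-negative")
    return _series_length(traps, state, handle, force_pn)[0]


def equilibrium_separation(
    traps: TrapPair,
    folded: ConstructState,
    unfolded: ConstructState,
    handle: PolymerSegment,
    force_bracket_pn: tuple[float, float] = (0.5, 30.0),
) -> float:
    """Separation D at which the two states are equally populated (ΔG(D) = 0)."""
    d_lo = separation_for_force(traps, folded, handle, force_bracket_pn[0])
    d_hi = separation_for_force(traps, folded, handle, force_bracket_pn[1])

    def dg(d: float) -> float:
        return free_energy_difference(traps, folded, unfolded, handle, d)

    g_lo, g_hi = dg(d_lo), dg(d_hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            "free-energy difference does not change sign over the force bracket; "
            "widen force_bracket_pn"
        )
    return brentq(dg, d_lo, d_hi, xtol=1e-9)
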