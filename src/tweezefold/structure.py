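"""Contour-length structural inference from extension changes at force.

A folding transition at tension F removes contour length ΔL from the
stretched, disordered polypeptide and may change the hard-core size H of the
folded portion (defined by its two pulling points).  The protein length
change at force is

    Δl(F) = z(F) · ΔL - ΔH,

with z(F) the WLC relative extension of the polypeptide (persistence length
0.6 nm) and ΔH = H_folded - H_unfolded (positive when the folded state's hard
core is larger).  Dividing ΔL by 0.365 nm per residue gives the number of
amino acids sequestered by folding.

Note that Δl is the *protein* length change at force.  At constant trap
separation the measured extension jump is attenuated by the series
compliance; convert measured jumps with the dumbbell model
(:func:`tweezefold.dumbbell.predicted_extension_change`) before calling
:func:`residues_sequestered`, or pass the protein-level change directly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import DEFAULT_TEMPERATURE_K, NM_PER_RESIDUE, PEPTIDE_PERSISTENCE_NM
from .polymer import relative_extension_at_force

__all__ = [
    "StructuralTransition",
    "ConstructDefinition",
    "StateDefinition",
    "residues_sequestered",
    "state_contour_table",
]

#: below this relative extension the inversion is ill-conditioned
MIN_RELATIVE_EXTENSION = 0.05


@dataclass(frozen=True)
class StructuralTransition:
    """Inferred structural content of one folding/unfolding transition."""

    extension_change_nm: float
    force_pn: float
    hard_core_change_nm: float
    contour_change_nm: float
    residues: float
    residues_sd: float | None = None

    @property
    def residues_rounded(self) -> int:
        return int(round(self.residues))


def residues_sequestered(
    extension_change_nm: float,
    force_pn: float,
    hard_core_change_nm: float = 0.0,
    persistence_length_nm: float = PEPTIDE_PERSISTENCE_NM,
    extension_change_sd_nm: float | None = None,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    nm_per_residue: float = NM_PER_RESIDUE,
) -> StructuralTransition:
    """Residues sequestered by a folding transition, from its length change.

    ``extension_change_nm`` is the protein extension change Δl at force
    ``force_pn`` (positive); ``hard_core_change_nm`` is ΔH, folded minus
    unfolded.  Solves z(F)·ΔL = Δl + ΔH for the contour change ΔL and
    converts to residues.  Uncertainty on Δl propagates linearly:
    sd(ΔL) = sd(Δl)/z(F).
    """
    if force_pn <= 0:
        raise ValueError("force must be positive")
    if extension_change_nm <= 0:
        raise ValueError("extension change must be positive for a folding transition")
    z = relative_extension_at_force(persistence_length_nm, force_pn, temperature_k)
    if z < MIN_RELATIVE_EXTENSION:
        raise ValueError(
            f"relative extension z(F) = {z:.3f} < {MIN_RELATIVE_EXTENSION}; the "
            "contour inversion is ill-conditioned — use higher-force data"
        )
    contour = (extension_change_nm + hard_core_change_nm) / z
    if contour <= 0:
        raise ValueError(
            "hard-core change exceeds the extension change; no contour is released"
        )
    residues = contour / nm_per_residue
    residues_sd = None
    if extension_change_sd_nm is not None:
        residues_sd = extension_change_sd_nm / z / nm_per_residue
    return StructuralTransition(
        extension_change_nm=extension_change_nm,
        force_pn=force_pn,
        hard_core_change_nm=hard_core_change_nm,
        contour_change_nm=contour,
        residues=residues,
        residues_sd=residues_sd,
    )


@dataclass(frozen=True)
class StateDefinition:
    """Residue bookkeeping of one construct state."""

    sequestered_residues: int   # residues folded (removed from the tether)
    hard_core_nm: float
    energy_kbt: float = 0.0


@dataclass(frozen=True)
class ConstructDefinition:
    """A crosslinked two-SNARE conjugate between two pulling sites.

    ``qa_residues``/``r_residues`` count the residues of each SNARE motif
    between its pulling site and the crosslink; ``loop_residues`` the extra
    residues in the crosslink loop.  In the fully unfolded state the whole
    span is disordered.
    """

    name: str
    qa_residues: int
    r_residues: int
    loop_residues: int
    states: dict[str, StateDefinition]

    def __post_init__(self) -> None:
        if min(self.qa_residues, self.r_residues, self.loop_residues) < 0:
            raise ValueError("residue counts must be non-negative")
        if self.total_residues == 0:
            raise ValueError("construct has no residues between the pulling sites")
        for label, st in self.states.items():
            if st.sequestered_residues < 0 or st.sequestered_residues > self.total_residues:
                raise ValueError(
                    f"state {label!r} sequesters {st.sequestered_residues} residues, "
                    f"outside the construct span of {self.total_residues}"
                )

    @property
    def total_residues(self) -> int:
        return self.qa_residues + self.r_residues + self.loop_residues


def state_contour_table(
    construct: ConstructDefinition, nm_per_residue: float = NM_PER_RESIDUE
) -> dict[str, float]:
    """Unfolded contour length (nm) of each modeled state of a construct."""
    return {
        label: (construct.total_residues - st.sequestered_residues) * nm_per_residue
        for label, st in construct.states.items()
    }
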