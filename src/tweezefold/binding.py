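"""Tethered-ligand affinity chain and relative fusion-rate predictions.

Crosslinking tethers the R-SNARE near the chaperone-bound Qa-SNARE, so the
observed folding rate of the intramolecular complex is a bimolecular
association at the tether's effective concentration c:

    k_f = k_on · c   →   k_on = k_f / c,
    K_d = k_off / k_on,       ΔG_bind = ln(c° / K_d),  c° = 1 M.

Stabilizing or destabilizing the binding partner by ΔΔG rescales the
dissociation constant as K_d · exp(ΔΔG).

For variants, the overall fusion rate is assumed proportional to the
equilibrium population of the intermediate complex times the rate of
downstream partner binding:

    k_m / k_WT = (r_m / r_WT) · exp(G_m - G_WT),

with G the unfolding energy (kBT) of the complex and r the downstream binding
measure (here the SNAP-25 binding probability).  Uncertainty propagates to
first order from the energy SEMs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BindingResult",
    "FusionRatePrediction",
    "intramolecular_kon",
    "dissociation_chain",
    "extrapolate_affinity",
    "bimolecular_rate",
    "relative_fusion_rate",
    "load_variant_table",
    "predict_fusion_rates",
    "affinity_chain",
]

#: standard-state concentration for binding free energies, mol/L
STANDARD_STATE_M = 1.0

#: censored marker used for stabilities below the assay detection limit
CENSORED_PREFIX = "<"


@dataclass(frozen=True)
class BindingResult:
    """The tethered-ligand affinity chain for one construct."""

    effective_concentration_m: float
    kon_per_m_s: float
    koff_per_s: float
    kd_m: float
    binding_energy_kbt: float
    extrapolated_kd_m: float | None = None


@dataclass(frozen=True)
class FusionRatePrediction:
    """Predicted fold-change in overall fusion rate for one variant."""

    mutation: str
    fold_change: float | None   # None when the variant energy is censored
    fold_change_sd: float | None
    censored: bool = False


def intramolecular_kon(folding_rate_per_s: float, effective_concentration_m: float) -> float:
    """Bimolecular association rate constant (1/M/s) from a tethered folding rate."""
    if folding_rate_per_s <= 0 or effective_concentration_m <= 0:
        raise ValueError("rate and concentration must be positive")
    return folding_rate_per_s / effective_concentration_m


def dissociation_chain(koff_per_s: float, kon_per_m_s: float) -> tuple[float, float]:
    """(K_d in M, binding energy in kBT at the 1 M standard state)."""
    if koff_per_s <= 0 or kon_per_m_s <= 0:
        raise ValueError("rates must be positive")
    kd = koff_per_s / kon_per_m_s
    return kd, math.log(STANDARD_STATE_M / kd)


def extrapolate_affinity(kd_m: float, delta_delta_g_kbt: float) -> float:
    """K_d of an alternative state requiring an extra ΔΔG (kBT) to bind."""
    if kd_m <= 0:
        raise ValueError("dissociation constant must be positive")
    return kd_m * math.exp(delta_delta_g_kbt)


def bimolecular_rate(
    concentration_m: float,
    binding_probability: float | None = None,
    window_s: float | None = None,
    mean_wait_s: float | None = None,
) -> float:
    """Bimolecular rate constant (1/M/s) from single-molecule binding statistics.

    Probability form: with binding probability P per window of length T at
    concentration c, k = -ln(1-P) / (c·T).  Waiting-time form: with mean time
    to binding Δt, k = 1/(Δt·c).  Supply either (probability, window) or
    mean_wait.
    """
    if concentration_m <= 0:
        raise ValueError("concentration must be positive")
    if mean_wait_s is not None:
        if mean_wait_s <= 0:
            raise ValueError("mean waiting time must be positive")
        return 1.0 / (mean_wait_s * concentration_m)
    if binding_probability is None or window_s is None:
        raise ValueError("supply binding_probability and window_s, or mean_wait_s")
    if not 0.0 < binding_probability < 1.0:
        if binding_probability >= 1.0:
            raise ValueError(
                "binding probability of 1 within the window implies an "
                "unresolvably fast rate"
            )
        raise ValueError("binding probability must lie in (0, 1)")
    if window_s <= 0:
        raise ValueError("observation window must be positive")
    return -math.log1p(-binding_probability) / (concentration_m * window_s)


def relative_fusion_rate(
    g_mutant_kbt: float,
    g_wt_kbt: float,
    r_mutant: float,
    r_wt: float,
    g_mutant_sem: float | None = None,
    g_wt_sem: float | None = None,
) -> tuple[float, float | None]:
    """Fold-change (r_m/r_WT)·exp(G_m − G_WT) with first-order uncertainty."""
    if r_mutant <= 0 or r_wt <= 0:
        raise ValueError("binding measures must be positive")
    fold = (r_mutant / r_wt) * math.exp(g_mutant_kbt - g_wt_kbt)
    sd = None
    if g_mutant_sem is not None and g_wt_sem is not None:
        sd = fold * math.sqrt(g_mutant_sem**2 + g_wt_sem**2)
    return fold, sd


def load_variant_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the variant parameter table (bundled measurements by default).

    Censored unfolding energies ("<1.5") are parsed to NaN with
    ``energy_censored`` set; all other columns are numeric where possible.
    """
    if path is None:
        with resources.as_file(
            resources.files("tweezefold.data") / "template_complex_table.csv"
        ) as p:
            df = pd.read_csv(p, dtype={"unfolding_energy_kbt": str})
    else:
        df = pd.read_csv(path, dtype={"unfolding_energy_kbt": str})
    raw = df["unfolding_energy_kbt"].astype(str).str.strip()
    df["energy_censored"] = raw.str.startswith(CENSORED_PREFIX)
    df["unfolding_energy_kbt"] = pd.to_numeric(
        raw.str.lstrip(CENSORED_PREFIX), errors="coerce"
    ).where(~df["energy_censored"])
    return df


def predict_fusion_rates(
    table: pd.DataFrame | None = None, reference: str = "WT"
) -> list[FusionRatePrediction]:
    """Fold-change predictions for every variant in a parameter table.

    Censored stabilities (below the detection limit) propagate as censored —
    the fusion rate is reported as effectively abolished, never as a number
    computed from the detection limit.
    """
    if table is None:
        table = load_variant_table()
    ref_rows = table[table["mutation"] == reference]
    if ref_rows.empty:
        raise ValueError(f"reference row {reference!r} not found")
    ref = ref_rows.iloc[0]
    g_wt = float(ref["unfolding_energy_kbt"])
    r_wt = float(ref["snap25_binding_prob"])
    g_wt_sem = float(ref.get("unfolding_energy_sem_kbt", np.nan))

    out: list[FusionRatePrediction] = []
    for _, row in table.iterrows():
        name = str(row["mutation"])
        if bool(row.get("energy_censored", False)):
            out.append(FusionRatePrediction(name, None, None, censored=True))
            continue
        g_m = row["unfolding_energy_kbt"]
        r_m = row["snap25_binding_prob"]
        if pd.isna(g_m) or pd.isna(r_m):
            continue
        sem = row.get("unfolding_energy_sem_kbt", np.nan)
        fold, sd = relative_fusion_rate(
            float(g_m), g_wt, float(r_m), r_wt,
            None if pd.isna(sem) else float(sem),
            None if pd.isna(g_wt_sem) else g_wt_sem,
        )
        out.append(FusionRatePrediction(name, fold, sd))
    return out


def affinity_chain(
    folding_rate_per_s: float,
    unfolding_rate_per_s: float,
    effective_concentration_m: float,
    closed_state_penalty_kbt: float | None = None,
) -> BindingResult:
    """Full chain: c → k_on → K_d → binding energy (→ closed-state K_d).

    Because folding is binding-limited in the tethered geometry, the measured
    folding/unfolding rates double as association/dissociation rates at the
    effective concentration.
    """
    kon = intramolecular_kon(folding_rate_per_s, effective_concentration_m)
    kd, energy = dissociation_chain(unfolding_rate_per_s, kon)
    extrapolated = (
        extrapolate_affinity(kd, closed_state_penalty_kbt)
        if closed_state_penalty_kbt is not None
        else None
    )
    return BindingResult(
        effective_concentration_m=effective_concentration_m,
        kon_per_m_s=kon,
        koff_per_s=unfolding_rate_per_s,
        kd_m=kd,
        binding_energy_kbt=energy,
        extrapolated_kd_m=extrapolated,
    )
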