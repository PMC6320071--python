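"""Pipeline configuration: constants, construct states, traps, fit options.

A configuration is a YAML document with the sections below; unknown keys are
rejected and physical values validated.  ``default_config()`` returns the
wild-type template-complex setup used throughout the package.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import (
    DEFAULT_TEMPERATURE_K,
    DNA_HANDLE_BP,
    DNA_PERSISTENCE_NM,
    DNA_RISE_PER_BP_NM,
    NM_PER_RESIDUE,
    PEPTIDE_PERSISTENCE_NM,
)

__all__ = ["PipelineConfig", "StateConfig", "load_config", "default_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration document violates the schema."""


@dataclass
class StateConfig:
    unfolded_contour_nm: float
    hard_core_nm: float
    energy_kbt: float = 0.0


@dataclass
class PipelineConfig:
    temperature_k: float = DEFAULT_TEMPERATURE_K
    nm_per_residue: float = NM_PER_RESIDUE
    dna_persistence_nm: float = DNA_PERSISTENCE_NM
    peptide_persistence_nm: float = PEPTIDE_PERSISTENCE_NM
    dna_handle_bp: int = DNA_HANDLE_BP
    dna_rise_per_bp_nm: float = DNA_RISE_PER_BP_NM
    trap_stiffness_1_pn_nm: float = 0.2
    trap_stiffness_2_pn_nm: float = 0.2
    sampling_rate_hz: float = 1000.0
    noise_sigma_nm: float = 1.5
    pulling_speed_nm_s: float = 10.0
    hmm_filter_window: int | None = None
    ts_fraction: float | None = None
    states: dict[str, StateConfig] = field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = (
            "temperature_k", "nm_per_residue", "dna_persistence_nm",
            "peptide_persistence_nm", "dna_handle_bp", "dna_rise_per_bp_nm",
            "trap_stiffness_1_pn_nm", "trap_stiffness_2_pn_nm",
            "sampling_rate_hz", "pulling_speed_nm_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sigma_nm < 0:
            raise ConfigError("noise_sigma_nm must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def default_config() -> PipelineConfig:
    """Wild-type template-complex defaults (states 6 and 7 of the construct)."""
    return PipelineConfig(
        states={
            "folded_template_complex": StateConfig(35.0, 5.0, 0.0),
            "partially_closed_syntaxin": StateConfig(69.1, 2.2, 5.2),
        }
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML configuration document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    states_doc = doc.pop("states", {}) or {}
    states = {}
    for label, body in states_doc.items():
        if not isinstance(body, dict):
            raise ConfigError(f"state {label!r} must be a mapping")
        extra = set(body) - set(StateConfig.__dataclass_fields__)
        if extra:
            raise ConfigError(f"state {label!r} has unknown keys {sorted(extra)}")
        st = StateConfig(**body)
        if st.unfolded_contour_nm < 0 or st.hard_core_nm < 0:
            raise ConfigError(f"state {label!r} has negative lengths")
        states[label] = st
    try:
        return PipelineConfig(states=states, **doc)
    except TypeError as err:
        raise ConfigError(str(err)) from err
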