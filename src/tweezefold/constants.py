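"""Physical constants and instrument defaults.

All mechanics in this package are done in the pN/nm/s unit system, where the
thermal energy at room temperature is kBT ~ 4.114 pN nm.  Energies exposed to
users are expressed in units of kBT unless a field name says otherwise.
"""

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM_PER_K = 0.0138065

#: Default experiment temperature (room temperature), K.
DEFAULT_TEMPERATURE_K = 298.0

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: Conversion of a number density of 1 molecule/nm^3 to mol/L.
#: 1 nm^-3 = 1e24 L^-1; divide by Avogadro's number.
NM3_TO_MOLAR = 1e24 / AVOGADRO

#: Contour length per amino-acid residue, nm.
NM_PER_RESIDUE = 0.365

#: Persistence length of double-stranded DNA, nm.
DNA_PERSISTENCE_NM = 40.0

#: Persistence length of an unfolded polypeptide, nm.
PEPTIDE_PERSISTENCE_NM = 0.6

#: Rise per base pair of B-form DNA, nm (used for the handle contour length).
DNA_RISE_PER_BP_NM = 0.34

#: Length of the DNA handle tethering the protein to one bead, bp.
DNA_HANDLE_BP = 2260

#: kcal/mol per kBT at 298 K.
KCAL_PER_MOL_PER_KBT = 0.593


def thermal_energy(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kBT in pN nm at the given temperature."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return BOLTZMANN_PN_NM_PER_K * temperature_k
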