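"""Physical constants and element data used across the package.

Unit conventions (everywhere in the package):

* scattering wavenumber ``q`` — nm⁻¹
* lengths — nm
* electron densities — e Å⁻³ (converted internally with :data:`E_A3_TO_E_NM3`)
* absolute scattered intensities — cm⁻¹
"""

from __future__ import annotations

import math

#: Classical electron radius, cm (Thomson scattering length).
R_ELECTRON_CM: float = 0.28179e-12

#: Avogadro constant, mol⁻¹.
N_AVOGADRO: float = 6.02214076e23

#: Boltzmann constant, J K⁻¹.
K_BOLTZMANN: float = 1.380649e-23

#: Elementary charge, C.
E_CHARGE: float = 1.602176634e-19

#: Vacuum permittivity, F m⁻¹.
EPSILON_0: float = 8.8541878128e-12

#: 1 e Å⁻³ expressed in e nm⁻³.
E_A3_TO_E_NM3: float = 1.0e3

#: 1 e Å⁻³ expressed in e cm⁻³.
E_A3_TO_E_CM3: float = 1.0e24


def bjerrum_length_nm(temperature: float = 298.0, dielectric: float = 78.5) -> float:
    """Bjerrum length λ_B = e²/(4π ε0 εr k_B T) in nm.

    At 298 K in water (εr = 78.5) this is ≈ 0.714 nm.
    """
    lam_m = E_CHARGE**2 / (4.0 * math.pi * EPSILON_0 * dielectric * K_BOLTZMANN * temperature)
    return lam_m * 1.0e9


# Atomic numbers (= electron counts for neutral atoms) for the elements that
# occur in peptide/lipid coordinate sets.
ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "FE": 26, "ZN": 30, "BR": 35, "I": 53,
}

# Bondi van der Waals radii, nm.
VDW_RADIUS_NM: dict[str, float] = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "F": 0.147, "NA": 0.227,
    "MG": 0.173, "P": 0.180, "S": 0.180, "CL": 0.175, "K": 0.275, "CA": 0.231,
    "FE": 0.200, "ZN": 0.139, "BR": 0.185, "I": 0.198,
}

# United-atom pseudo-atoms (CHn) expanded to an effective electron count and a
# slightly enlarged radius; used when coordinate files carry united-atom names.
UNITED_ATOM_ELECTRONS: dict[str, int] = {"CH1": 7, "CH2": 8, "CH3": 9, "CH4": 10}
UNITED_ATOM_RADIUS_NM: dict[str, float] = {"CH1": 0.185, "CH2": 0.195, "CH3": 0.205, "CH4": 0.215}


def normalize_element(symbol: str) -> str:
    """Normalize a (possibly mixed-case) element symbol, e.g. ``'Cl'`` → ``'CL'``."""
    sym = symbol.strip().upper()
    if not sym:
        raise ValueError("empty element symbol")
    return sym


def electrons_for(symbol: str) -> int:
    """Electron count for a neutral atom or CHn united-atom pseudo-atom."""
    sym = normalize_element(symbol)
    if sym in UNITED_ATOM_ELECTRONS:
        return UNITED_ATOM_ELECTRONS[sym]
    try:
        return ATOMIC_NUMBER[sym]
    except KeyError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None


def vdw_radius_for(symbol: str) -> float:
    """Van der Waals radius (nm) for an element or CHn pseudo-atom."""
    sym = normalize_element(symbol)
    if sym in UNITED_ATOM_RADIUS_NM:
        return UNITED_ATOM_RADIUS_NM[sym]
    try:
        return VDW_RADIUS_NM[sym]
    except KeyError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None
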