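"""Micelle molar mass and association number from absolute forward scattering.

On absolute scale (cm⁻¹) the forward intensity of a dilute micellar
solution is

    I(0) = c_mic · M_mic · [r0 · v_p · (ρ_l − ρ_0)]² / N_A

so the micelle molar mass follows model-independently as

    M_mic = I(0) · N_A / (c_mic · [r0 · v_p · (ρ_l − ρ_0)]²)

with c_mic in g cm⁻³, v_p the partial specific volume in cm³ g⁻¹,
electron densities in e Å⁻³ (converted to e cm⁻³ internally) and r0 the
classical electron radius.  The association number is p = M_mic/M_mol.

The Tanford chain-volume and alkyl-tail electron-density helpers supply
the contrast inputs for a lipidated peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._constants import E_A3_TO_E_CM3, N_AVOGADRO, R_ELECTRON_CM
from .datatypes import ScatteringCurve

__all__ = [
    "ContrastInputs", "MassResult", "tanford_volume", "tail_electron_density",
    "micelle_molar_mass", "association_number", "forward_intensity_from_mass",
    "ratio_association_estimate",
]


@dataclass
class ContrastInputs:
    """Everything the absolute-intensity molar-mass formula needs.

    i0 (cm⁻¹), c_mic (g cm⁻³), v_p (cm³ g⁻¹), rho_l and rho_0 (e Å⁻³).
    ``cmc`` (g cm⁻³) is subtracted from c_mic when
    ``subtract_free_monomer`` is enabled (off by default: the standard
    worked analysis uses the total concentration).
    """

    i0: float
    c_mic: float
    v_p: float
    rho_l: float
    rho_0: float = 0.333
    cmc: Optional[float] = None
    subtract_free_monomer: bool = False

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValueError("i0 must be > 0")
        if self.c_mic <= 0:
            raise ValueError("c_mic must be > 0")
        if self.v_p <= 0:
            raise ValueError("v_p must be > 0")
        if self.rho_0 <= 0:
            raise ValueError("rho_0 must be > 0")

    @property
    def effective_concentration(self) -> float:
        if self.subtract_free_monomer:
            if self.cmc is None:
                raise ValueError("subtract_free_monomer requires a cmc value")
            c = self.c_mic - self.cmc
            if c <= 0:
                raise ValueError("concentration does not exceed the CMC")
            return c
        return self.c_mic


@dataclass
class MassResult:
    """Micelle molar mass (g mol⁻¹) and association number (if computed)."""

    m_mic: float
    p: Optional[float]
    inputs: ContrastInputs

    def __post_init__(self) -> None:
        if self.m_mic <= 0:
            raise ValueError("m_mic must be > 0")
        if self.p is not None and self.p <= 0:
            raise ValueError("p must be > 0")


def tanford_volume(n_carbons: float) -> float:
    """Tanford volume per alkyl chain, v = 27.4 + 26.9·n (Å³).

    ``n_carbons`` excludes the terminal CH₃ group.
    """
    if n_carbons < 0:
        raise ValueError("n_carbons must be >= 0")
    return 27.4 + 26.9 * n_carbons


def tail_electron_density(n_electrons: float, v_l: float) -> float:
    """Alkyl-tail electron density (e Å⁻³) = electrons / chain volume (Å³)."""
    if n_electrons <= 0:
        raise ValueError("n_electrons must be > 0")
    if v_l <= 0:
        raise ValueError("v_l must be > 0")
    return n_electrons / v_l


def _contrast_factor_cm4_per_g2(v_p: float, rho_l: float, rho_0: float) -> float:
    # [r0 (cm) · v_p (cm³/g) · Δρ (e/cm³)]² in cm⁴ g⁻²
    delta_rho_cm3 = (rho_l - rho_0) * E_A3_TO_E_CM3
    return (R_ELECTRON_CM * v_p * delta_rho_cm3) ** 2


def micelle_molar_mass(inputs: ContrastInputs,
                       m_mol: Optional[float] = None) -> MassResult:
    """Micelle molar mass from absolute forward scattering.

    When the monomer molar mass ``m_mol`` is given, the association
    number p = M_mic/M_mol is filled in as well.
    """
    if inputs.rho_l == inputs.rho_0:
        raise ZeroDivisionError("degenerate contrast: rho_l equals rho_0")
    k = _contrast_factor_cm4_per_g2(inputs.v_p, inputs.rho_l, inputs.rho_0)
    m_mic = float(inputs.i0 * N_AVOGADRO / (inputs.effective_concentration * k))
    p = association_number(m_mic, m_mol) if m_mol is not None else None
    return MassResult(m_mic=m_mic, p=p, inputs=inputs)


def association_number(m_mic: float, m_mol: float) -> float:
    """Association number p = M_mic / M_mol."""
    if m_mic <= 0:
        raise ValueError("m_mic must be > 0")
    if m_mol <= 0:
        raise ValueError("m_mol must be > 0")
    return m_mic / m_mol


def forward_intensity_from_mass(c_mic: float, m_mic: float, v_p: float,
                                rho_l: float, rho_0: float = 0.333) -> float:
    """Inverse of :func:`micelle_molar_mass`: absolute I(0) in cm⁻¹."""
    if c_mic <= 0 or m_mic <= 0:
        raise ValueError("c_mic and m_mic must be > 0")
    k = _contrast_factor_cm4_per_g2(v_p, rho_l, rho_0)
    return c_mic * m_mic * k / N_AVOGADRO


def ratio_association_estimate(curve_hi: ScatteringCurve, curve_lo: ScatteringCurve,
                               q_probe: float, p_ref: float) -> dict:
    """Rough association number from concentration-normalized low-q intensities.

    p ≈ p_ref × [I_hi(q_probe)/c_hi] / [I_lo(q_probe)/c_lo].  A caveat
    flag is raised when the high-concentration curve shows a
    structure-factor peak, which biases the ratio downward.
    """
    from .saxs.fitting import detect_interference_peak

    for name, cur in (("curve_hi", curve_hi), ("curve_lo", curve_lo)):
        if cur.concentration is None:
            raise ValueError(f"{name} is missing concentration metadata")

    def probe(curve: ScatteringCurve) -> float:
        # nearest grid point, falling back to linear interpolation when the
        # probe lies between widely spaced points
        idx = int(np.argmin(np.abs(curve.q - q_probe)))
        dq_local = np.median(np.diff(curve.q))
        if abs(curve.q[idx] - q_probe) <= dq_local:
            return float(curve.intensity[idx])
        return float(np.interp(q_probe, curve.q, curve.intensity))

    norm_hi = probe(curve_hi) / curve_hi.concentration
    norm_lo = probe(curve_lo) / curve_lo.concentration
    ratio = norm_hi / norm_lo
    peak_flag = detect_interference_peak(curve_hi)
    return {
        "p_estimate": float(p_ref * ratio),
        "intensity_ratio": float(ratio),
        "structure_factor_caveat": bool(peak_flag),
    }
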