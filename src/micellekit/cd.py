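"""Circular-dichroism helicity analysis for short peptides.

The machine signal θ (mdeg) is normalized to whole-molecule molar
ellipticity [θ] = θ/(10·c·l) (deg cm² dmol⁻¹, c in mol L⁻¹, l in cm),
then divided by the residue count to give per-residue values.  The
α-helix fraction uses the chain-length-corrected theoretical limit

    [θ]222(theor) = −37400 × (1 − 2.5/N)

so f_a = [θ]222(obs, per residue) / [θ]222(theor).  The [θ]222/[θ]208
ratio discriminates coiled-coil association (ratio ≥ 1) from isolated
helices (ratio < 1).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import CDSpectrum, HelicityResult

__all__ = [
    "mdeg_to_molar_ellipticity", "theoretical_helix_ellipticity",
    "helix_fraction", "coiled_coil_ratio", "smooth_spectrum",
    "read_ellipticity_at", "analyze_spectrum",
]

#: Infinite-chain per-residue molar ellipticity at 222 nm for a pure helix.
THETA_HELIX_INF = -37400.0
#: End-effect correction length (residues).
HELIX_END_CORRECTION = 2.5


def mdeg_to_molar_ellipticity(spectrum: CDSpectrum) -> np.ndarray:
    """Whole-molecule molar ellipticity [θ](λ) = θ_mdeg/(10·c·l).

    Units: deg cm² dmol⁻¹ with c in mol L⁻¹ and l in cm.
    """
    if spectrum.concentration is None or spectrum.pathlength is None:
        raise ValueError("concentration and pathlength are required")
    if spectrum.concentration <= 0:
        raise ValueError("concentration must be > 0")
    return spectrum.ellipticity / (10.0 * spectrum.concentration * spectrum.pathlength)


def molar_ellipticity_to_mdeg(theta_molar: np.ndarray, concentration: float,
                              pathlength: float) -> np.ndarray:
    """Inverse of :func:`mdeg_to_molar_ellipticity` (used by generators)."""
    return np.asarray(theta_molar, float) * 10.0 * concentration * pathlength


def theoretical_helix_ellipticity(n_residues: float) -> float:
    """Per-residue [θ]222 of a 100 % helical N-residue chain.

    −37400 × (1 − 2.5/N); → −37400 as N → ∞.
    """
    if n_residues <= HELIX_END_CORRECTION:
        raise ValueError(f"n_residues must exceed {HELIX_END_CORRECTION}")
    return THETA_HELIX_INF * (1.0 - HELIX_END_CORRECTION / n_residues)


def helix_fraction(theta222_whole_molecule: float, n_residues: int) -> HelicityResult:
    """α-helix fraction from the whole-molecule [θ]222.

    Divides by the residue count first (per-residue value), then by the
    chain-length-corrected theoretical helix limit.  f_a > 1 (over-unity
    from band overlap or concentration error) is reported clipped to 1
    with the ``clipped`` flag set.
    """
    if n_residues == 0:
        raise ValueError("n_residues must be nonzero")
    theta_pr = theta222_whole_molecule / n_residues
    theta_theor = theoretical_helix_ellipticity(n_residues)
    f_a = theta_pr / theta_theor
    clipped = f_a > 1.0
    return HelicityResult(
        theta222_per_residue=float(theta_pr),
        theta222_theor=float(theta_theor),
        f_a=float(min(f_a, 1.0)) if clipped else float(f_a),
        clipped=bool(clipped),
    )


def coiled_coil_ratio(theta222_per_residue: float, theta208_per_residue: float):
    """[θ]222/[θ]208 with classification: ≥ 1 → coiled-coil indicated,
    < 1 → isolated coils."""
    if theta208_per_residue == 0:
        raise ZeroDivisionError("theta208 must be nonzero")
    ratio = theta222_per_residue / theta208_per_residue
    coil_class = "coiled_coil_indicated" if ratio >= 1.0 else "isolated_coils"
    return float(ratio), coil_class


def smooth_spectrum(spectrum: CDSpectrum, window: int = 9, order: int = 2) -> CDSpectrum:
    """Savitzky–Golay smoothing of the ellipticity channel.

    The filter preserves polynomials up to ``order`` exactly, and its
    residual (raw − smoothed) oscillates around zero mean on noise-like
    spectra — the hallmark of a well-behaved smooth.
    """
    if window % 2 == 0 or window < order + 2:
        raise ValueError("window must be odd and >= order + 2")
    if window > spectrum.ellipticity.size:
        raise ValueError("window larger than the spectrum")
    smoothed = savgol_filter(spectrum.ellipticity, window_length=window, polyorder=order)
    return CDSpectrum(
        wavelength=spectrum.wavelength.copy(), ellipticity=smoothed,
        concentration=spectrum.concentration, pathlength=spectrum.pathlength,
        n_residues=spectrum.n_residues, label=spectrum.label,
    )


def read_ellipticity_at(spectrum_values: np.ndarray, wavelength: np.ndarray,
                        target_nm: float) -> float:
    """Value at a target wavelength by linear interpolation on the grid."""
    wl = np.asarray(wavelength, float)
    vals = np.asarray(spectrum_values, float)
    if target_nm < wl.min() or target_nm > wl.max():
        raise ValueError(f"{target_nm} nm is outside the recorded range")
    order = np.argsort(wl)
    return float(np.interp(target_nm, wl[order], vals[order]))


def analyze_spectrum(spectrum: CDSpectrum, *, smooth: bool = False,
                     window: int = 9, order: int = 2) -> HelicityResult:
    """Full helicity analysis of a raw CD spectrum (mdeg).

    Normalizes to molar ellipticity, reads [θ]222 and [θ]208 by linear
    interpolation, and returns per-residue values, the helix fraction
    and the coiled-coil classification.
    """
    if spectrum.n_residues is None:
        raise ValueError("spectrum needs n_residues for helicity analysis")
    work = smooth_spectrum(spectrum, window, order) if smooth else spectrum
    theta_molar = mdeg_to_molar_ellipticity(work)
    t222 = read_ellipticity_at(theta_molar, work.wavelength, 222.0)
    t208 = read_ellipticity_at(theta_molar, work.wavelength, 208.0)
    res = helix_fraction(t222, spectrum.n_residues)
    res.theta208_per_residue = t208 / spectrum.n_residues
    if res.theta208_per_residue != 0:
        res.ratio_222_208, res.coil_class = coiled_coil_ratio(
            res.theta222_per_residue, res.theta208_per_residue)
    return res
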