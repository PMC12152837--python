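"""Closed-form SAXS models for micellar lipopeptide solutions.

Form factors
    homogeneous sphere, core–shell sphere (micelle: alkyl core + peptide
    shell), Gaussian chain (Debye; dilute oligomers behaving as polymer
    coils), and a low-q power law (mass-fractal-like aggregates).

Structure factors
    Percus–Yevick hard spheres (analytic) and the Hayter–Penfold
    rescaled-MSA model for charged spheres with screened-Coulomb
    repulsion (numerical OZ/MSA solve, see :mod:`micellekit.saxs.oz`).

Units: q in nm⁻¹, lengths in nm, electron densities in e Å⁻³,
absolute intensities in cm⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .._constants import E_A3_TO_E_NM3, bjerrum_length_nm
from ..datatypes import validate_qgrid
from .oz import OZSolution, RescaledMSACache, solve_rescaled_msa

__all__ = [
    "SphereParams", "CoreShellParams", "GaussianChainParams", "PowerLawParams",
    "HayterPenfoldParams", "CombinedModel",
    "sphere_form_factor", "core_shell_amplitude", "core_shell_form_factor",
    "gaussian_chain_intensity", "power_law_intensity",
    "hard_sphere_py_sf", "hayter_penfold_sf", "combined_intensity",
    "kappa_from_counterions",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SphereParams:
    """Homogeneous sphere: radius (nm) and contrast Δρ vs solvent (e Å⁻³)."""

    radius: float
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")


@dataclass
class CoreShellParams:
    """Core–shell sphere: inner (core) and outer radii with electron densities.

    ``core_radius`` < ``outer_radius``; densities in e Å⁻³ for the core
    (alkyl), shell (peptide) and solvent (water, 0.333).
    """

    core_radius: float
    outer_radius: float
    rho_core: float
    rho_shell: float
    rho_solvent: float = 0.333

    def __post_init__(self) -> None:
        if not 0 < self.core_radius < self.outer_radius:
            raise ValueError("require 0 < core_radius < outer_radius")


@dataclass
class GaussianChainParams:
    """Debye coil: radius of gyration (nm) and forward intensity i0 (cm⁻¹)."""

    rg: float
    i0: float

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise ValueError("rg must be > 0")
        if self.i0 < 0:
            raise ValueError("i0 must be >= 0")


@dataclass
class PowerLawParams:
    """I(q) = amplitude · q^(−alpha); amplitude in cm⁻¹·(nm⁻¹)^alpha."""

    amplitude: float
    alpha: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class HayterPenfoldParams:
    """Charged-sphere structure-factor parameters (rescaled MSA).

    Parameters
    ----------
    hs_radius : float
        Hard-sphere radius R_HS, nm.
    volume_fraction : float
        Hard-sphere volume fraction φ, 0 < φ < 0.74.
    z_eff : float
        Effective charge modulus per micelle, elementary charges.
    inv_screening_length : float, optional
        Debye screening κ, nm⁻¹.  When ``None`` it is computed from the
        monovalent counterion concentration implied by the micelle number
        density × z_eff (pure-water conditions, no added salt).
    temperature : float
        K; dielectric_const dimensionless (water at 298 K: 78.5).
    """

    hs_radius: float
    volume_fraction: float
    z_eff: float
    inv_screening_length: Optional[float] = None
    temperature: float = 298.0
    dielectric_const: float = 78.5

    def __post_init__(self) -> None:
        if self.hs_radius <= 0:
            raise ValueError("hs_radius must be > 0")
        if not 0 < self.volume_fraction < 0.74:
            raise ValueError("volume_fraction must be in (0, 0.74)")
        if self.z_eff < 0:
            raise ValueError("z_eff (charge modulus) must be >= 0")
        if self.inv_screening_length is not None and self.inv_screening_length < 0:
            raise ValueError("inv_screening_length must be >= 0")

    @property
    def number_density(self) -> float:
        """Micelle number density, nm⁻³."""
        return self.volume_fraction / (4.0 / 3.0 * math.pi * self.hs_radius**3)

    def kappa(self) -> float:
        """Screening κ (nm⁻¹): supplied value or counterion-derived default."""
        if self.inv_screening_length is not None:
            return self.inv_screening_length
        return kappa_from_counterions(
            self.number_density, self.z_eff,
            temperature=self.temperature, dielectric=self.dielectric_const,
        )


def kappa_from_counterions(number_density: float, z_eff: float, *,
                           temperature: float = 298.0,
                           dielectric: float = 78.5) -> float:
    """Debye κ (nm⁻¹) from monovalent counterions released by the micelles.

    κ² = 4π λ_B Σ ρ_i z_i² with ρ_counter = z_eff · ρ_micelle (salt-free
    water, the study's solution condition).
    """
    lam_b = bjerrum_length_nm(temperature, dielectric)
    rho_counter = number_density * z_eff
    return math.sqrt(4.0 * math.pi * lam_b * rho_counter)


_FORM_CHOICES = ("sphere", "core_shell", "gaussian_chain", "power_law")
_STRUCTURE_CHOICES = ("none", "hard_sphere_PY", "hayter_penfold")


@dataclass
class CombinedModel:
    """Model intensity I(q) = scale · P(q) · S(q) + background.

    ``combination_mode='decoupling'`` uses
    I = scale·P·[1 + β(q)(S−1)] + background; for the monodisperse
    particles handled here β ≡ 1, so the two modes coincide.
    """

    form: str
    structure: str = "none"
    scale: float = 1.0
    background: float = 0.0
    combination_mode: str = "product"

    def __post_init__(self) -> None:
        if self.form not in _FORM_CHOICES:
            raise ValueError(f"form must be one of {_FORM_CHOICES}")
        if self.structure not in _STRUCTURE_CHOICES:
            raise ValueError(f"structure must be one of {_STRUCTURE_CHOICES}")
        if self.combination_mode not in ("product", "decoupling"):
            raise ValueError("combination_mode must be 'product' or 'decoupling'")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.structure != "none" and self.form in ("gaussian_chain", "power_law"):
            raise ValueError(
                f"structure factor '{self.structure}' is unsupported with the "
                f"'{self.form}' form factor (no hard-core length scale)"
            )


# ---------------------------------------------------------------------------
# form factors
# ---------------------------------------------------------------------------

def _sphere_kernel(x: np.ndarray) -> np.ndarray:
    """f(x) = 3(sin x − x cos x)/x³ with a series guard for small x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    # 1 - x²/10 + x⁴/280
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def sphere_form_factor(q: np.ndarray, p: SphereParams) -> np.ndarray:
    """Normalized sphere form factor P(q) = f(qR)² ∈ [0, 1], P(0) = 1."""
    q = validate_qgrid(q)
    return _sphere_kernel(q * p.radius) ** 2


def core_shell_amplitude(q: np.ndarray, p: CoreShellParams) -> np.ndarray:
    """Scattering amplitude F(q) of a core–shell sphere, in electrons.

    F(q) = (4π/3)[(ρc−ρsh)R_i³ f(qR_i) + (ρsh−ρ0)R_o³ f(qR_o)], with
    densities converted e Å⁻³ → e nm⁻³ so F is an excess electron count.
    """
    q = validate_qgrid(q)
    d_core = (p.rho_core - p.rho_shell) * E_A3_TO_E_NM3
    d_shell = (p.rho_shell - p.rho_solvent) * E_A3_TO_E_NM3
    pref = 4.0 * math.pi / 3.0
    return pref * (d_core * p.core_radius**3 * _sphere_kernel(q * p.core_radius)
                   + d_shell * p.outer_radius**3 * _sphere_kernel(q * p.outer_radius))


def core_shell_form_factor(q: np.ndarray, p: CoreShellParams,
                           normalized: bool = True) -> np.ndarray:
    """Core–shell intensity |F(q)|²; normalized to 1 at q→0 by default."""
    amp = core_shell_amplitude(q, p)
    intensity = amp**2
    if not normalized:
        return intensity
    pref = 4.0 * math.pi / 3.0
    f0 = pref * ((p.rho_core - p.rho_shell) * E_A3_TO_E_NM3 * p.core_radius**3
                 + (p.rho_shell - p.rho_solvent) * E_A3_TO_E_NM3 * p.outer_radius**3)
    if f0 == 0.0:
        raise ZeroDivisionError("zero forward amplitude: cannot normalize")
    return intensity / f0**2


def gaussian_chain_intensity(q: np.ndarray, p: GaussianChainParams) -> np.ndarray:
    """Debye coil intensity I(q) = i0 · 2(e^(−x) + x − 1)/x², x = q²Rg²."""
    q = validate_qgrid(q)
    x = (q * p.rg) ** 2
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs**2 / 12.0
    xl = x[~small]
    out[~small] = 2.0 * (np.expm1(-xl) + xl) / xl**2
    return p.i0 * out


def power_law_intensity(q: np.ndarray, p: PowerLawParams) -> np.ndarray:
    """I(q) = amplitude · q^(−alpha) (mass-fractal-like low-q scattering)."""
    q = validate_qgrid(q)
    return p.amplitude * q ** (-p.alpha)


# ---------------------------------------------------------------------------
# structure factors
# ---------------------------------------------------------------------------

def hard_sphere_py_sf(q: np.ndarray, hs_radius: float, volume_fraction: float) -> np.ndarray:
    """Analytic Percus–Yevick hard-sphere structure factor.

    S(0) equals the PY isothermal-compressibility value
    (1−φ)⁴/(1+2φ)²; S(q) → 1 at large q.
    """
    q = validate_qgrid(q)
    if hs_radius <= 0:
        raise ValueError("hs_radius must be > 0")
    phi = volume_fraction
    if not 0 < phi < 0.74:
        raise ValueError("volume_fraction must be in (0, 0.74)")
    a = (1.0 + 2.0 * phi) ** 2 / (1.0 - phi) ** 4
    b = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / (1.0 - phi) ** 4
    cc = phi * a / 2.0

    A = q * 2.0 * hs_radius
    out = np.empty_like(A)
    small = A < 0.02
    # q→0 limit: 24φ ∫ x² c(x) dx = 24φ (a/3 + b/4 + c/6)
    out[small] = 1.0 / (1.0 + 24.0 * phi * (a / 3.0 + b / 4.0 + cc / 6.0))
    Al = A[~small]
    sinA, cosA = np.sin(Al), np.cos(Al)
    t1 = a * (sinA - Al * cosA) / Al**2
    t2 = b * (2.0 * Al * sinA + (2.0 - Al**2) * cosA - 2.0) / Al**3
    t3 = cc * (-(Al**4) * cosA
               + 4.0 * ((3.0 * Al**2 - 6.0) * cosA + (Al**3 - 6.0 * Al) * sinA + 6.0)) / Al**5
    out[~small] = 1.0 / (1.0 + 24.0 * phi * (t1 + t2 + t3) / Al)
    return out


def _hp_tail(p: HayterPenfoldParams):
    """βu(r) for the screened-Coulomb (DLVO/Yukawa) micelle repulsion."""
    lam_b = bjerrum_length_nm(p.temperature, p.dielectric_const)
    d = 2.0 * p.hs_radius
    kappa = p.kappa()
    if p.z_eff > 0 and kappa <= 0:
        raise ValueError(
            "unscreened Coulomb repulsion (kappa = 0 with z_eff > 0) has no "
            "MSA solution here; provide inv_screening_length > 0"
        )
    amp = p.z_eff**2 * lam_b / (1.0 + kappa * d / 2.0) ** 2

    def beta_u(r: np.ndarray) -> np.ndarray:
        return amp * np.exp(-kappa * (r - d)) / r

    return beta_u


def hayter_penfold_sf(q: np.ndarray, p: HayterPenfoldParams, *,
                      cache: Optional[RescaledMSACache] = None,
                      n_grid: int = 8192, tol: float = 1e-10,
                      s_tol: float = 1e-5,
                      return_solution: bool = False):
    """Charged-sphere structure factor: rescaled MSA (Hayter–Penfold type).

    Solves the OZ equation with the MSA closure for hard spheres with a
    screened-Coulomb tail; when the plain MSA gives g(d⁺) < 0 (the dilute
    charged regime) the Hansen–Hayter rescaling is applied.  At
    z_eff = 0 this reduces to the PY hard-sphere result.

    Parameters
    ----------
    cache : RescaledMSACache, optional
        Warm-start store for repeated nearby evaluations (model fitting).
    return_solution : bool
        Also return the full :class:`OZSolution`.
    """
    q = validate_qgrid(q)
    tail = _hp_tail(p) if p.z_eff > 0 else None
    sol = solve_rescaled_msa(2.0 * p.hs_radius, p.number_density, tail,
                             warm_start=cache, n_grid=n_grid, tol=tol,
                             s_tol=s_tol)
    s_q = sol.structure_factor(q)
    if return_solution:
        return s_q, sol
    return s_q


# ---------------------------------------------------------------------------
# combined model
# ---------------------------------------------------------------------------

def _form_intensity(q: np.ndarray, model: CombinedModel, form_params) -> np.ndarray:
    # sphere/core_shell are normalized shapes (scale carries the cm⁻¹ units);
    # gaussian_chain/power_law carry their own absolute amplitude
    if model.form == "sphere":
        return sphere_form_factor(q, form_params)
    if model.form == "core_shell":
        return core_shell_form_factor(q, form_params, normalized=True)
    if model.form == "gaussian_chain":
        return gaussian_chain_intensity(q, form_params)
    if model.form == "power_law":
        return power_law_intensity(q, form_params)
    raise ValueError(f"unknown form {model.form!r}")


def combined_intensity(q: np.ndarray, model: CombinedModel, form_params,
                       structure_params=None, *,
                       cache: Optional[RescaledMSACache] = None) -> np.ndarray:
    """Model intensity I(q) in cm⁻¹ for a form × structure combination.

    Product mode: I = scale·P(q)·S(q) + background.  Decoupling mode uses
    β(q) = |⟨F⟩|²/⟨|F|²⟩, which is identically 1 for the monodisperse
    particles supported here, so both modes agree.
    """
    q = validate_qgrid(q)
    pq = _form_intensity(q, model, form_params)
    if model.structure == "none":
        sq = np.ones_like(q)
    elif model.structure == "hard_sphere_PY":
        sq = hard_sphere_py_sf(q, structure_params.hs_radius,
                               structure_params.volume_fraction)
    elif model.structure == "hayter_penfold":
        sq = hayter_penfold_sf(q, structure_params, cache=cache)
    else:  # pragma: no cover - guarded by CombinedModel validation
        raise ValueError(f"unknown structure {model.structure!r}")

    if model.combination_mode == "decoupling":
        beta = 1.0  # monodisperse particles
        eff = 1.0 + beta * (sq - 1.0)
    else:
        eff = sq
    return model.scale * pq * eff + model.background
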