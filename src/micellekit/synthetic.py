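"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the study conditions of a lipopeptide
(semaglutide-like) self-assembly experiment in salt-free water:

* dilute-oligomer SAXS curves (Gaussian coils, forward intensity
  2.5×10⁻³ cm⁻¹ at 0.1 wt %),
* concentrated micellar curves (core–shell spheres × charged-sphere
  structure factor with an interference peak near q = 0.4–0.5 nm⁻¹),
* low-q power-law "fractal" curves (exponent ≈ 2.6),
* α-helix/coil CD spectra on the 180–400 nm range,
* packed spherical micelle (or dispersed trimer) coordinate sets,
* Nile-red-style CMC titrations with a breakpoint at 0.06 wt %.

Every generator is a deterministic function of (parameters, seed), and
each zero-noise output round-trips through its analysis stage to the
generating parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._constants import electrons_for, vdw_radius_for
from .cd import molar_ellipticity_to_mdeg, theoretical_helix_ellipticity
from .coords import fibonacci_sphere
from .datatypes import CDSpectrum, CoordinateSet, NoiseSpec, ScatteringCurve
from .mass import forward_intensity_from_mass
from .saxs.models import (
    CombinedModel,
    CoreShellParams,
    GaussianChainParams,
    HayterPenfoldParams,
    PowerLawParams,
    combined_intensity,
)

__all__ = [
    "make_saxs_curve", "make_cd_spectrum", "make_micelle_coordinates",
    "make_titration", "preset_curve", "PRESETS", "SEMAGLUTIDE_MOLAR_MASS",
]

#: Monomer molar mass used by the presets (g mol⁻¹).
SEMAGLUTIDE_MOLAR_MASS = 4113.6


# ---------------------------------------------------------------------------
# SAXS curves
# ---------------------------------------------------------------------------

def make_saxs_curve(model: CombinedModel, form_params, structure_params=None,
                    qgrid: Optional[np.ndarray] = None,
                    noise: Optional[NoiseSpec] = None,
                    concentration: Optional[float] = None,
                    label: str = "synthetic") -> ScatteringCurve:
    """Synthetic SAXS curve: model intensity with multiplicative Gaussian
    noise and an absolute floor.

    σ(q) = I_model·relative_sd + floor and I_obs = I_model + σ·ε with
    ε ~ N(0, 1) from the seeded generator.  At zero noise the σ column is
    a nominal 10⁻⁶ of the peak intensity so the curve stays weighted.
    """
    if qgrid is None:
        qgrid = np.geomspace(0.02, 5.0, 180)
    if noise is None:
        noise = NoiseSpec()
    ideal = combined_intensity(qgrid, model, form_params, structure_params)
    sigma = ideal * noise.relative_sd + noise.floor
    if noise.relative_sd == 0 and noise.floor == 0:
        observed = ideal.copy()
        sigma = np.full_like(ideal, 1e-6 * float(np.max(np.abs(ideal))))
    else:
        rng = np.random.default_rng(noise.seed)
        observed = ideal + sigma * rng.standard_normal(ideal.shape)
    return ScatteringCurve(q=qgrid, intensity=observed, sigma=sigma,
                           concentration=concentration, label=label)


@dataclass
class _Preset:
    model: CombinedModel
    form_params: object
    structure_params: object
    concentration: float
    qgrid: np.ndarray
    truth: dict = field(default_factory=dict)


def _micellar_preset(concentration: float, z_eff: float, hs_radius: float,
                     p_assoc: int = 30) -> _Preset:
    """Concentrated aged sample: core–shell micelles with charged-sphere
    interactions; absolute scale from the forward-scattering relation."""
    core = CoreShellParams(core_radius=1.5, outer_radius=hs_radius,
                           rho_core=0.29, rho_shell=0.40, rho_solvent=0.333)
    phi = concentration * 1.17  # dry volume fraction from v_p = 1.17 cm³/g
    hp = HayterPenfoldParams(hs_radius=hs_radius, volume_fraction=phi, z_eff=z_eff)
    scale = forward_intensity_from_mass(concentration, p_assoc * SEMAGLUTIDE_MOLAR_MASS,
                                        v_p=1.17, rho_l=0.291)
    model = CombinedModel(form="core_shell", structure="hayter_penfold",
                          scale=scale, background=1e-4)
    return _Preset(model=model, form_params=core, structure_params=hp,
                   concentration=concentration,
                   qgrid=np.geomspace(0.05, 5.0, 160),
                   truth={"z_eff": z_eff, "hs_radius": hs_radius,
                          "core_radius": 1.5, "volume_fraction": phi,
                          "scale": scale, "p": p_assoc})


def _dilute_preset() -> _Preset:
    """Aged 0.1 wt % solution: small oligomers as Gaussian coils with
    forward intensity 2.5×10⁻³ cm⁻¹."""
    gp = GaussianChainParams(rg=1.8, i0=0.0025)
    model = CombinedModel(form="gaussian_chain", structure="none", scale=1.0,
                          background=0.0)
    return _Preset(model=model, form_params=gp, structure_params=None,
                   concentration=0.001, qgrid=np.geomspace(0.02, 5.0, 180),
                   truth={"rg": 1.8, "i0": 0.0025})


def _fractal_preset() -> _Preset:
    """Fresh dilute solution: mass-fractal-like aggregates, I ∼ q^−2.6."""
    pp = PowerLawParams(amplitude=1e-4, alpha=2.6)
    model = CombinedModel(form="power_law", structure="none", scale=1.0,
                          background=0.0)
    return _Preset(model=model, form_params=pp, structure_params=None,
                   concentration=0.001, qgrid=np.geomspace(0.02, 2.0, 140),
                   truth={"alpha": 2.6, "amplitude": 1e-4})


PRESETS = {
    "aged_0.1wt": _dilute_preset,
    "aged_0.5wt": lambda: _micellar_preset(0.005, z_eff=9.81, hs_radius=2.3),
    "aged_1wt": lambda: _micellar_preset(0.01, z_eff=10.8, hs_radius=2.45),
    "fresh_0.1wt": _fractal_preset,
    "fractal_fresh": _fractal_preset,
}


def preset_curve(name: str, *, seed: int = 0, relative_sd: float = 0.02,
                 floor: float = 0.0):
    """Generate a named study-condition curve.

    Returns ``(curve, truth)`` where ``truth`` holds the generating
    parameter values.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    ps = PRESETS[name]()
    noise = NoiseSpec(relative_sd=relative_sd, floor=floor, seed=seed)
    curve = make_saxs_curve(ps.model, ps.form_params, ps.structure_params,
                            qgrid=ps.qgrid, noise=noise,
                            concentration=ps.concentration, label=name)
    return curve, dict(ps.truth)


# ---------------------------------------------------------------------------
# CD spectra
# ---------------------------------------------------------------------------

def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((wl - center) ** 2) / (2.0 * width**2))


def make_cd_spectrum(f_helix: float, n_residues: int = 31,
                     concentration: float = 1e-4, pathlength: float = 0.001,
                     noise_mdeg: float = 0.0, seed: int = 0,
                     wavelength: Optional[np.ndarray] = None) -> CDSpectrum:
    """Synthetic CD spectrum of a partially helical peptide, in mdeg.

    A linear combination of fixed helix (minima at 208/222 nm, maximum
    near 190 nm) and coil (minimum near 198 nm) per-residue band shapes,
    constructed so that the per-residue [θ]222 equals
    f_helix × [θ]222(theor); the helicity analysis therefore recovers
    ``f_helix`` exactly at zero noise.  Additive Gaussian noise of
    ``noise_mdeg`` (mdeg, 1σ) emulates instrument noise.

    Defaults: 0.1 mM peptide in a 0.01 mm cell, 180–400 nm.
    """
    if not 0.0 <= f_helix <= 1.0:
        raise ValueError("f_helix must lie in [0, 1]")
    if wavelength is None:
        wavelength = np.arange(180.0, 400.5, 0.5)
    wl = np.asarray(wavelength, float)
    theta_th = theoretical_helix_ellipticity(n_residues)

    helix = (theta_th * _gauss(wl, 222.0, 6.5)
             + 1.05 * theta_th * _gauss(wl, 208.0, 5.5)
             - 1.8 * theta_th * _gauss(wl, 190.0, 5.0))
    coil = (0.55 * theta_th * _gauss(wl, 198.0, 6.0)
            - 0.12 * theta_th * _gauss(wl, 218.0, 9.0))
    # pin the 222 nm values: helix → theta_th exactly, coil → 0 exactly
    bump = _gauss(wl, 222.0, 3.0)
    helix = helix + (theta_th - np.interp(222.0, wl, helix)) * bump
    coil = coil - np.interp(222.0, wl, coil) * bump

    per_residue = f_helix * helix + (1.0 - f_helix) * coil
    whole_molecule = per_residue * n_residues
    mdeg = molar_ellipticity_to_mdeg(whole_molecule, concentration, pathlength)
    if noise_mdeg > 0:
        rng = np.random.default_rng(seed)
        mdeg = mdeg + noise_mdeg * rng.standard_normal(mdeg.shape)
    return CDSpectrum(wavelength=wl, ellipticity=mdeg,
                      concentration=concentration, pathlength=pathlength,
                      n_residues=n_residues, label=f"synthetic f={f_helix}")


# ---------------------------------------------------------------------------
# micelle coordinates
# ---------------------------------------------------------------------------

def make_micelle_coordinates(p: int, core_radius: float = 1.5,
                             shell_thickness: float = 0.95,
                             chain_beads: int = 8, seed: int = 0,
                             arrangement: str = "micelle",
                             min_distance: float = 0.10,
                             max_retries: int = 200) -> CoordinateSet:
    """Bead-model micelle (or dispersed oligomer) coordinate set.

    ``arrangement='micelle'`` packs p chains radially: alkyl-tail beads
    (CH₂ pseudo-atoms) inside ``core_radius``, head beads (peptide-like
    C/N/O) in the shell.  ``arrangement='dispersed'`` scatters whole
    chains in a box several diameters wide (the trimer reference state,
    with tails exposed to solvent).  A minimum inter-bead distance is
    enforced by rejection; packing failure raises RuntimeError.
    """
    if p < 1:
        raise ValueError("association number p must be >= 1")
    if arrangement not in ("micelle", "dispersed"):
        raise ValueError("arrangement must be 'micelle' or 'dispersed'")
    rng = np.random.default_rng(seed)
    n_tail = max(chain_beads // 2, 1)
    n_head = chain_beads - n_tail
    tail_elements = ["CH2"] * n_tail
    head_elements = (["N", "C", "O"] * ((n_head + 2) // 3))[:n_head]
    elements = tail_elements + head_elements

    outer = core_radius + shell_thickness
    base_dirs = fibonacci_sphere(max(p, 2))[:p]

    # rigid chain template along +z: tail beads terminal-inward within the
    # core, head beads through the shell; identical geometry in both
    # arrangements so dispersed vs packed differ only by inter-chain burial
    r_tail = np.linspace(0.15 * core_radius, 0.90 * core_radius, n_tail)
    r_head = (np.linspace(core_radius + 0.10 * shell_thickness,
                          outer - 0.05 * shell_thickness, max(n_head, 1))[:n_head]
              if n_head else np.empty(0))
    template = np.zeros((chain_beads, 3))
    template[:, 2] = np.concatenate([r_tail, r_head])

    placed: list[np.ndarray] = []

    def ok(pts: np.ndarray) -> bool:
        if not placed:
            return True
        prev = np.vstack(placed)
        d2 = ((pts[:, None, :] - prev[None, :, :]) ** 2).sum(axis=2)
        return not (d2 < min_distance**2).any()

    def rotate_to(direction: np.ndarray) -> np.ndarray:
        # rotation taking +z onto `direction`
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, direction)
        s = np.linalg.norm(v)
        c = float(z @ direction)
        if s < 1e-12:
            return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        return np.eye(3) + vx + vx @ vx * ((1.0 - c) / s**2)

    for k in range(p):
        for _attempt in range(max_retries):
            if arrangement == "micelle":
                direction = base_dirs[k] + 0.10 * rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                pts = template @ rotate_to(direction).T
            else:
                box = 6.0 * outer * max(p, 4) ** (1.0 / 3.0)
                origin = rng.uniform(-box / 2, box / 2, size=3)
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                pts = template @ rotate_to(direction).T + origin
            if ok(pts):
                placed.append(pts)
                break
        else:
            raise RuntimeError(
                f"could not pack chain {k + 1}/{p} after {max_retries} retries")
    positions = np.vstack(placed)
    all_elements = np.array(elements * p, dtype=object)
    electrons = np.array([electrons_for(e) for e in all_elements], dtype=float)
    radii = np.array([vdw_radius_for(e) for e in all_elements], dtype=float)
    return CoordinateSet(positions=positions, elements=all_elements,
                         electrons=electrons, radii=radii,
                         label=f"synthetic {arrangement} p={p}")


# ---------------------------------------------------------------------------
# CMC titration
# ---------------------------------------------------------------------------

def make_titration(cmc: float = 0.06, n_points: int = 14,
                   relative_sd: float = 0.0, seed: int = 0,
                   conc_range: Optional[tuple] = None,
                   slope_below: float = 0.05, slope_above: float = 1.0,
                   baseline: float = 1.0):
    """Nile-red-style fluorescence titration with a breakpoint at the CMC.

    Concentrations (wt %) are log-spaced across ``conc_range`` (default
    one decade either side of the CMC); the response is two-segment
    linear in log₁₀(concentration) with slopes ``slope_below`` /
    ``slope_above``.  Noise is additive Gaussian with σ =
    ``relative_sd`` × (response range).  Returns ``(concentration,
    response)`` arrays.
    """
    if conc_range is None:
        conc_range = (cmc / 10.0, cmc * 10.0)
    lo, hi = conc_range
    if not lo < cmc < hi:
        raise ValueError("cmc must lie inside the generated concentration range")
    conc = np.geomspace(lo, hi, n_points)
    u = np.log10(conc)
    uc = math.log10(cmc)
    resp = baseline + slope_below * (u - uc) + (slope_above - slope_below) * np.clip(u - uc, 0.0, None)
    if relative_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + relative_sd * (resp.max() - resp.min()) * rng.standard_normal(resp.shape)
    return conc, resp
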