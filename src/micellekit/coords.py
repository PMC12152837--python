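"""Coordinate-based micelle profiling: radial electron density and SASA.

Post-processes micelle configurations (e.g. frames exported from
atomistic simulations): spherically averaged electron-density profiles
around the micelle center, Shrake–Rupley solvent-accessible surface
area on a deterministic Fibonacci point set, and the aggregation
propensity AP = SASA(initial)/SASA(final).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import CoordinateSet, DensityProfile

__all__ = [
    "radial_electron_density", "average_density_profile", "sasa",
    "aggregation_propensity", "fibonacci_sphere",
]

NM3_TO_A3 = 1.0e3  # 1 nm³ = 1000 Å³


def _center(cs: CoordinateSet, mode: str) -> np.ndarray:
    if mode == "center_of_mass":
        w = cs.electrons  # electron-weighted center: the scattering center
        return (cs.positions * w[:, None]).sum(axis=0) / w.sum()
    if mode == "geometric":
        return cs.positions.mean(axis=0)
    raise ValueError("center must be 'center_of_mass' or 'geometric'")


def radial_electron_density(cs: CoordinateSet, center: str = "center_of_mass",
                            bin_width: float = 0.05,
                            r_max: Optional[float] = None) -> DensityProfile:
    """Spherically averaged electron density around the micelle center.

    Electrons are summed per spherical shell and divided by the shell
    volume; densities are reported in e Å⁻³.  The profile conserves the
    total electron count: Σ density·V_shell = Σ electrons.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(cs) < 10:
        raise ValueError("need at least 10 atoms for a radial profile")
    c = _center(cs, center)
    r = np.linalg.norm(cs.positions - c, axis=1)
    if r_max is None:
        r_max = float(r.max()) + bin_width
    n_bins = max(int(np.ceil(r_max / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.clip((r / bin_width).astype(int), 0, n_bins - 1)
    electrons = np.bincount(idx, weights=cs.electrons, minlength=n_bins)
    shell_vol_nm3 = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    density = electrons / (shell_vol_nm3 * NM3_TO_A3)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return DensityProfile(bin_centers=centers, electron_density=density,
                          bin_width=bin_width)


def average_density_profile(frames: Iterable[CoordinateSet],
                            center: str = "center_of_mass",
                            bin_width: float = 0.05) -> DensityProfile:
    """Plain mean of per-frame radial profiles on a common grid."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames supplied")
    r_max = 0.0
    for cs in frames:
        c = _center(cs, center)
        r_max = max(r_max, float(np.linalg.norm(cs.positions - c, axis=1).max()))
    r_max += bin_width
    profiles = [radial_electron_density(cs, center, bin_width, r_max=r_max)
                for cs in frames]
    dens = np.mean([p.electron_density for p in profiles], axis=0)
    return DensityProfile(bin_centers=profiles[0].bin_centers,
                          electron_density=dens, bin_width=bin_width)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n_points, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _body_frame(cs: CoordinateSet) -> np.ndarray:
    """Right-handed principal-axes frame of the configuration.

    The sampling point set is expressed in this frame so that SASA is
    exactly covariant under rigid rotation/translation (a lab-fixed
    point set would leave a sampling residual of order 1/n_points).
    Axis signs are fixed by the third moment of the electron-weighted
    coordinates along each axis, which is itself rotation-covariant.
    """
    w = cs.electrons / cs.electrons.sum()
    centered = cs.positions - (cs.positions * w[:, None]).sum(axis=0)
    cov = (w[:, None, None] * centered[:, :, None] * centered[:, None, :]).sum(axis=0)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs.T[::-1].copy()  # descending variance
    for k in range(2):
        m3 = float((w * (centered @ axes[k]) ** 3).sum())
        if m3 < 0:
            axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def sasa(cs: CoordinateSet, probe_radius: float = 0.14, n_points: int = 960):
    """Shrake–Rupley solvent-accessible surface area, nm².

    Each atom's extended sphere (r_vdw + probe) is sampled with a
    deterministic Fibonacci point set oriented along the configuration's
    principal axes; points buried inside any neighbour's extended sphere
    are discarded.  Returns ``(total_area, per_atom_areas)``.
    """
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    sphere = fibonacci_sphere(n_points) @ _body_frame(cs)
    ext = cs.radii + probe_radius
    tree = cKDTree(cs.positions)
    max_ext = float(ext.max())
    per_atom = np.zeros(len(cs))
    for i in range(len(cs)):
        pts = cs.positions[i] + ext[i] * sphere
        neighbors = [j for j in tree.query_ball_point(cs.positions[i], ext[i] + max_ext)
                     if j != i]
        if neighbors:
            centers = cs.positions[neighbors]
            rads = ext[neighbors]
            d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (rads**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return float(per_atom.sum()), per_atom


def aggregation_propensity(initial: CoordinateSet, final: CoordinateSet,
                           probe_radius: float = 0.14, n_points: int = 960) -> float:
    """AP = SASA(initial)/SASA(final); AP > 1 indicates compaction."""
    area_i, _ = sasa(initial, probe_radius, n_points)
    area_f, _ = sasa(final, probe_radius, n_points)
    if area_f <= 0:
        raise ZeroDivisionError("final configuration has zero accessible area")
    return float(area_i / area_f)
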