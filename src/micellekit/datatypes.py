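"""Core data containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def validate_qgrid(q: np.ndarray) -> np.ndarray:
    """Validate a scattering-wavenumber grid (nm⁻¹).

    Must be 1-D, finite, strictly positive and strictly increasing.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q grid must be a non-empty 1-D array")
    if not np.all(np.isfinite(q)):
        raise ValueError("q grid contains non-finite values")
    if np.any(q <= 0):
        raise ValueError("q grid values must be > 0")
    if np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing (no duplicates)")
    return q


@dataclass
class ScatteringCurve:
    """A measured or synthetic SAXS profile on absolute scale.

    Parameters
    ----------
    q : array
        Scattering wavenumber, nm⁻¹, strictly increasing.
    intensity : array
        Scattered intensity, cm⁻¹.
    sigma : array, optional
        1-σ uncertainties, cm⁻¹, strictly positive where present.
    concentration : float, optional
        Sample mass concentration, g cm⁻³.
    label : str
        Free-text sample label.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    concentration: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = validate_qgrid(self.q)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity must have equal length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma values must be > 0 where present")

    def __len__(self) -> int:
        return self.q.size

    @property
    def weighted(self) -> bool:
        return self.sigma is not None


@dataclass
class FitResult:
    """Outcome of a weighted nonlinear SAXS model fit."""

    best_params: dict
    param_uncertainties: dict
    chi2_reduced: float
    n_points: int
    converged: bool
    model_id: str
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and self.chi2_reduced < 0:
            raise ValueError("chi2_reduced must be >= 0")


@dataclass
class BreakpointResult:
    """Two-segment piecewise-linear breakpoint estimate (e.g. a CMC)."""

    breakpoint: float
    slope_left: float
    slope_right: float
    breakpoint_uncertainty: float
    significant: bool
    p_value: float = float("nan")


@dataclass
class CDSpectrum:
    """A circular-dichroism spectrum in raw machine units (mdeg).

    ``concentration`` is the whole-molecule molar concentration (mol L⁻¹)
    and ``pathlength`` the cell path length in cm; both are needed to
    normalize to molar ellipticity.
    """

    wavelength: np.ndarray
    ellipticity: np.ndarray
    concentration: Optional[float] = None
    pathlength: Optional[float] = None
    n_residues: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelength.shape != self.ellipticity.shape:
            raise ValueError("wavelength and ellipticity must have equal length")
        if self.pathlength is not None and self.pathlength <= 0:
            raise ValueError("pathlength must be > 0")
        if self.n_residues is not None and self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")


@dataclass
class HelicityResult:
    """Derived per-residue CD quantities and the α-helix fraction."""

    theta222_per_residue: float
    theta222_theor: float
    f_a: float
    theta208_per_residue: float = float("nan")
    ratio_222_208: float = float("nan")
    coil_class: str = ""
    clipped: bool = False


@dataclass
class CoordinateSet:
    """Atomic coordinates with element-derived electron counts and radii.

    positions are in nm; electrons per atom; radii are van der Waals
    radii in nm.
    """

    positions: np.ndarray
    elements: np.ndarray
    electrons: np.ndarray
    radii: np.ndarray
    frame_id: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        n = self.positions.shape[0]
        self.elements = np.asarray(self.elements, dtype=object)
        self.electrons = np.asarray(self.electrons, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        for name, arr in (("elements", self.elements), ("electrons", self.electrons),
                          ("radii", self.radii)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} must match positions in length")
        if np.any(self.electrons < 1):
            raise ValueError("electron counts must be >= 1")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be > 0")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class DensityProfile:
    """Radial electron-density profile around a micelle center."""

    bin_centers: np.ndarray
    electron_density: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.electron_density = np.asarray(self.electron_density, dtype=float)
        if self.bin_centers.shape != self.electron_density.shape:
            raise ValueError("bin_centers and electron_density must match")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


@dataclass
class NoiseSpec:
    """Multiplicative Gaussian noise with an absolute floor, for generators."""

    relative_sd: float = 0.0
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
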