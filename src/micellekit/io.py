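"""File readers and writers: SAXS ASCII, CD CSV, and coordinate files.

Conventions
-----------
* SAXS ASCII: whitespace-delimited columns ``q I [sigma]``, comment and
  header lines start with ``#``; header metadata as ``# key = value``
  (recognized keys: ``units`` (``nm^-1`` or ``A^-1``), ``concentration``
  (g cm⁻³), ``label``).  Internal q units are nm⁻¹; Å⁻¹ input is
  converted (×10) at this boundary.
* CD CSV: two columns ``wavelength_nm, ellipticity_mdeg`` with a ``#``
  header block carrying ``concentration`` (mol L⁻¹), ``pathlength``
  (cm) and ``n_residues``.
* Coordinates: PDB or GRO, read through MDAnalysis; positions are
  converted to nm, electron counts and van der Waals radii derived from
  element symbols (united-atom CHn names are recognized).
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import List, Optional, Union

import numpy as np

from ._constants import (
    ATOMIC_NUMBER,
    UNITED_ATOM_ELECTRONS,
    electrons_for,
    normalize_element,
    vdw_radius_for,
)
from .datatypes import CDSpectrum, CoordinateSet, ScatteringCurve

__all__ = [
    "read_saxs_ascii", "write_saxs_ascii", "read_cd_csv", "write_cd_csv",
    "read_coordinates", "write_pdb",
]

_Q_UNITS = ("nm^-1", "A^-1")


def _parse_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*([\w.\-]+)\s*[:=]\s*(.+?)\s*$", line)
            if m:
                meta[m.group(1).lower()] = m.group(2)
    return meta


def read_saxs_ascii(path, units: Optional[str] = None) -> ScatteringCurve:
    """Read a SAXS curve; see the module docstring for the format.

    ``units`` overrides the header's q-unit declaration; default nm⁻¹.
    """
    path = Path(path)
    meta = _parse_header(path)
    units = units or meta.get("units", "nm^-1")
    if units not in _Q_UNITS:
        raise ValueError(f"units must be one of {_Q_UNITS}")
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"unparseable SAXS ASCII file {path}: {exc}") from exc
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 numeric columns (q, I)")
    q = data[:, 0]
    if units == "A^-1":
        q = q * 10.0
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: q column must be strictly increasing")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    conc = float(meta["concentration"]) if "concentration" in meta else None
    curve = ScatteringCurve(q=q, intensity=data[:, 1], sigma=sigma,
                            concentration=conc, label=meta.get("label", path.stem))
    if sigma is None:
        warnings.warn(f"{path.name}: no sigma column; curve will be fitted unweighted",
                      stacklevel=2)
    return curve


def write_saxs_ascii(curve: ScatteringCurve, path, units: str = "nm^-1") -> None:
    """Write a curve in the 3-column (or 2-column) ASCII format."""
    if units not in _Q_UNITS:
        raise ValueError(f"units must be one of {_Q_UNITS}")
    q = curve.q / 10.0 if units == "A^-1" else curve.q
    cols = [q, curve.intensity] + ([curve.sigma] if curve.sigma is not None else [])
    header = [f"units = {units}"]
    if curve.concentration is not None:
        header.append(f"concentration = {curve.concentration!r}")
    if curve.label:
        header.append(f"label = {curve.label}")
    header.append("columns = q intensity" + (" sigma" if curve.sigma is not None else ""))
    np.savetxt(path, np.column_stack(cols), header="\n".join(header),
               fmt="%.10e")


def read_cd_csv(path) -> CDSpectrum:
    """Read a CD spectrum CSV with a ``#`` metadata header block."""
    path = Path(path)
    meta = _parse_header(path)
    data = np.loadtxt(path, comments="#", delimiter=",", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need 2 columns (wavelength, ellipticity)")
    return CDSpectrum(
        wavelength=data[:, 0], ellipticity=data[:, 1],
        concentration=float(meta["concentration"]) if "concentration" in meta else None,
        pathlength=float(meta["pathlength"]) if "pathlength" in meta else None,
        n_residues=int(meta["n_residues"]) if "n_residues" in meta else None,
        label=meta.get("label", path.stem),
    )


def write_cd_csv(spectrum: CDSpectrum, path) -> None:
    header = []
    if spectrum.concentration is not None:
        header.append(f"concentration = {spectrum.concentration!r}")
    if spectrum.pathlength is not None:
        header.append(f"pathlength = {spectrum.pathlength!r}")
    if spectrum.n_residues is not None:
        header.append(f"n_residues = {spectrum.n_residues}")
    if spectrum.label:
        header.append(f"label = {spectrum.label}")
    header.append("columns = wavelength_nm, ellipticity_mdeg")
    np.savetxt(path, np.column_stack([spectrum.wavelength, spectrum.ellipticity]),
               delimiter=",", header="\n".join(header), fmt="%.6f,%.8e")


def _element_from_name(name: str) -> str:
    """Element from a PDB/GRO atom name: CHn united atoms recognized,
    otherwise leading letters with digits stripped, mapped to a known symbol."""
    raw = normalize_element(name)
    if raw in UNITED_ATOM_ELECTRONS:
        return raw
    letters = re.sub(r"[^A-Z]", "", raw)
    if not letters:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if letters[:2] in ATOMIC_NUMBER and letters[:2] not in ("CA", "CD", "CB", "NE", "ND"):
        # two-letter symbols accepted unless they collide with common
        # protein atom-name prefixes (CA = C-alpha, not calcium, etc.)
        return letters[:2]
    if letters[0] in ATOMIC_NUMBER:
        return letters[0]
    raise ValueError(f"cannot infer element from atom name {name!r}")


def read_coordinates(path, frame: Optional[int] = None
                     ) -> Union[CoordinateSet, List[CoordinateSet]]:
    """Read a PDB or GRO coordinate file into :class:`CoordinateSet`\\ s.

    Positions are converted to nm.  Velocities in GRO files are ignored.
    Returns a single set for single-frame files (or when ``frame`` is
    given), else a list over frames.
    """
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element/mass guessing chatter
        universe = mda.Universe(str(path))
    atoms = universe.atoms
    try:
        symbols = [str(e) for e in atoms.elements]
        if any(not s.strip() for s in symbols):
            raise AttributeError
    except Exception:
        symbols = [_element_from_name(n) for n in atoms.names]
    symbols = [normalize_element(s) for s in symbols]
    try:
        names = [normalize_element(n) for n in atoms.names]
    except Exception:
        names = symbols
    # united-atom pseudo-atoms keep their CHn identity even when the file
    # carries an element column (which can only say carbon)
    symbols = [n if n in UNITED_ATOM_ELECTRONS else s
               for n, s in zip(names, symbols)]
    try:
        electrons = np.array([electrons_for(s) for s in symbols], float)
        radii = np.array([vdw_radius_for(s) for s in symbols], float)
    except KeyError as exc:
        raise ValueError(f"{path}: {exc}") from exc

    frames = []
    for i, _ts in enumerate(universe.trajectory):
        frames.append(CoordinateSet(
            positions=atoms.positions / 10.0,  # Å → nm
            elements=np.array(symbols, dtype=object),
            electrons=electrons.copy(), radii=radii.copy(),
            frame_id=i, label=path.stem,
        ))
    if frame is not None:
        return frames[frame]
    return frames[0] if len(frames) == 1 else frames


def write_pdb(cs: CoordinateSet, path) -> None:
    """Write a coordinate set as a minimal PDB file (positions nm → Å).

    United-atom CHn beads keep their pseudo-atom name with element C.
    """
    with open(path, "w") as fh:
        fh.write(f"REMARK   {cs.label or 'micellekit coordinate set'}\n")
        for i, (pos, el) in enumerate(zip(cs.positions, cs.elements), start=1):
            name = str(el)[:4]
            element = "C" if name.startswith("CH") else str(el).capitalize()[:2]
            x, y, z = pos * 10.0
            fh.write(
                f"HETATM{i:>5d} {name:<4s} MOL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n"
            )
        fh.write("END\n")
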