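"""File input/output: 3-column scattering profiles and PDB bead models.

Profiles are whitespace-separated text with columns (S, I, sigma); lines
starting with ``#`` are comments and extra columns are ignored — the common
beamline-reduction dialect.  Bead models are written as PDB ATOM records
with residue name ``DUM`` on chain A; a stored two-fold symmetry axis goes
into a ``REMARK 290 SAXSKIT C2`` line so that round-trips preserve it.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from .types import BeadModel, C2Symmetry, ScatteringProfile

logger = logging.getLogger("saxskit")

__all__ = ["read_profile", "write_profile", "read_bead_model", "write_bead_model"]


def read_profile(
    path,
    concentration: float = 0.0,
    label: str = "",
    wavelength: Optional[float] = None,
) -> ScatteringProfile:
    """Read a (S, I, sigma) text profile.

    Rows with non-positive S or sigma are dropped (count logged); the
    remaining S values must be strictly increasing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    dropped = 0
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            dropped += 1
            continue
        try:
            s, i, e = (float(p) for p in parts[:3])
        except ValueError:
            dropped += 1
            continue
        if s <= 0 or e <= 0:
            dropped += 1
            continue
        rows.append((s, i, e))
    if dropped:
        logger.info("read_profile(%s): dropped %d unusable rows", path, dropped)
    if len(rows) < 2:
        raise ValueError(f"{path}: no usable data (fewer than 2 valid rows)")
    arr = np.array(rows, dtype=float)
    return ScatteringProfile(
        s_grid=arr[:, 0],
        intensity=arr[:, 1],
        sigma=arr[:, 2],
        concentration=concentration,
        wavelength=wavelength,
        label=label or path.stem,
    )


def write_profile(profile: ScatteringProfile, path) -> None:
    """Write a profile as 3-column text with a small comment header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# concentration_mg_ml = {profile.concentration}\n")
        if profile.label:
            fh.write(f"# label = {profile.label}\n")
        fh.write("# S(1/A)  I  sigma\n")
        for s, i, e in zip(profile.s_grid, profile.intensity, profile.sigma):
            fh.write(f"{s:.8e} {i:.8e} {e:.8e}\n")


def write_bead_model(model: BeadModel, path) -> None:
    """Write a bead model as a PDB file, one DUM pseudo-residue per bead."""
    path = Path(path)
    lines = []
    lines.append(f"REMARK 265 SAXSKIT BEAD DIAMETER {model.bead_diameter:.3f}")
    if model.symmetry is not None:
        a, p = model.symmetry.axis, model.symmetry.point
        lines.append(
            "REMARK 290 SAXSKIT C2 "
            f"{a[0]:.6f} {a[1]:.6f} {a[2]:.6f} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}"
        )
    for k, (x, y, z) in enumerate(model.coords, start=1):
        serial = k % 100000
        resseq = k % 10000
        lines.append(
            f"ATOM  {serial:5d}  CA  DUM A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_bead_model(path, bead_diameter: Optional[float] = None) -> BeadModel:
    """Read a bead model (or any PDB coordinate file, one bead per atom).

    The diameter defaults to 3.8 A unless a SAXSKIT remark in the file or
    the ``bead_diameter`` argument overrides it.  A crystal-structure PDB is
    accepted as-is, which is how reference profiles from known structures
    are computed.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    diameter = bead_diameter
    symmetry = None
    for line in text.splitlines():
        if line.startswith("REMARK 265 SAXSKIT BEAD DIAMETER") and diameter is None:
            diameter = float(line.split()[-1])
        elif line.startswith("REMARK 290 SAXSKIT C2"):
            vals = [float(t) for t in line.split()[4:10]]
            symmetry = C2Symmetry(axis=vals[:3], point=vals[3:])
    pdb_file = pdb.PDBFile.read(_io.StringIO(text))
    try:
        structure = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises on empty coordinate sets
        raise ValueError(f"{path}: no atom records") from exc
    if structure.array_length() == 0:
        raise ValueError(f"{path}: no atom records")
    return BeadModel(
        structure.coord,
        bead_diameter=diameter if diameter is not None else 3.8,
        symmetry=symmetry,
    )
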