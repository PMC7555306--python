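"""Core containers for 1-D scattering curves and bead models.

Conventions
-----------
The scattering-vector length used throughout is ``S = 2 sin(theta) / lambda``
in inverse Angstrom, where ``2 theta`` is the scattering angle.  The other
common convention, ``q = 4 pi sin(theta) / lambda``, relates to it by
``q = 2 pi S``; :func:`s_to_q` and :func:`q_to_s` convert between the two.
Getting this factor wrong is the classic SAXS unit bug, hence the explicit
helpers.  All lengths are Angstrom, all concentrations mg/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "ScatteringProfile",
    "BeadModel",
    "C2Symmetry",
    "s_to_q",
    "q_to_s",
]


def s_to_q(s):
    """Convert S = 2 sin(theta)/lambda to q = 4 pi sin(theta)/lambda."""
    return np.asarray(s, dtype=float) * TWO_PI


def q_to_s(q):
    """Convert q = 4 pi sin(theta)/lambda to S = 2 sin(theta)/lambda."""
    return np.asarray(q, dtype=float) / TWO_PI


@dataclass(frozen=True)
class ScatteringProfile:
    """One measured or simulated solution-scattering curve.

    Parameters
    ----------
    s_grid : array
        Scattering-vector lengths S (1/A), strictly increasing, all > 0.
    intensity : array
        I(S, C) in arbitrary units, same length as ``s_grid``.
    sigma : array
        Per-point standard error of the intensity.  Non-negative; exactly
        zero is allowed for ideal (noise-free) model curves, but operations
        that weight by errors will refuse or substitute documented
        effective weights.
    concentration : float
        Protein concentration C in mg/mL (>= 0; 0 denotes an
        infinite-dilution extrapolated curve).
    wavelength : float, optional
        X-ray wavelength lambda in Angstrom (metadata only).
    label : str
        Free text, e.g. ``"dark"`` or ``"light"``.
    """

    s_grid: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    concentration: float = 0.0
    wavelength: Optional[float] = None
    label: str = ""

    def __post_init__(self):
        s = np.asarray(self.s_grid, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        e = np.asarray(self.sigma, dtype=float)
        if s.ndim != 1 or len(s) != len(i) or len(s) != len(e):
            raise ValueError("s_grid, intensity and sigma must be 1-D and equally long")
        if len(s) < 2:
            raise ValueError("profile needs at least 2 points")
        if np.any(s <= 0):
            raise ValueError("all S values must be positive")
        if np.any(np.diff(s) <= 0):
            raise ValueError("S grid must be strictly increasing")
        if np.any(e < 0):
            raise ValueError("sigma must be non-negative")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        object.__setattr__(self, "s_grid", s)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", e)

    def __len__(self) -> int:
        return len(self.s_grid)

    @property
    def q_grid(self) -> np.ndarray:
        """The same grid in the q = 2 pi S convention."""
        return s_to_q(self.s_grid)

    def with_(self, **kwargs) -> "ScatteringProfile":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class C2Symmetry:
    """A two-fold rotation axis, stored as a unit direction through a point."""

    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("C2 axis must be a non-zero vector")
        object.__setattr__(self, "axis", a / n)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Rotate coordinates by 180 degrees about the axis."""
        x = np.asarray(coords, dtype=float) - self.point
        a = self.axis
        # Rodrigues at 180 deg: R v = 2 (a.v) a - v
        return 2.0 * np.outer(x @ a, a) - x + self.point


class BeadModel:
    """An assembly of identical spheres ("dummy residues").

    Each bead carries a single scattering amplitude at zero angle
    (``form_factor``, default 1), so the model's forward scattering is
    ``(sum f)**2``.  The default diameter of 3.8 A matches the spacing of
    consecutive C-alpha atoms in a polypeptide, the standard building block
    of low-resolution ab initio models.
    """

    __slots__ = ("coords", "bead_diameter", "form_factor", "symmetry")

    def __init__(
        self,
        coords,
        bead_diameter: float = 3.8,
        form_factor=1.0,
        symmetry: Optional[C2Symmetry] = None,
    ):
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must be an (n, 3) array with n >= 1")
        if bead_diameter <= 0:
            raise ValueError("bead_diameter must be positive")
        f = np.broadcast_to(np.asarray(form_factor, dtype=float), (coords.shape[0],)).copy()
        self.coords = coords
        self.bead_diameter = float(bead_diameter)
        self.form_factor = f
        self.symmetry = symmetry
        if symmetry is not None and not self.satisfies_c2(1e-6):
            raise ValueError("coordinates do not map onto themselves under the stored C2 axis")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def center_of_mass(self) -> np.ndarray:
        w = self.form_factor
        return (self.coords * w[:, None]).sum(axis=0) / w.sum()

    def radius_of_gyration(self) -> float:
        """Coordinate-moment Rg: rms distance of beads from the centroid."""
        c = self.coords - self.center_of_mass()
        w = self.form_factor / self.form_factor.sum()
        return float(np.sqrt((w * (c**2).sum(axis=1)).sum()))

    def max_extent(self) -> float:
        """Largest pairwise bead-center distance (Dmax of the centers)."""
        from scipy.spatial.distance import pdist

        if len(self) < 2:
            return 0.0
        return float(pdist(self.coords).max())

    def satisfies_c2(self, tol: float = 1e-6) -> bool:
        """True if the bead set maps onto itself under the stored axis."""
        if self.symmetry is None:
            return False
        from scipy.spatial import cKDTree

        mapped = self.symmetry.apply(self.coords)
        d, _ = cKDTree(self.coords).query(mapped)
        return bool(np.all(d <= tol))

    def transformed(self, rotation: np.ndarray = None, translation=None) -> "BeadModel":
        """Rigidly moved copy (symmetry annotation is dropped)."""
        c = self.coords
        if rotation is not None:
            c = c @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            c = c + np.asarray(translation, dtype=float)
        return BeadModel(c, self.bead_diameter, self.form_factor.copy())

    def __repr__(self) -> str:
        sym = "C2" if self.symmetry is not None else "none"
        return (
            f"BeadModel(n={len(self)}, diameter={self.bead_diameter:.2f} A, "
            f"symmetry={sym})"
        )
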