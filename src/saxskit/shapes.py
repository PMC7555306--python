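"""Synthetic bead-shape generator.

Produces bead models that emulate the specimen geometries of a
multidomain-photoreceptor SAXS study: single globular domains (spheres,
ellipsoids), elongated rods, tandem chains of domain blobs (a multidomain
monomer), and two-fold symmetric dimers of such chains.  A rigid hinge
bend of the distal half of a chain emulates a light-activated
conformational change between a straight ("dark") and bent ("light")
state.

Beads are placed on a jittered cubic grid filling the requested envelope;
the grid pitch is chosen so that roughly the requested number of grid
points falls inside, and the set is then subsampled to exactly
``n_beads``.  The same spec and seed always give the same coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .types import BeadModel, C2Symmetry

__all__ = ["ShapeSpec", "generate_shape"]


@dataclass(frozen=True)
class ShapeSpec:
    """Geometric description of a synthetic specimen.

    kind:
        'sphere' (radius), 'ellipsoid' (semi_axes), 'rod' (radius, length,
        axis x), 'tandem' (chain of overlapping spherical domains with
        radii ``domain_radii`` along x), or 'c2_dimer' (two tandem arms
        related by a two-fold axis along z).
    hinge_angle:
        Degrees; 0 = straight.  For 'tandem' the distal half of the chain
        is rotated rigidly about the junction; for 'c2_dimer' the same
        bend is applied to each arm (the symmetry is preserved exactly).
    """

    kind: str
    n_beads: int = 500
    radius: float = 30.0
    length: float = 100.0
    semi_axes: Tuple[float, float, float] = (40.0, 25.0, 25.0)
    domain_radii: Sequence[float] = (16.0, 16.0, 14.0, 18.0)
    arm_offset: float = 10.0
    hinge_angle: float = 0.0
    bead_diameter: float = 3.8
    overlap: float = 0.8  # center spacing of adjacent domains as a fraction of r_i + r_j

    def __post_init__(self):
        if self.kind not in ("sphere", "ellipsoid", "rod", "tandem", "c2_dimer"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if not (0.0 <= self.hinge_angle <= 90.0):
            raise ValueError("hinge_angle must be in [0, 90] degrees")
        r_bead = self.bead_diameter / 2.0
        dims = {
            "sphere": (self.radius,),
            "ellipsoid": self.semi_axes,
            "rod": (self.radius, self.length / 2.0),
            "tandem": tuple(self.domain_radii),
            "c2_dimer": tuple(self.domain_radii),
        }[self.kind]
        if min(dims) < r_bead:
            raise ValueError("shape dimensions smaller than the bead radius are impossible")


def _domain_centers(radii: Sequence[float], overlap: float, x0: float = 0.0) -> np.ndarray:
    centers = [np.array([x0, 0.0, 0.0])]
    for r_prev, r in zip(radii[:-1], radii[1:]):
        step = overlap * (r_prev + r)
        centers.append(centers[-1] + np.array([step, 0.0, 0.0]))
    return np.array(centers)


def _envelope(spec: ShapeSpec):
    """Return (inside(points) -> bool mask, bounding box, approx volume)."""
    if spec.kind == "sphere":
        r = spec.radius
        lo, hi = np.full(3, -r), np.full(3, r)
        vol = 4.0 / 3.0 * math.pi * r**3
        return (lambda p: (p**2).sum(axis=1) <= r**2), (lo, hi), vol
    if spec.kind == "ellipsoid":
        a = np.asarray(spec.semi_axes, dtype=float)
        lo, hi = -a, a
        vol = 4.0 / 3.0 * math.pi * a.prod()
        return (lambda p: ((p / a) ** 2).sum(axis=1) <= 1.0), (lo, hi), vol
    if spec.kind == "rod":
        r, h = spec.radius, spec.length / 2.0
        lo = np.array([-h, -r, -r])
        hi = np.array([h, r, r])
        vol = math.pi * r**2 * spec.length
        return (
            lambda p: (np.abs(p[:, 0]) <= h) & ((p[:, 1:] ** 2).sum(axis=1) <= r**2),
            (lo, hi),
            vol,
        )
    # tandem chain of spherical domains (also one arm of the dimer)
    radii = np.asarray(spec.domain_radii, dtype=float)
    centers = _domain_centers(radii, spec.overlap)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    vol = (4.0 / 3.0 * math.pi * radii**3).sum()

    def inside(p):
        ok = np.zeros(len(p), dtype=bool)
        for c, r in zip(centers, radii):
            ok |= ((p - c) ** 2).sum(axis=1) <= r**2
        return ok

    return inside, (lo, hi), vol


_JITTER = 0.02  # fraction of the grid pitch; keeps the lattice quasi-stratified


def _fill(spec: ShapeSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Fill the envelope with ~n beads on a lightly jittered cubic grid.

    The pitch is calibrated so the inside-count lands within a few percent
    of the target; all inside points are kept (no random subsampling,
    which would break the stratification that makes the model's scattering
    track the continuum envelope closely).
    """
    inside, (lo, hi), vol = _envelope(spec)
    pitch = (vol / n) ** (1.0 / 3.0)
    pts = None
    for _ in range(8):
        axes = [np.arange(l + pitch / 2.0, h, pitch) for l, h in zip(lo, hi)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        jitter = rng.uniform(-_JITTER * pitch, _JITTER * pitch, size=grid.shape)
        cand = grid + jitter
        cand = cand[inside(cand)]
        if len(cand) == 0:
            pitch *= 0.6
            continue
        pts = cand
        ratio = len(cand) / n
        if 0.98 <= ratio <= 1.02:
            break
        pitch *= ratio ** (1.0 / 3.0)
    if pts is None or len(pts) < max(1, n // 2):
        raise ValueError("could not place the requested number of beads in the envelope")
    return pts


def _analytic_rg(spec: ShapeSpec):
    """Continuum Rg of the envelope, where a closed form exists."""
    if spec.kind == "sphere":
        return math.sqrt(3.0 / 5.0) * spec.radius
    if spec.kind == "ellipsoid":
        a, b, c = spec.semi_axes
        return math.sqrt((a**2 + b**2 + c**2) / 5.0)
    if spec.kind == "rod":
        return math.sqrt(spec.radius**2 / 2.0 + spec.length**2 / 12.0)
    return None


def _apply_hinge(coords: np.ndarray, spec: ShapeSpec) -> np.ndarray:
    """Rigidly rotate the distal half of a tandem chain about its junction.

    The rotation is about the y axis through the hinge point, so every
    intra-segment pairwise distance is preserved exactly.
    """
    if spec.hinge_angle == 0.0:
        return coords
    radii = np.asarray(spec.domain_radii, dtype=float)
    centers = _domain_centers(radii, spec.overlap)
    m = len(radii) // 2
    hinge_x = 0.5 * (centers[m - 1, 0] + centers[m, 0])
    theta = math.radians(spec.hinge_angle)
    rot = np.array(
        [
            [math.cos(theta), 0.0, math.sin(theta)],
            [0.0, 1.0, 0.0],
            [-math.sin(theta), 0.0, math.cos(theta)],
        ]
    )
    out = coords.copy()
    distal = coords[:, 0] > hinge_x
    pivot = np.array([hinge_x, 0.0, 0.0])
    out[distal] = (coords[distal] - pivot) @ rot.T + pivot
    return out


def generate_shape(spec: ShapeSpec, seed: int = 0) -> BeadModel:
    """Generate a bead model for the given shape specification.

    For 'c2_dimer' the first arm is filled and bent, then the second arm is
    produced by rotating the first by 180 degrees about the z axis, so the
    returned model satisfies its C2 invariant to machine precision.
    """
    rng = np.random.default_rng(seed)
    if spec.kind == "c2_dimer":
        if len(spec.domain_radii) < 2:
            raise ValueError("a dimer arm needs at least 2 domains")
        n_arm = max(spec.n_beads // 2, 1)
        arm_spec = ShapeSpec(
            kind="tandem",
            n_beads=n_arm,
            domain_radii=spec.domain_radii,
            overlap=spec.overlap,
            hinge_angle=spec.hinge_angle,
            bead_diameter=spec.bead_diameter,
        )
        arm = _apply_hinge(_fill(arm_spec, n_arm, rng), arm_spec)
        arm = arm + np.array([spec.arm_offset + spec.domain_radii[0], 0.0, 0.0])
        sym = C2Symmetry(axis=[0.0, 0.0, 1.0], point=[0.0, 0.0, 0.0])
        coords = np.vstack([arm, sym.apply(arm)])
        return BeadModel(coords, bead_diameter=spec.bead_diameter, symmetry=sym)
    coords = _fill(spec, spec.n_beads, rng)
    if spec.kind == "tandem":
        coords = _apply_hinge(coords, spec)
    else:
        # For envelopes with a closed-form Rg, absorb the residual
        # discretization bias by rescaling about the centroid so the bead
        # cloud's coordinate Rg equals the continuum value exactly.
        rg_target = _analytic_rg(spec)
        if rg_target is not None:
            center = coords.mean(axis=0)
            c = coords - center
            rg_actual = math.sqrt(((c**2).sum(axis=1)).mean())
            coords = center + c * (rg_target / rg_actual)
    return BeadModel(coords, bead_diameter=spec.bead_diameter)
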