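"""Multivariate classification of restored model ensembles.

Ab initio shape restoration does not yield a unique model: independent
runs on the same curve produce a family of shapes that all fit the data.
To extract the probable shapes, every model is rigidly superimposed onto
a reference through its principal axes of inertia (trying all proper
axis-sign combinations and, optionally, the mirror images, since
enantiomers scatter identically), digitized on a common lattice of
4 x 4 x 4 A^3 voxels, embedded by principal component analysis, and
clustered by K-means on the PC1-PC2 plane.  Classes are ranked by the
mean chi-square of their members against the target curve; the selected
classes are averaged voxel-wise into consensus shapes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .debye import debye_intensity
from .restore import chi2_fit
from .types import BeadModel, ScatteringProfile

logger = logging.getLogger("saxskit")

__all__ = [
    "VoxelGrid",
    "ClassificationResult",
    "align_inertia",
    "voxelize",
    "common_grid",
    "embed_pca",
    "cluster_models",
    "select_and_average",
    "classify_ensemble",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Occupancy counts on a regular cubic lattice."""

    origin: np.ndarray
    spacing: float
    shape: Tuple[int, int, int]
    occupancy: np.ndarray

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        occ = np.asarray(self.occupancy)
        if occ.shape != tuple(self.shape):
            raise ValueError("occupancy shape does not match grid shape")
        if np.any(occ < 0):
            raise ValueError("occupancy must be non-negative")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def same_lattice(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) < 1e-9
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )

    def flat(self) -> np.ndarray:
        return np.asarray(self.occupancy, dtype=float).ravel()


def _principal_axes(coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the gyration tensor, eigenvalues descending."""
    c = coords - coords.mean(axis=0)
    gyr = c.T @ c / len(c)
    vals, vecs = np.linalg.eigh(gyr)
    order = np.argsort(vals)[::-1]
    vecs = vecs[:, order]
    # force a right-handed basis so that det=+1 sign combinations below
    # correspond to proper rotations of the model
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vals[order], vecs


_SIGN_COMBOS = [np.diag(s) for s in
                [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]]


def align_inertia(
    model: BeadModel,
    reference: BeadModel,
    try_mirror: bool = True,
) -> Tuple[BeadModel, bool]:
    """Superimpose ``model`` onto ``reference`` via principal axes of inertia.

    Both are centered; the model's inertia eigenvectors are rotated onto
    the reference's.  The eigenvector decomposition leaves a sign
    ambiguity per axis: all 4 proper (det = +1) combinations are tried
    and, when ``try_mirror``, the 4 reflected ones as well (mirror shapes
    fit SAXS data identically).  The variant minimizing the mean
    nearest-neighbor distance to the reference wins; exact ties fall to
    the earlier variant in a fixed lexicographic enumeration, so
    degenerate (near-spherical) inputs still give deterministic output.

    Returns the aligned model and whether a mirror was applied.
    """
    if len(model) < 4 or len(reference) < 4:
        raise ValueError("need at least 4 beads in both models")
    vals_m, axes_m = _principal_axes(model.coords)
    vals_r, axes_r = _principal_axes(reference.coords)
    if np.min(np.abs(np.diff(vals_m))) <= 1e-6 * max(vals_m[0], 1e-30):
        logger.warning("align_inertia: near-degenerate inertia tensor; "
                       "falling back to exhaustive sign search with fixed tie-break")
    ref_centered = reference.coords - reference.coords.mean(axis=0)
    tree = cKDTree(ref_centered)
    centered = model.coords - model.coords.mean(axis=0)
    # coordinates in the model's own principal frame
    local = centered @ axes_m

    best = None
    variants = [(s, False) for s in _SIGN_COMBOS]
    if try_mirror:
        variants += [(s, True) for s in _SIGN_COMBOS]
    for signs, mirrored in variants:
        local_v = local.copy()
        if mirrored:
            local_v[:, 2] = -local_v[:, 2]
        cand = local_v @ (axes_r @ signs).T
        score = tree.query(cand)[0].mean()
        if best is None or score < best[0]:
            best = (score, cand, mirrored)
    _, coords, mirrored = best
    coords = coords + reference.coords.mean(axis=0)
    return BeadModel(coords, model.bead_diameter, model.form_factor.copy()), mirrored


def common_grid(models: Sequence[BeadModel], spacing: float = 4.0) -> Tuple[np.ndarray, Tuple[int, int, int]]:
    """Lattice (origin, shape) enclosing every model with a one-voxel margin,
    centered at the ensemble center of mass."""
    allc = np.vstack([m.coords for m in models])
    center = allc.mean(axis=0)
    half = np.abs(allc - center).max(axis=0) + spacing
    n_half = np.ceil(half / spacing).astype(int)
    origin = center - (n_half + 0.5) * spacing
    shape = tuple(int(x) for x in (2 * n_half + 1))
    return origin, shape


def voxelize(
    model: BeadModel,
    spacing: float = 4.0,
    origin: Optional[np.ndarray] = None,
    shape: Optional[Tuple[int, int, int]] = None,
    mode: str = "count",
) -> VoxelGrid:
    """Digitize a bead model onto a cubic lattice.

    Each bead increments the voxel containing its center; boxes are
    half-open, ``[edge, edge + spacing)``, so a bead exactly on a boundary
    lands in the higher-index voxel on every platform.  When origin/shape
    are omitted an enclosing grid with a one-voxel margin is built.
    ``mode='binary'`` marks occupancy 0/1 instead of counts.
    """
    if (origin is None) != (shape is None):
        raise ValueError("origin and shape must be given together")
    if origin is None:
        origin, shape = common_grid([model], spacing)
    origin = np.asarray(origin, dtype=float)
    idx = np.floor((model.coords - origin) / spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        raise ValueError("bead outside the fixed voxel grid")
    occ = np.zeros(shape, dtype=float)
    np.add.at(occ, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    if mode == "binary":
        occ = (occ > 0).astype(float)
    elif mode != "count":
        raise ValueError("mode must be 'count' or 'binary'")
    return VoxelGrid(origin=origin, spacing=spacing, shape=tuple(shape), occupancy=occ)


def embed_pca(grids: Sequence[VoxelGrid]):
    """PCA embedding of voxelized models.

    Returns (pc_coords, explained_variance_ratio, components); signs are
    fixed so each component's largest-magnitude loading is positive.  A
    zero-variance ensemble (all grids identical) maps every model to the
    origin with zero explained variance rather than erroring.
    """
    if len(grids) < 3:
        raise ValueError("need at least 3 models for a PCA embedding")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_lattice(g):
            raise ValueError("all voxel grids must share one lattice")
    x = np.stack([g.flat() for g in grids])
    xc = x - x.mean(axis=0)
    if not np.any(np.abs(xc) > 1e-12):
        m = len(grids)
        k = min(m - 1, x.shape[1])
        return np.zeros((m, k)), np.zeros(k), np.zeros((k, x.shape[1]))
    from sklearn.decomposition import PCA

    pca = PCA(n_components=min(len(grids) - 1, x.shape[1]), svd_solver="full")
    coords = pca.fit_transform(x)
    comps = pca.components_
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            coords[:, k] = -coords[:, k]
    return coords, pca.explained_variance_ratio_, comps


def cluster_models(pc_coords: np.ndarray, k="auto", seed: int = 0) -> np.ndarray:
    """K-means on the PC1-PC2 plane; seeded 10-start, deterministic.

    ``k='auto'`` scans k in 2..min(8, M-1) and keeps the silhouette
    maximizer; if even the best silhouette is below 0.25 the ensemble has
    no real cluster structure and a single class is returned.  A
    degenerate, zero-spread ensemble likewise gets a single class with a
    logged warning.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    x = np.asarray(pc_coords, dtype=float)[:, :2]
    m = len(x)
    if m < 2:
        raise ValueError("need at least 2 models to cluster")
    if k != "auto" and int(k) > m:
        raise ValueError("k cannot exceed the number of models")
    if np.allclose(x, x[0], atol=1e-12):
        logger.warning("cluster_models: zero spread on PC1-PC2; single class returned")
        return np.zeros(m, dtype=int)
    if k == "auto":
        best = None
        for kk in range(2, min(8, m - 1) + 1):
            km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(x)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(x, km.labels_)
            if best is None or score > best[0]:
                best = (score, km.labels_)
        if best is None or best[0] < 0.25:
            logger.warning("cluster_models: no real cluster structure "
                           "(best silhouette %s); single class",
                           "n/a" if best is None else f"{best[0]:.2f}")
            return np.zeros(m, dtype=int)
        return best[1].astype(int)
    k = int(k)
    if k > m:
        raise ValueError("k cannot exceed the number of models")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    return km.labels_.astype(int)


@dataclass(frozen=True)
class ClassificationResult:
    pc_coords: np.ndarray
    explained_variance: np.ndarray
    labels: np.ndarray
    k: int
    class_averages: Tuple[BeadModel, ...]
    class_mean_chi2: Tuple[float, ...]
    selected_classes: Tuple[int, ...]
    mirror_flags: Tuple[bool, ...]


def select_and_average(
    models: Sequence[BeadModel],
    labels: np.ndarray,
    target: ScatteringProfile,
    pc_coords: Optional[np.ndarray] = None,
    explained_variance: Optional[np.ndarray] = None,
    occupancy_threshold: float = 0.5,
    selection_band: float = 0.10,
    spacing: float = 4.0,
) -> ClassificationResult:
    """Average each class into a consensus shape and select the best classes.

    Within a class, members are aligned (inertia axes, mirrors allowed) to
    the member with the lowest chi-square against the target; their binary
    voxel occupancies are averaged and voxels reaching
    ``occupancy_threshold`` become consensus beads at the voxel centers.
    Classes are ranked by mean member chi-square; every class within
    ``selection_band`` (relative) of the best mean is selected.
    """
    labels = np.asarray(labels, dtype=int)
    if len(models) == 0:
        raise ValueError("empty ensemble")
    if len(models) != len(labels):
        raise ValueError("one label per model required")
    chi2s = np.array([
        chi2_fit(target, debye_intensity(m, target.s_grid)).chi2 for m in models
    ])
    classes = np.unique(labels)
    averages: List[BeadModel] = []
    mean_chi2: List[float] = []
    mirror_flags: List[bool] = []
    for cls in classes:
        members = np.flatnonzero(labels == cls)
        ref = models[members[np.argmin(chi2s[members])]]
        aligned = []
        any_mirror = False
        for j in members:
            if models[j] is ref:
                aligned.append(ref)
                continue
            m_aligned, mirrored = align_inertia(models[j], ref, try_mirror=True)
            any_mirror |= mirrored
            aligned.append(m_aligned)
        origin, shape = common_grid(aligned, spacing)
        occ = np.mean(
            [voxelize(m, spacing, origin, shape, mode="binary").occupancy for m in aligned],
            axis=0,
        )
        sel = np.argwhere(occ >= occupancy_threshold)
        if len(sel) == 0:  # pathological spread: fall back to any occupancy
            sel = np.argwhere(occ > 0)
        centers = origin + (sel + 0.5) * spacing
        averages.append(BeadModel(centers, bead_diameter=spacing))
        mean_chi2.append(float(chi2s[members].mean()))
        mirror_flags.append(any_mirror)
    mean_chi2_arr = np.array(mean_chi2)
    best = mean_chi2_arr.min()
    selected = tuple(int(classes[i]) for i in np.flatnonzero(
        mean_chi2_arr <= best * (1.0 + selection_band)))
    m = len(models)
    return ClassificationResult(
        pc_coords=pc_coords if pc_coords is not None else np.zeros((m, 2)),
        explained_variance=(explained_variance if explained_variance is not None
                            else np.zeros(2)),
        labels=labels,
        k=len(classes),
        class_averages=tuple(averages),
        class_mean_chi2=tuple(mean_chi2),
        selected_classes=selected,
        mirror_flags=tuple(mirror_flags),
    )


def classify_ensemble(
    models: Sequence[BeadModel],
    target: ScatteringProfile,
    k="auto",
    seed: int = 0,
    spacing: float = 4.0,
    occupancy_threshold: float = 0.5,
) -> ClassificationResult:
    """Full protocol: align to the best-fitting member, voxelize on a common
    lattice, PCA, K-means on PC1-PC2, then class selection and averaging."""
    if len(models) < 3:
        raise ValueError("need at least 3 models")
    chi2s = [chi2_fit(target, debye_intensity(m, target.s_grid)).chi2 for m in models]
    ref = models[int(np.argmin(chi2s))]
    aligned = []
    for m in models:
        if m is ref:
            aligned.append(BeadModel(
                ref.coords - ref.coords.mean(axis=0) + ref.coords.mean(axis=0),
                ref.bead_diameter, ref.form_factor.copy()))
            continue
        aligned.append(align_inertia(m, ref, try_mirror=True)[0])
    origin, shape = common_grid(aligned, spacing)
    grids = [voxelize(m, spacing, origin, shape) for m in aligned]
    pc_coords, evr, _ = embed_pca(grids)
    labels = cluster_models(pc_coords, k=k, seed=seed)
    return select_and_average(
        aligned, labels, target,
        pc_coords=pc_coords, explained_variance=evr,
        occupancy_threshold=occupancy_threshold, spacing=spacing,
    )
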