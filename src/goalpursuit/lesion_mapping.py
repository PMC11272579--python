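"""Voxelwise lesion-behaviour mapping with permutation cluster correction.

Each voxel with sufficient damaged and intact patients is tested with the
regression of persistence bias on binary damage status (algebraically a
two-sample t-test), signed so that a positive t means damage predicts a
*lower* persistence bias.  Supra-threshold voxels are grouped into connected
clusters, and a chance cluster-size distribution is built by shuffling the
behavioural biases across patients.

Two null conventions are provided: ``pooled`` takes the 95% cut-off of all
chance cluster sizes pooled across permutations (the convention of the
original analysis), while ``max`` uses the per-permutation maximum cluster
size, the standard construction that controls family-wise error at alpha.
The pooled cut-off is liberal when many small chance clusters occur per map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .synthetic_cohort import LesionCohort

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class TMap:
    """Voxelwise t-statistics with an explicit tested-voxel mask.

    Untested voxels (too few damaged or intact patients) carry NaN so they
    can never be confused with a genuine t of 0.
    """

    t: np.ndarray  # 3-D, NaN where untested
    mask: np.ndarray  # 3-D boolean, True where tested
    n_patients: int

    def save(self, path, voxel_size_mm: float = 2.4) -> None:
        import nibabel as nib

        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.t.astype(np.float32), affine), str(path))


@dataclass
class Cluster:
    """A connected set of supra-threshold voxels."""

    voxels: np.ndarray  # (size, 3) integer coordinates
    size: int
    peak: tuple[int, int, int]
    peak_t: float

    def overlaps(self, mask: np.ndarray) -> bool:
        return bool(mask[tuple(self.voxels.T)].any())


def _flat_t(
    X: np.ndarray,
    y: np.ndarray,
    tested: np.ndarray,
    n1: np.ndarray,
) -> np.ndarray:
    """Vectorised two-group t over flattened voxels (positive = damage lowers y).

    ``X`` is (n_patients, n_voxels) binary, ``n1`` its column sums, ``tested``
    the voxel inclusion mask.  Identical to the simple-regression t on a
    binary damage regressor, up to sign.
    """
    n = y.size
    y = np.asarray(y, dtype=float)
    s1 = X.T @ y  # damaged-group sum per voxel
    total = y.sum()
    ss_tot = float(((y - y.mean()) ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        n0 = n - n1
        m1 = s1 / n1
        m0 = (total - s1) / n0
        d = m0 - m1  # intact minus damaged: positive when damage lowers y
        ss_within = ss_tot - (n1 * n0 / n) * d**2
        ss_within = np.maximum(ss_within, 0.0)
        sp = np.sqrt(ss_within / (n - 2))
        se = sp * np.sqrt(1.0 / n1 + 1.0 / n0)
        t = d / se
        t[~tested] = np.nan
        # zero-variance voxels: difference without spread
        degenerate = tested & (se == 0)
        t[degenerate] = np.where(d[degenerate] > 0, np.inf, np.where(d[degenerate] < 0, -np.inf, 0.0))
    return t


def voxelwise_t(cohort: LesionCohort, min_overlap: int = 2) -> TMap:
    """Voxelwise lesion-behaviour t-map.

    Only voxels damaged in at least ``min_overlap`` patients *and* intact in
    at least ``min_overlap`` patients are tested.
    """
    n = cohort.n_patients
    if n < 2:
        raise ValueError("need >= 2 patients")
    X = cohort.maps.reshape(n, -1).astype(float)
    n1 = X.sum(axis=0)
    tested = (n1 >= min_overlap) & ((n - n1) >= min_overlap)
    if not tested.any():
        warnings.warn("no voxel satisfies the overlap criterion; t-map is empty")
    t = _flat_t(X, cohort.biases, tested, n1)
    dims = cohort.grid_dims
    return TMap(t=t.reshape(dims), mask=tested.reshape(dims), n_patients=n)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def extract_clusters(
    tmap: TMap,
    threshold: float = 2.3,
    connectivity: int = 6,
) -> list[Cluster]:
    """Connected components of {t > threshold}, sorted by size descending."""
    supra = np.where(np.isnan(tmap.t), False, tmap.t > threshold)
    labels, n_clusters = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    clusters = []
    for lab in range(1, n_clusters + 1):
        voxels = np.argwhere(labels == lab)
        ts = tmap.t[tuple(voxels.T)]
        peak_idx = int(np.argmax(ts))
        clusters.append(
            Cluster(
                voxels=voxels,
                size=voxels.shape[0],
                peak=tuple(int(c) for c in voxels[peak_idx]),
                peak_t=float(ts[peak_idx]),
            )
        )
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


def _chance_cluster_sizes(
    cohort: LesionCohort,
    n_perm: int,
    threshold: float,
    connectivity: int,
    min_overlap: int,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """Cluster sizes under bias shuffling: (pooled sizes, per-perm maxima)."""
    n = cohort.n_patients
    X = cohort.maps.reshape(n, -1).astype(float)
    n1 = X.sum(axis=0)
    tested = (n1 >= min_overlap) & ((n - n1) >= min_overlap)
    structure = _connectivity_structure(connectivity)
    dims = cohort.grid_dims
    pooled: list[int] = []
    maxima: list[int] = []
    for _ in range(n_perm):
        y = rng.permutation(cohort.biases)
        t = _flat_t(X, y, tested, n1)
        supra = np.where(np.isnan(t), False, t > threshold).reshape(dims)
        labels, n_clusters = ndimage.label(supra, structure=structure)
        if n_clusters == 0:
            maxima.append(0)
            continue
        sizes = np.bincount(labels.ravel())[1:]
        pooled.extend(int(s) for s in sizes)
        maxima.append(int(sizes.max()))
    return pooled, maxima


def permutation_cluster_threshold(
    cohort: LesionCohort,
    n_perm: int = 1000,
    threshold: float = 2.3,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    null: str = "pooled",
    connectivity: int = 6,
    min_overlap: int = 2,
) -> int:
    """Minimum cluster size for significance from a permutation null.

    ``null='pooled'`` (original convention): the smallest integer s such that
    at most ``alpha`` of all chance clusters, pooled across permutations,
    reach size s; 0 if no chance cluster was ever found.  ``null='max'``
    (family-wise control): the smallest s whose add-one permutation p-value
    against the per-permutation maximum cluster size is <= alpha.  An
    observed cluster is significant iff its size >= the returned value.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: cluster threshold will be coarse")
    pooled, maxima = _chance_cluster_sizes(
        cohort, n_perm, threshold, connectivity, min_overlap, rng
    )
    if null == "pooled":
        if not pooled:
            return 0
        sizes = np.asarray(pooled)
        for s in range(1, int(sizes.max()) + 2):
            if np.mean(sizes >= s) <= alpha:
                return s
        return int(sizes.max()) + 1  # pragma: no cover
    if null == "max":
        maxima_arr = np.asarray(maxima)
        for s in range(1, int(maxima_arr.max(initial=0)) + 2):
            if (1 + np.sum(maxima_arr >= s)) / (n_perm + 1) <= alpha:
                return s
        return int(maxima_arr.max(initial=0)) + 2  # pragma: no cover
    raise ValueError("null must be 'pooled' or 'max'")


def significant_clusters(
    cohort: LesionCohort,
    n_perm: int = 1000,
    threshold: float = 2.3,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    null: str = "pooled",
    connectivity: int = 6,
    min_overlap: int = 2,
) -> tuple[list[Cluster], int]:
    """Observed clusters surviving permutation correction.

    Returns ``(clusters, min_size)`` where ``clusters`` are the observed
    supra-threshold clusters with size >= ``min_size``.
    """
    tmap = voxelwise_t(cohort, min_overlap=min_overlap)
    observed = extract_clusters(tmap, threshold=threshold, connectivity=connectivity)
    min_size = permutation_cluster_threshold(
        cohort,
        n_perm=n_perm,
        threshold=threshold,
        alpha=alpha,
        rng=rng,
        null=null,
        connectivity=connectivity,
        min_overlap=min_overlap,
    )
    if min_size <= 0:
        surviving = observed
    else:
        surviving = [c for c in observed if c.size >= min_size]
    return surviving, min_size


def roi_mask(
    grid_dims: tuple[int, int, int],
    roi_center: tuple[int, int, int],
    roi_radius_vox: float,
) -> np.ndarray:
    """Boolean Euclidean ball of the given voxel radius around a center."""
    center = np.asarray(roi_center, dtype=float)
    if (center < 0).any() or (center >= np.asarray(grid_dims)).any():
        raise ValueError("roi_center must lie inside the grid")
    grids = np.indices(grid_dims, dtype=float)
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= roi_radius_vox**2


def roi_split(
    cohort: LesionCohort,
    roi_center: Optional[tuple[int, int, int]] = None,
    roi_radius_vox: float = 3.0,
) -> np.ndarray:
    """Label each patient ROI-damaged iff any lesioned voxel lies in the ball."""
    if roi_center is None:
        roi_center = cohort.roi_center
    ball = roi_mask(cohort.grid_dims, roi_center, roi_radius_vox)
    return np.array([bool((m & ball).any()) for m in cohort.maps])


def clusters_to_frame(clusters: list[Cluster]):
    """Cluster report table: cluster_id, size, peak coordinates, peak t."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cluster_id": i,
                "size": c.size,
                "peak_x": c.peak[0],
                "peak_y": c.peak[1],
                "peak_z": c.peak[2],
                "peak_t": c.peak_t,
            }
            for i, c in enumerate(clusters)
        ]
    )
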