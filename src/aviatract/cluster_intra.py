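"""Intra-subject fiber clustering (first level of the bundle segmentation).

The subject's tractogram is partitioned by region (left/right
hemisphere, interhemispheric, cerebellum) and fiber length, each group's
density mask is parcellated by k-means into ~27-voxel parcels, a
parcel-parcel fiber-count connectivity matrix is clustered by
average-linkage agglomeration, fibers are assigned to parcel clusters by
trajectory overlap (>= 31%), and every retained cluster (>= 5 members)
is represented by its medoid fiber (the centroid).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import distance_transform_edt
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .core import Tractogram, mcp_matrix, points_to_voxels, resample_streamline
from .phantom import REGION_CBL, REGION_INT, REGION_LH, REGION_RH

__all__ = [
    "RegionPartition",
    "ParcelMap",
    "FiberCluster",
    "Centroid",
    "split_by_region",
    "split_by_length",
    "density_mask",
    "parcellate",
    "parcel_connectivity",
    "cluster_parcels",
    "assign_fibers",
    "compute_centroid",
    "cluster_subject",
]

log = logging.getLogger(__name__)

REGION_NAMES = {REGION_LH: "LH", REGION_RH: "RH", REGION_INT: "INT", REGION_CBL: "CBL"}


@dataclass
class RegionPartition:
    """Disjoint fiber-index subsets covering the tractogram, per region."""

    subsets: dict[str, np.ndarray]  # region name -> fiber indices


@dataclass
class ParcelMap:
    """Integer parcel-label volume (0 = background) from k-means."""

    labels: np.ndarray
    n_parcels: int
    target_mean_size: int


@dataclass
class FiberCluster:
    """One intra-subject fiber cluster with its provenance keys."""

    member_indices: np.ndarray  # indices into the subject tractogram
    parcels: np.ndarray  # parcel labels forming the cluster area
    region: str
    length_range_index: int
    subject_id: str = ""


@dataclass
class Centroid:
    """The member fiber minimizing the mean MCP distance to the others."""

    points: np.ndarray
    member_index: int  # index into the subject tractogram
    cluster: FiberCluster = field(repr=False, default=None)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def split_by_region(t: Tractogram, region_labels: np.ndarray) -> RegionPartition:
    """Assign each fiber to LH / RH / INT / CBL.

    A fiber goes to the region holding the majority of its points;
    fibers touching both hemispheres are interhemispheric.  Points over
    unlabeled voxels take the nearest labeled voxel (logged).
    """
    labels = np.asarray(region_labels)
    filled = labels
    if (labels == 0).any() and (labels != 0).any():
        _, (ix, iy, iz) = distance_transform_edt(labels == 0, return_indices=True)
        filled = labels[ix, iy, iz]
    subsets: dict[str, list[int]] = {"LH": [], "RH": [], "INT": [], "CBL": []}
    n_unlabeled = 0
    shape = np.asarray(labels.shape)
    for i, sl in enumerate(t.streamlines):
        vox = np.clip(points_to_voxels(sl, t.affine), 0, shape - 1)
        lab = labels[vox[:, 0], vox[:, 1], vox[:, 2]]
        if (lab == 0).any():
            n_unlabeled += int((lab == 0).sum())
            lab = filled[vox[:, 0], vox[:, 1], vox[:, 2]]
        if (lab == REGION_LH).any() and (lab == REGION_RH).any():
            subsets["INT"].append(i)
            continue
        counts = np.bincount(lab, minlength=5)
        subsets[REGION_NAMES[int(counts[1:].argmax()) + 1]].append(i)
    if n_unlabeled:
        log.info("split_by_region: %d points over unlabeled voxels remapped", n_unlabeled)
    return RegionPartition({k: np.asarray(v, dtype=int) for k, v in subsets.items()})


def split_by_length(
    lengths: np.ndarray, window: tuple[float, float], n_ranges: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Bin fibers into equal-width length ranges inside the window.

    Returns ``(bin_index, kept)`` where ``bin_index`` is -1 for
    discarded fibers (outside the window) and the last bin is
    right-closed.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy l_min < l_max")
    lengths = np.asarray(lengths, dtype=float)
    kept = (lengths >= lo) & (lengths <= hi)
    idx = np.floor((lengths - lo) / (hi - lo) * n_ranges).astype(int)
    idx = np.clip(idx, 0, n_ranges - 1)
    idx[~kept] = -1
    return idx, kept


def _fiber_voxels(sl: np.ndarray, affine: np.ndarray, shape) -> np.ndarray:
    vox = points_to_voxels(sl, affine)
    vox = np.clip(vox, 0, np.asarray(shape) - 1)
    return np.unique(vox, axis=0)


def density_mask(
    fibers: list[np.ndarray],
    affine: np.ndarray,
    shape: tuple[int, int, int],
    min_fibers: int = 5,
) -> np.ndarray:
    """Voxels crossed by at least ``min_fibers`` distinct fibers.

    A fiber contributes at most once per voxel regardless of how many of
    its points fall there.
    """
    counts = np.zeros(shape, dtype=np.int64)
    for sl in fibers:
        vox = _fiber_voxels(sl, affine, shape)
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return counts >= min_fibers


def parcellate(
    mask: np.ndarray, voxel_size: float, mean_parcel_size: int = 27, seed: int = 0
) -> ParcelMap:
    """k-means parcellation of a binary mask into ~equal random parcels.

    ``k = max(1, round(n_voxels / mean_parcel_size))``; k-means runs on
    the voxel-center mm coordinates and every voxel takes the label of
    its nearest final center (labels start at 1).
    """
    mask = np.asarray(mask, dtype=bool)
    vox = np.argwhere(mask)
    if len(vox) == 0:
        raise ValueError("empty mask")
    k = max(1, int(round(len(vox) / mean_parcel_size)))
    coords = (vox + 0.5) * voxel_size
    km = KMeans(n_clusters=min(k, len(vox)), n_init=4, random_state=seed).fit(coords)
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[mask] = km.labels_ + 1
    return ParcelMap(labels, int(km.n_clusters), mean_parcel_size)


def parcel_connectivity(
    fibers: list[np.ndarray], pm: ParcelMap, affine: np.ndarray
) -> np.ndarray:
    """Symmetric parcel x parcel matrix of co-visiting fiber counts.

    ``M[p, q]`` = number of fibers traversing both parcels ``p`` and
    ``q`` (p != q); the diagonal is zero by convention.  Row/column 0 is
    unused (background).
    """
    n = pm.n_parcels + 1
    m = np.zeros((n, n), dtype=np.int64)
    shape = pm.labels.shape
    for sl in fibers:
        vox = _fiber_voxels(sl, affine, shape)
        par = np.unique(pm.labels[vox[:, 0], vox[:, 1], vox[:, 2]])
        par = par[par > 0]
        if len(par) > 1:
            pi, pj = np.meshgrid(par, par, indexing="ij")
            m[pi, pj] += 1
    np.fill_diagonal(m, 0)
    return m


def cluster_parcels(m: np.ndarray, cut: float = 0.9) -> list[np.ndarray]:
    """Average-linkage clusters of connected parcels.

    Distance ``D[p,q] = 1 - M[p,q] / max(M)``; the dendrogram is cut at
    height ``cut``.  An all-zero matrix yields singletons.
    """
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("connectivity matrix must be symmetric")
    parcels = np.arange(1, m.shape[0])  # label 0 is background
    if len(parcels) == 0:
        return []
    if len(parcels) == 1:
        return [parcels.copy()]
    if m.max() == 0:
        return [np.array([p]) for p in parcels]
    sub = m[1:, 1:]
    d = 1.0 - sub / sub.max()
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    flat = fcluster(z, t=cut, criterion="distance")
    return [parcels[flat == c] for c in np.unique(flat)]


def assign_fibers(
    fibers: list[np.ndarray],
    fiber_indices: np.ndarray,
    parcel_clusters: list[np.ndarray],
    pm: ParcelMap,
    affine: np.ndarray,
    min_frac: float = 0.31,
    min_members: int = 5,
    region: str = "",
    length_range_index: int = -1,
    subject_id: str = "",
) -> list[FiberCluster]:
    """Assign fibers to parcel clusters by trajectory overlap.

    A fiber's fraction in a cluster is the share of its points lying in
    the cluster's parcels; it joins the cluster of maximal fraction if
    that fraction reaches ``min_frac``.  Clusters with fewer than
    ``min_members`` fibers are discarded (logged).
    """
    if not parcel_clusters:
        return []
    cluster_of_parcel = np.zeros(pm.n_parcels + 1, dtype=np.int64)  # 0 = none
    for ci, parcels in enumerate(parcel_clusters, start=1):
        cluster_of_parcel[parcels] = ci
    members: dict[int, list[int]] = {}
    shape = pm.labels.shape
    for fi, sl in zip(fiber_indices, fibers):
        vox = np.clip(points_to_voxels(sl, affine), 0, np.asarray(shape) - 1)
        par = pm.labels[vox[:, 0], vox[:, 1], vox[:, 2]]
        cl = cluster_of_parcel[par]
        counts = np.bincount(cl, minlength=len(parcel_clusters) + 1)
        frac = counts[1:] / len(sl)
        best = int(frac.argmax())
        if frac[best] >= min_frac:
            members.setdefault(best + 1, []).append(int(fi))
    out = []
    n_dropped = 0
    for ci, parcels in enumerate(parcel_clusters, start=1):
        mem = members.get(ci, [])
        if len(mem) < min_members:
            n_dropped += 1
            continue
        out.append(
            FiberCluster(
                np.asarray(mem, dtype=int), parcels, region, length_range_index, subject_id
            )
        )
    if n_dropped:
        log.info("assign_fibers: %d clusters below %d members dropped", n_dropped, min_members)
    return out


def compute_centroid(
    cluster: FiberCluster,
    fibers: list[np.ndarray],
    n_resample: int | None = None,
    max_members_exact: int = 256,
    seed: int = 0,
) -> Centroid:
    """Medoid fiber of a cluster under the symmetric MCP distance.

    The centroid is the member minimizing the mean distance to the other
    members (ties broken by lower fiber index).  For clusters larger
    than ``max_members_exact`` the mean is taken over a seeded reference
    subsample; distances can be computed on ``n_resample``-point copies
    of the fibers for speed.
    """
    idx = cluster.member_indices
    if len(idx) == 1:
        return Centroid(fibers[idx[0]], int(idx[0]), cluster)
    mem = [fibers[i] for i in idx]
    if n_resample is not None:
        mem = [resample_streamline(f, n_resample) for f in mem]
        dm = None
        if len(mem) <= max_members_exact:
            dm = mcp_matrix(mem)
            mean_d = dm.sum(axis=1) / (len(mem) - 1)
        else:
            rng = np.random.default_rng(seed)
            ref = rng.choice(len(mem), size=max_members_exact, replace=False)
            refs = np.asarray([mem[r] for r in ref])
            cand = np.asarray(mem)
            from .core import mcp_block

            mean_d = np.empty(len(cand))
            for i0 in range(0, len(cand), 128):
                blk = cand[i0 : i0 + 128]
                mean_d[i0 : i0 + 128] = mcp_block(blk, refs).mean(axis=1)
    else:
        from .core import mcp_distance

        n = len(mem)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = mcp_distance(mem[i], mem[j])
        mean_d = dm.sum(axis=1) / (n - 1)
    best = int(np.flatnonzero(mean_d == mean_d.min()).min())
    return Centroid(fibers[idx[best]], int(idx[best]), cluster)


def cluster_subject(
    t: Tractogram,
    region_labels: np.ndarray,
    window: tuple[float, float],
    n_ranges: int = 8,
    min_density: int = 5,
    mean_parcel_size: int = 27,
    dendrogram_cut: float = 0.9,
    min_frac: float = 0.31,
    min_members: int = 5,
    centroid_resample: int = 21,
    subject_id: str = "",
    seed: int = 0,
) -> tuple[list[FiberCluster], list[Centroid]]:
    """Full Step-1 pipeline for one subject's tractogram."""
    voxel_size = float(t.affine[0, 0])
    shape = region_labels.shape
    partition = split_by_region(t, region_labels)
    lengths = t.lengths()
    clusters: list[FiberCluster] = []
    centroids: list[Centroid] = []
    for region, fidx in partition.subsets.items():
        if len(fidx) == 0:
            continue
        bins, kept = split_by_length(lengths[fidx], window, n_ranges)
        for b in range(n_ranges):
            sub = fidx[bins == b]
            if len(sub) == 0:
                continue
            fibers = [t.streamlines[i] for i in sub]
            dm = density_mask(fibers, t.affine, shape, min_density)
            if not dm.any():
                log.info("cluster_subject: empty density mask (%s, bin %d)", region, b)
                continue
            pm = parcellate(dm, voxel_size, mean_parcel_size, seed=seed + 97 * b)
            m = parcel_connectivity(fibers, pm, t.affine)
            pcl = cluster_parcels(m, dendrogram_cut)
            fcl = assign_fibers(
                fibers, sub, pcl, pm, t.affine, min_frac, min_members,
                region=region, length_range_index=b, subject_id=subject_id,
            )
            for c in fcl:
                clusters.append(c)
                centroids.append(
                    compute_centroid(c, t.streamlines, n_resample=centroid_resample, seed=seed)
                )
    return clusters, centroids
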