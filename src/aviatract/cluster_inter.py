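"""Inter-subject centroid clustering (second level of the segmentation).

Centroids from all subjects, resampled to 21 points in a common
(template) space, are compared with a length-corrected pairwise
distance, turned into Gaussian affinities, clustered with HDBSCAN and
filtered for presence in at least half of the cohort.  The distance
correction

    d = max(d_floor, d_pw * nf / (nf + min(len_a, len_b)))

relaxes the distance constraint as the shorter centroid gets longer
(halving the raw distance when the minimum length equals ``nf``).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import HDBSCAN

from .core import resample_streamline, streamline_length

__all__ = [
    "CentroidSet",
    "InterParams",
    "InterCluster",
    "resample_centroid",
    "normalized_pairwise_distance",
    "distance_matrix",
    "affinity_matrix",
    "hdbscan_interclusters",
    "presence_filter",
    "grid_optimize",
]


@dataclass
class InterParams:
    """Parameters of the inter-subject centroid clustering."""

    nf: float = 4.0  # mm, normalization factor of the length correction
    camd: float = 2.0  # mm, maximum distance for the centroid affinity
    sigma2: float = 1600.0  # mm^2, variance of the centroid affinity
    d_floor: float = 0.01  # mm, minimum normalized distance
    d_excl: float = 0.4  # mm, maximum distance after exclusion (medoid pruning)
    min_pop_frac: float = 0.5  # minimum population fraction of a kept cluster
    n_points: int = 21  # centroid resampling point count

    def __post_init__(self) -> None:
        if min(self.nf, self.camd, self.sigma2, self.d_floor, self.d_excl) <= 0:
            raise ValueError("all inter-clustering parameters must be positive")
        if self.d_floor >= self.camd:
            raise ValueError("d_floor must be smaller than camd")


@dataclass
class CentroidSet:
    """Centroids of the whole cohort in a common coordinate space."""

    points: np.ndarray  # (n, n_points, 3) mm
    subject_ids: np.ndarray  # (n,) str or int labels
    regions: np.ndarray | None = None
    cluster_refs: list = field(default_factory=list)
    space: str = "template"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.points.ndim != 3:
            raise ValueError("points must be (n_centroids, n_points, 3)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=1), axis=2).sum(axis=1)

    @classmethod
    def from_streamlines(cls, streamlines, subject_ids, n_points: int = 21, **kw):
        pts = np.asarray([resample_centroid(s, n_points) for s in streamlines])
        return cls(pts, np.asarray(subject_ids), **kw)


@dataclass
class InterCluster:
    """A population-level cluster of centroids."""

    member_indices: np.ndarray
    subjects: np.ndarray  # unique contributing subject ids
    presence_fraction: float


def resample_centroid(c: np.ndarray, n_points: int = 21) -> np.ndarray:
    """Resample a centroid to ``n_points`` equidistant points (arc length)."""
    return resample_streamline(c, n_points)


def _corrected(d_pw: np.ndarray, len_a, len_b, p: InterParams) -> np.ndarray:
    min_len = np.minimum(len_a, len_b)
    return np.maximum(p.d_floor, d_pw * p.nf / (p.nf + min_len))


def normalized_pairwise_distance(
    a: np.ndarray, b: np.ndarray, p: InterParams
) -> float:
    """Length-corrected pairwise distance between two resampled centroids.

    The raw distance is the mean point-to-corresponding-point Euclidean
    distance, minimized over the two point orderings (a centroid has no
    preferred direction); the correction divides by ``1 + min_len/nf``
    and floors the result at ``d_floor``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("centroids must share the same point count")
    direct = np.linalg.norm(a - b, axis=1).mean()
    flipped = np.linalg.norm(a - b[::-1], axis=1).mean()
    d_pw = min(direct, flipped)
    return float(_corrected(d_pw, streamline_length(a), streamline_length(b), p))


def distance_matrix(cs: CentroidSet, p: InterParams) -> np.ndarray:
    """All-pairs corrected centroid distances (zero diagonal)."""
    pts = cs.points
    direct = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1).mean(axis=-1)
    flipped = np.linalg.norm(pts[:, None] - pts[None, :, ::-1], axis=-1).mean(axis=-1)
    d_pw = np.minimum(direct, flipped)
    lens = cs.lengths
    d = _corrected(d_pw, lens[:, None], lens[None, :], p)
    np.fill_diagonal(d, 0.0)
    return d


def affinity_matrix(cs: CentroidSet, p: InterParams) -> np.ndarray:
    """Gaussian-kernel affinities ``exp(-d²/sigma²)``, zero beyond CAMD."""
    d = distance_matrix(cs, p)
    a = np.exp(-(d**2) / p.sigma2)
    a[d > p.camd] = 0.0
    np.fill_diagonal(a, 1.0)
    return a


def hdbscan_interclusters(
    affinity: np.ndarray, cs: CentroidSet, p: InterParams
) -> list[InterCluster]:
    """HDBSCAN clustering of centroids from the affinity structure.

    Runs on the corrected distances (zero-affinity pairs replaced by a
    sentinel beyond CAMD) with ``min_cluster_size`` tied to half the
    cohort; a post-pass removes members farther than ``d_excl`` from the
    cluster medoid.  Noise is allowed and unreported.
    """
    n_subjects = len(np.unique(cs.subject_ids))
    d = distance_matrix(cs, p)
    sentinel = max(10.0 * p.camd, float(d.max()) * 2.0 + 1.0)
    d = np.where((affinity <= 0.0) & ~np.eye(len(d), dtype=bool), sentinel, d)
    mcs = max(2, int(np.ceil(p.min_pop_frac * n_subjects)))
    if len(cs) < mcs:
        return []
    labels = HDBSCAN(
        min_cluster_size=mcs, min_samples=mcs, metric="precomputed", copy=True
    ).fit_predict(d.astype(np.float64))
    out: list[InterCluster] = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        idx = np.flatnonzero(labels == lab)
        if p.d_excl > 0 and len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            medoid = idx[sub.mean(axis=1).argmin()]
            keep = d[medoid, idx] <= p.d_excl
            idx = idx[keep]
        if len(idx) == 0:
            continue
        subs = np.unique(cs.subject_ids[idx])
        out.append(InterCluster(idx, subs, len(subs) / n_subjects))
    return out


def presence_filter(
    clusters: list[InterCluster], n_subjects: int, p: InterParams
) -> list[InterCluster]:
    """Keep clusters present in at least ``min_pop_frac`` of the cohort."""
    return [
        c for c in clusters
        if len(np.unique(c.subjects)) / n_subjects >= p.min_pop_frac
    ]


def grid_optimize(
    cs: CentroidSet,
    p: InterParams | None = None,
    nf_grid: np.ndarray | None = None,
    camd_grid: np.ndarray | None = None,
) -> tuple[tuple[float, float], np.ndarray]:
    """Scan the (nf, CAMD) grid and return the cluster-count maximizer.

    The inter-subject clustering (affinity, HDBSCAN, presence filter) is
    rerun at every grid point; the argmax of the retained-cluster count
    is returned together with the full count surface (rows = nf, cols =
    CAMD).  Ties resolve to the first grid point in row-major order.
    """
    p = p or InterParams()
    if nf_grid is None:
        nf_grid = np.linspace(1.0, 100.0, 10)
    if camd_grid is None:
        camd_grid = np.linspace(0.1, 4.0, 10)
    n_subjects = len(np.unique(cs.subject_ids))
    surface = np.zeros((len(nf_grid), len(camd_grid)), dtype=int)
    for i, nf in enumerate(nf_grid):
        for j, camd in enumerate(camd_grid):
            pij = replace(p, nf=float(nf), camd=float(camd))
            if pij.d_floor >= pij.camd:
                pij = replace(pij, d_floor=pij.camd / 2.0)
            aff = affinity_matrix(cs, pij)
            clusters = hdbscan_interclusters(aff, cs, pij)
            surface[i, j] = len(presence_filter(clusters, n_subjects, pij))
    flat = int(surface.argmax())
    i, j = np.unravel_index(flat, surface.shape)
    return (float(nf_grid[i]), float(camd_grid[j])), surface
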