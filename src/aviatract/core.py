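"""Core containers and streamline geometry.

The package works in a single canonical space: millimetres (RAS-like),
voxel centers at ``(i + 0.5) * voxel_size``, half-open voxel ownership
``[edge, edge + size)``.  Streamlines are ordered ``(n, 3)`` float arrays
of mm points; a :class:`Tractogram` is the central currency passed
between the tracking and clustering stages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tractogram",
    "streamline_length",
    "resample_streamline",
    "points_to_voxels",
    "voxel_affine",
    "mcp_distance",
    "mcp_matrix",
]


def voxel_affine(voxel_size: float) -> np.ndarray:
    """Voxel-to-mm affine for an isotropic center-aligned grid."""
    a = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    a[:3, 3] = voxel_size / 2.0
    return a


def points_to_voxels(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map mm points to integer voxel indices (nearest voxel center)."""
    inv = np.linalg.inv(affine)
    ijk = points @ inv[:3, :3].T + inv[:3, 3]
    return np.floor(ijk + 0.5).astype(np.int64)


def streamline_length(points: np.ndarray) -> float:
    """Polyline length in mm (sum of segment lengths)."""
    p = np.asarray(points, dtype=float)
    if len(p) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def resample_streamline(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` equidistant points along arc length."""
    p = np.asarray(points, dtype=float)
    if len(p) < 2:
        raise ValueError("streamline needs at least 2 points")
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("zero-length streamline cannot be resampled")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 3))
    for k in range(3):
        out[:, k] = np.interp(t, s, p[:, k])
    return out


@dataclass
class Tractogram:
    """Ordered set of streamlines with their voxel-to-mm affine.

    ``provenance`` records the subject id and the parameters that
    produced the streamlines.
    """

    streamlines: list[np.ndarray]
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([streamline_length(s) for s in self.streamlines])

    def subset(self, indices) -> "Tractogram":
        idx = np.asarray(indices)
        return Tractogram(
            [self.streamlines[i] for i in idx],
            self.affine.copy(),
            dict(self.provenance),
        )


def mcp_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean-of-mean-closest-point distance between two fibers.

    ``d(A,B) = 1/2 [ mean_a min_b |a-b| + mean_b min_a |b-a| ]`` — zero for
    identical fibers, symmetric by construction.
    """
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def mcp_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise symmetric MCP distances between two stacks of fibers.

    ``a`` is (n, m, 3), ``b`` is (k, m, 3); returns (n, k).  Squared
    point distances come from the inner-product expansion so the heavy
    step is a single matrix product.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m, _ = a.shape
    k = b.shape[0]
    na = (a**2).sum(-1)  # (n, m)
    nb = (b**2).sum(-1)  # (k, m)
    # d2[a, i, b, j] laid out so both reductions hit contiguous axes
    d2 = (a.reshape(n * m, 3) @ b.reshape(k * m, 3).T).reshape(n, m, k, m)
    d2 *= -2.0
    d2 += na.reshape(n, m, 1, 1)
    d2 += nb.reshape(1, 1, k, m)
    np.clip(d2, 0.0, None, out=d2)
    fwd = np.sqrt(d2.min(axis=3)).mean(axis=1)  # mean_a min_b
    bwd = np.sqrt(d2.min(axis=1)).mean(axis=2)  # mean_b min_a
    return 0.5 * (fwd + bwd)


def mcp_matrix(fibers: list[np.ndarray], chunk: int = 128) -> np.ndarray:
    """All-pairs symmetric mean-closest-point distance matrix.

    Fibers must share a point count (resample first if needed); computed
    in blocks to bound memory.
    """
    pts = np.asarray(fibers, dtype=float)  # (n, m, 3)
    n = len(pts)
    out = np.zeros((n, n))
    for i0 in range(0, n, chunk):
        a = pts[i0 : i0 + chunk]
        for j0 in range(i0, n, chunk):
            b = pts[j0 : j0 + chunk]
            block = mcp_block(a, b)
            out[i0 : i0 + len(a), j0 : j0 + len(b)] = block
            out[j0 : j0 + len(b), i0 : i0 + len(a)] = block.T
    np.fill_diagonal(out, 0.0)
    return out
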