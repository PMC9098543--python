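"""Unit-sphere tessellations and quasi-uniform direction sets.

Direction sets for the acquisition scheme are obtained by electrostatic
repulsion of antipodally symmetric point charges; ODF sampling uses
subdivided-icosahedron tessellations.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "icosphere",
    "vertex_neighbors",
    "electrostatic_energy",
    "disperse_directions",
]


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


@lru_cache(maxsize=8)
def icosphere(subdivisions: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Subdivided icosahedron projected to the unit sphere.

    Returns ``(vertices, faces)`` with ``10 * 4**s + 2`` vertices.
    Results are cached and returned read-only.
    """
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        verts_list = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def _mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            idx = midpoint.get(key)
            if idx is None:
                m = verts_list[a] + verts_list[b]
                m = m / np.linalg.norm(m)
                verts_list.append(m)
                idx = len(verts_list) - 1
                midpoint[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = _mid(a, b), _mid(b, c), _mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces, dtype=np.int64)
    verts = np.ascontiguousarray(verts)
    verts.setflags(write=False)
    faces.setflags(write=False)
    return verts, faces


@lru_cache(maxsize=8)
def vertex_neighbors(subdivisions: int = 3) -> np.ndarray:
    """Padded ``(n_vertices, max_degree)`` neighbor-index array (-1 = pad)."""
    verts, faces = icosphere(subdivisions)
    nbrs: list[set[int]] = [set() for _ in range(len(verts))]
    for a, b, c in faces:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    deg = max(len(s) for s in nbrs)
    out = np.full((len(verts), deg), -1, dtype=np.int32)
    for i, s in enumerate(nbrs):
        out[i, : len(s)] = sorted(s)
    out.setflags(write=False)
    return out


def electrostatic_energy(directions: np.ndarray) -> float:
    """Coulomb energy of an antipodally symmetric charge set.

    ``sum_{i<j} 1/|d_i - d_j| + 1/|d_i + d_j|`` — the quantity minimized
    when spreading diffusion-encoding directions over the half-sphere.
    """
    d = np.asarray(directions, dtype=float)
    diff = d[:, None, :] - d[None, :, :]
    summ = d[:, None, :] + d[None, :, :]
    iu = np.triu_indices(len(d), k=1)
    e = 1.0 / np.linalg.norm(diff[iu], axis=-1) + 1.0 / np.linalg.norm(summ[iu], axis=-1)
    return float(e.sum())


def _forces(d: np.ndarray) -> np.ndarray:
    diff = d[:, None, :] - d[None, :, :]
    summ = d[:, None, :] + d[None, :, :]
    nd = np.linalg.norm(diff, axis=-1)
    ns = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(nd, np.inf)
    np.fill_diagonal(ns, np.inf)
    f = (diff / nd[..., None] ** 3).sum(axis=1) + (summ / ns[..., None] ** 3).sum(axis=1)
    # keep only the tangential component
    f -= (f * d).sum(axis=1, keepdims=True) * d
    return f


def disperse_directions(
    n: int, seed: int = 0, n_iter: int = 400, step0: float = 0.05
) -> np.ndarray:
    """Quasi-uniform antipodally symmetric unit directions.

    Projected-gradient descent on the electrostatic energy with a
    backtracking step size; deterministic for a given ``seed`` and
    monotonically non-increasing in energy.
    """
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    energy = electrostatic_energy(d)
    step = step0
    for _ in range(n_iter):
        f = _forces(d)
        fmax = np.abs(f).max()
        if fmax == 0:
            break
        cand = d + step * f / fmax
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        e_cand = electrostatic_energy(cand)
        if e_cand < energy:
            d, energy = cand, e_cand
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return d
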