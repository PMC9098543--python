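"""Streamline-regularized deterministic (SRD) tractography.

From every seed the tracker integrates forward and backward through the
ODF field.  At each step the candidate direction is the ODF peak
(trilinearly interpolated SH coefficients, evaluated on a tessellation)
closest to the previous direction within the aperture cone; the update
blends it with the previous direction,

    d = normalize((1 - w) * d_odf + w * d_prev),
    w = clamp(1 - GFA(x) / theta, 0, 1),

so tracking is ODF-driven in anisotropic tissue and inertia-driven where
GFA falls below the regularization factor theta.  Streamlines stop at
the mask boundary (no anisotropy stopping threshold) or when no in-cone
peak exists; when w saturates (GFA ~ 0) propagation continues straight.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import Tractogram
from .local_models import ScalarMap, SHCoeffField
from .sh import real_sym_sh_basis
from .sphere import icosphere, vertex_neighbors

__all__ = [
    "TrackingParams",
    "seed_voxels",
    "track_srd",
    "population_length_window",
]

# regularization weight above which the ODF is no longer consulted
_W_STRAIGHT = 1.0 - 1e-3


@dataclass
class TrackingParams:
    """SRD tracking parameters (defaults follow the acquisition protocol)."""

    seeds_per_voxel: int = 8
    aperture_deg: float = 30.0
    step: float = 0.05  # mm
    length_range: tuple[float, float] = (0.1, 100.0)  # mm
    gfa_reg_threshold: float = 0.12
    rng_seed: int = 0

    def validate(self, voxel_size: float) -> None:
        if not (0.0 < self.step < voxel_size):
            raise ValueError("step must lie in (0, voxel_size)")
        if not (0.0 < self.aperture_deg < 90.0):
            raise ValueError("aperture_deg must lie in (0, 90)")


def seed_voxels(
    mask: np.ndarray, voxel_size: float, params: TrackingParams
) -> np.ndarray:
    """Uniform random seed points, ``seeds_per_voxel`` per mask voxel.

    Deterministic given ``params.rng_seed``; seeds respect the half-open
    voxel ownership ``[edge, edge + size)``.
    """
    mask = np.asarray(mask, dtype=bool)
    vox = np.argwhere(mask)
    if len(vox) == 0:
        raise ValueError("empty mask")
    rng = np.random.default_rng(params.rng_seed)
    offs = rng.random((len(vox), params.seeds_per_voxel, 3))
    pts = (vox[:, None, :] + offs) * voxel_size
    return pts.reshape(-1, 3)


@njit(cache=True)
def _trilinear(field4, p, vs, out):
    nx, ny, nz, nc = field4.shape
    ux = p[0] / vs - 0.5
    uy = p[1] / vs - 0.5
    uz = p[2] / vs - 0.5
    i = int(np.floor(ux))
    j = int(np.floor(uy))
    k = int(np.floor(uz))
    fx = ux - i
    fy = uy - j
    fz = uz - k
    if i < 0:
        i, fx = 0, 0.0
    if j < 0:
        j, fy = 0, 0.0
    if k < 0:
        k, fz = 0, 0.0
    if i > nx - 2:
        i, fx = nx - 2, 1.0
    if j > ny - 2:
        j, fy = ny - 2, 1.0
    if k > nz - 2:
        k, fz = nz - 2, 1.0
    for c in range(nc):
        out[c] = 0.0
    for di in range(2):
        wx = fx if di == 1 else 1.0 - fx
        for dj in range(2):
            wy = fy if dj == 1 else 1.0 - fy
            for dk in range(2):
                wz = fz if dk == 1 else 1.0 - fz
                w = wx * wy * wz
                if w > 0.0:
                    for c in range(nc):
                        out[c] += w * field4[i + di, j + dj, k + dk, c]


@njit(cache=True)
def _track_half(
    p0, d0, coeffs, gfa1, mask, vs, B, verts, nbrs, cone,
    step, cos_ap, theta, max_steps, buf, cbuf, gbuf, vals,
):
    nvert = verts.shape[0]
    ncoef = B.shape[1]
    buf[0, 0] = p0[0]
    buf[0, 1] = p0[1]
    buf[0, 2] = p0[2]
    d = np.empty(3)
    d[0], d[1], d[2] = d0[0], d0[1], d0[2]
    p = np.empty(3)
    p[0], p[1], p[2] = p0[0], p0[1], p0[2]
    n = 1
    vi = 0
    best = -2.0
    for v in range(nvert):
        dd = abs(verts[v, 0] * d[0] + verts[v, 1] * d[1] + verts[v, 2] * d[2])
        if dd > best:
            best = dd
            vi = v
    while n <= max_steps:
        _trilinear(gfa1, p, vs, gbuf)
        w = 1.0 - gbuf[0] / theta
        if w < 0.0:
            w = 0.0
        elif w > 1.0:
            w = 1.0
        if w < _W_STRAIGHT:
            _trilinear(coeffs, p, vs, cbuf)
            # hill-climb the cached vertex toward the current direction
            for _ in range(12):
                moved = False
                bi = vi
                bd = abs(verts[vi, 0] * d[0] + verts[vi, 1] * d[1] + verts[vi, 2] * d[2])
                for q in range(nbrs.shape[1]):
                    j = nbrs[vi, q]
                    if j < 0:
                        break
                    dd = abs(verts[j, 0] * d[0] + verts[j, 1] * d[1] + verts[j, 2] * d[2])
                    if dd > bd:
                        bd = dd
                        bi = j
                        moved = True
                vi = bi
                if not moved:
                    break
            # ODF values on the cone around vi
            kk = 0
            for q in range(cone.shape[1]):
                j = cone[vi, q]
                if j < 0:
                    break
                s = 0.0
                for c in range(ncoef):
                    s += B[j, c] * cbuf[c]
                vals[j] = s
                kk += 1
            # best in-cone local maximum, closest to the previous direction
            jbest = -1
            sbest = 1.0
            bestdot = cos_ap
            for q in range(cone.shape[1]):
                j = cone[vi, q]
                if j < 0:
                    break
                dot = verts[j, 0] * d[0] + verts[j, 1] * d[1] + verts[j, 2] * d[2]
                adot = abs(dot)
                if adot < cos_ap or adot < bestdot:
                    continue
                ismax = True
                for r in range(nbrs.shape[1]):
                    jn = nbrs[j, r]
                    if jn < 0:
                        break
                    if vals[jn] > vals[j]:
                        ismax = False
                        break
                if ismax:
                    jbest = j
                    bestdot = adot
                    sbest = 1.0 if dot >= 0.0 else -1.0
            if jbest < 0:
                break  # no in-cone peak
            # weighted-neighbour refinement of the peak direction
            minv = vals[jbest]
            for r in range(nbrs.shape[1]):
                jn = nbrs[jbest, r]
                if jn < 0:
                    break
                if vals[jn] < minv:
                    minv = vals[jn]
            rx = (vals[jbest] - minv) * sbest * verts[jbest, 0]
            ry = (vals[jbest] - minv) * sbest * verts[jbest, 1]
            rz = (vals[jbest] - minv) * sbest * verts[jbest, 2]
            for r in range(nbrs.shape[1]):
                jn = nbrs[jbest, r]
                if jn < 0:
                    break
                wv = vals[jn] - minv
                sg = 1.0
                if (
                    verts[jn, 0] * verts[jbest, 0]
                    + verts[jn, 1] * verts[jbest, 1]
                    + verts[jn, 2] * verts[jbest, 2]
                ) < 0.0:
                    sg = -1.0
                rx += wv * sg * sbest * verts[jn, 0]
                ry += wv * sg * sbest * verts[jn, 1]
                rz += wv * sg * sbest * verts[jn, 2]
            rn = np.sqrt(rx * rx + ry * ry + rz * rz)
            if rn > 0.0:
                rx /= rn
                ry /= rn
                rz /= rn
                if rx * d[0] + ry * d[1] + rz * d[2] < cos_ap:
                    rx = sbest * verts[jbest, 0]
                    ry = sbest * verts[jbest, 1]
                    rz = sbest * verts[jbest, 2]
            else:
                rx = sbest * verts[jbest, 0]
                ry = sbest * verts[jbest, 1]
                rz = sbest * verts[jbest, 2]
            dx = (1.0 - w) * rx + w * d[0]
            dy = (1.0 - w) * ry + w * d[1]
            dz = (1.0 - w) * rz + w * d[2]
            dn = np.sqrt(dx * dx + dy * dy + dz * dz)
            if dn == 0.0:
                break
            d[0], d[1], d[2] = dx / dn, dy / dn, dz / dn
        # else: saturated regularization -> straight propagation
        px = p[0] + step * d[0]
        py = p[1] + step * d[1]
        pz = p[2] + step * d[2]
        i = int(np.floor(px / vs))
        j = int(np.floor(py / vs))
        k = int(np.floor(pz / vs))
        if (
            i < 0 or j < 0 or k < 0
            or i >= mask.shape[0] or j >= mask.shape[1] or k >= mask.shape[2]
            or mask[i, j, k] == 0
        ):
            break
        p[0], p[1], p[2] = px, py, pz
        buf[n, 0], buf[n, 1], buf[n, 2] = px, py, pz
        n += 1
    return n


@njit(cache=True)
def _track_batch(
    seeds, coeffs, gfa1, mask, vs, B, verts, nbrs, cone,
    step, cos_ap, theta, max_steps, out, out_n,
):
    nvert = verts.shape[0]
    ncoef = B.shape[1]
    cbuf = np.empty(ncoef)
    gbuf = np.empty(1)
    vals = np.empty(nvert)
    fbuf = np.empty((max_steps + 1, 3))
    bbuf = np.empty((max_steps + 1, 3))
    d0 = np.empty(3)
    for s in range(seeds.shape[0]):
        p0 = seeds[s]
        i = int(np.floor(p0[0] / vs))
        j = int(np.floor(p0[1] / vs))
        k = int(np.floor(p0[2] / vs))
        if (
            i < 0 or j < 0 or k < 0
            or i >= mask.shape[0] or j >= mask.shape[1] or k >= mask.shape[2]
            or mask[i, j, k] == 0
        ):
            out_n[s] = 0
            continue
        # first step uses the global ODF maximum at the seed
        _trilinear(coeffs, p0, vs, cbuf)
        best = -1.0e300
        bi = 0
        for v in range(nvert):
            val = 0.0
            for c in range(ncoef):
                val += B[v, c] * cbuf[c]
            if val > best:
                best = val
                bi = v
        d0[0], d0[1], d0[2] = verts[bi, 0], verts[bi, 1], verts[bi, 2]
        nf = _track_half(
            p0, d0, coeffs, gfa1, mask, vs, B, verts, nbrs, cone,
            step, cos_ap, theta, max_steps, fbuf, cbuf, gbuf, vals,
        )
        d0[0], d0[1], d0[2] = -d0[0], -d0[1], -d0[2]
        nb = _track_half(
            p0, d0, coeffs, gfa1, mask, vs, B, verts, nbrs, cone,
            step, cos_ap, theta, max_steps, bbuf, cbuf, gbuf, vals,
        )
        # backward half reversed, seed point deduplicated, then forward
        m = 0
        for q in range(nb - 1, 0, -1):
            out[s, m, 0] = bbuf[q, 0]
            out[s, m, 1] = bbuf[q, 1]
            out[s, m, 2] = bbuf[q, 2]
            m += 1
        for q in range(nf):
            out[s, m, 0] = fbuf[q, 0]
            out[s, m, 1] = fbuf[q, 1]
            out[s, m, 2] = fbuf[q, 2]
            m += 1
        out_n[s] = m


def _cone_indices(verts: np.ndarray, aperture_deg: float, margin_deg: float = 14.0):
    cosc = np.cos(np.deg2rad(aperture_deg + margin_deg))
    adot = np.abs(verts @ verts.T) >= cosc
    counts = adot.sum(axis=1)
    out = np.full((len(verts), counts.max()), -1, dtype=np.int32)
    for i in range(len(verts)):
        idx = np.flatnonzero(adot[i])
        out[i, : len(idx)] = idx
    return out


def track_srd(
    odf: SHCoeffField,
    gfa: ScalarMap,
    mask: np.ndarray,
    seeds: np.ndarray,
    params: TrackingParams,
    tess_subdiv: int = 3,
    chunk: int = 256,
) -> Tractogram:
    """Whole-mask SRD tracking from the given seed points.

    Seeds that produce no streamline within the length range are
    silently dropped (count recorded in the tractogram provenance).
    """
    vs = float(odf.affine[0, 0])
    params.validate(vs)
    verts, _ = icosphere(tess_subdiv)
    nbrs = vertex_neighbors(tess_subdiv)
    cone = _cone_indices(verts, params.aperture_deg)
    b = real_sym_sh_basis(odf.order, verts)
    coeffs = np.ascontiguousarray(odf.coeffs, dtype=np.float64)
    gfa1 = np.ascontiguousarray(gfa.data[..., None], dtype=np.float64)
    mask8 = np.ascontiguousarray(mask, dtype=np.uint8)
    seeds = np.ascontiguousarray(seeds, dtype=np.float64)
    cos_ap = np.cos(np.deg2rad(params.aperture_deg))
    max_steps = int(np.ceil(params.length_range[1] / params.step))

    streamlines: list[np.ndarray] = []
    n_dropped = 0
    lo, hi = params.length_range
    out = np.empty((min(chunk, len(seeds)), 2 * max_steps + 1, 3))
    out_n = np.empty(min(chunk, len(seeds)), dtype=np.int64)
    for s0 in range(0, len(seeds), chunk):
        sl = seeds[s0 : s0 + chunk]
        _track_batch(
            sl, coeffs, gfa1, mask8, vs,
            np.ascontiguousarray(b), np.ascontiguousarray(verts),
            nbrs, cone,
            params.step, cos_ap, params.gfa_reg_threshold, max_steps,
            out[: len(sl)], out_n[: len(sl)],
        )
        for i in range(len(sl)):
            n = out_n[i]
            if n < 2:
                n_dropped += 1
                continue
            length = params.step * (n - 1)
            if not (lo - 1e-9 <= length <= hi + 1e-9):
                n_dropped += 1
                continue
            streamlines.append(out[i, :n].copy())
    return Tractogram(
        streamlines,
        odf.affine.copy(),
        {
            "method": "SRD",
            "params": vars(params).copy(),
            "n_seeds": len(seeds),
            "n_dropped": n_dropped,
        },
    )


def population_length_window(
    tractograms: list[Tractogram], lo_pct: float = 2.0, hi_pct: float = 98.0
) -> tuple[float, float]:
    """2nd/98th percentile window of the pooled fiber-length histogram.

    Lengths of all subjects are pooled; the bounds come from linear
    interpolation of the empirical CDF.
    """
    lengths = np.concatenate([t.lengths() for t in tractograms]) if tractograms else np.array([])
    if lengths.size == 0:
        raise ValueError("no streamlines to pool")
    lo, hi = np.percentile(lengths, [lo_pct, hi_pct])
    return float(lo), float(hi)
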