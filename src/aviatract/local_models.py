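"""Per-voxel diffusion models: DTI and the analytical Q-ball ODF.

The Q-ball reconstruction decomposes the normalized single-shell signal
onto a real symmetric spherical-harmonics basis with Laplace-Beltrami
regularization and applies the Funk-Radon transform analytically
(degree-l coefficients scaled by ``2*pi*P_l(0)``), yielding a per-voxel
diffusion ODF.  Rotationally invariant maps (ADC, FA, AD, RD from the
tensor; GFA from the ODF) and the color-encoded direction map derive
from these fields.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import DWIStack
from .sh import frt_scaling, n_coeffs, real_sym_sh_basis, sh_degrees
from .sphere import icosphere, vertex_neighbors

__all__ = [
    "TensorField",
    "SHCoeffField",
    "ScalarMap",
    "fit_dti",
    "tensor_maps",
    "fit_sh",
    "fit_aqbi",
    "sample_odf",
    "gfa_from_samples",
    "gfa_map",
    "peak_directions",
    "ced_map",
    "percentile_threshold",
]

log = logging.getLogger(__name__)

# coefficient order of the symmetric tensor: xx, yy, zz, xy, xz, yz
_TRI = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (6 coefficients) + ln S0."""

    coeffs: np.ndarray  # (x, y, z, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    ln_s0: np.ndarray  # (x, y, z)
    mask: np.ndarray
    affine: np.ndarray

    def tensors(self) -> np.ndarray:
        """Full (x, y, z, 3, 3) symmetric tensor array."""
        t = np.zeros(self.coeffs.shape[:-1] + (3, 3))
        for c, (i, j) in enumerate(_TRI):
            t[..., i, j] = self.coeffs[..., c]
            t[..., j, i] = self.coeffs[..., c]
        return t


@dataclass
class SHCoeffField:
    """Per-voxel ODF spherical-harmonic coefficients (even degrees only)."""

    coeffs: np.ndarray  # (x, y, z, n_coeffs)
    order: int
    mask: np.ndarray
    affine: np.ndarray
    basis: str = "real_symmetric"

    def __post_init__(self) -> None:
        if self.coeffs.shape[-1] != n_coeffs(self.order):
            raise ValueError("coefficient count inconsistent with SH order")


@dataclass
class ScalarMap:
    """A named per-voxel scalar volume (ADC, FA, AD, RD or GFA)."""

    data: np.ndarray
    affine: np.ndarray
    name: str


def _dti_design(scheme) -> np.ndarray:
    g, b = scheme.bvecs, scheme.bvals
    x = np.column_stack(
        [
            np.ones(len(b)),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError("gradient scheme is rank-deficient for a tensor fit")
    return x


def fit_dti(dwi: DWIStack) -> TensorField:
    """Log-linear least-squares tensor fit inside the mask.

    Solves ``ln S = ln S0 - b g^T D g`` per voxel; non-positive signals
    are clamped to ``1e-6 * S0`` before the log.
    """
    x = _dti_design(dwi.scheme)
    pinv = np.linalg.pinv(x)
    sig = dwi.data[dwi.mask]
    s0 = dwi.mean_b0()[dwi.mask]
    eps = 1e-6 * np.where(s0 > 0, s0, 1.0)[:, None]
    lns = np.log(np.maximum(sig, eps))
    params = lns @ pinv.T  # (n_voxels, 7)
    coeffs = np.zeros(dwi.data.shape[:3] + (6,))
    ln_s0 = np.zeros(dwi.data.shape[:3])
    coeffs[dwi.mask] = params[:, 1:]
    ln_s0[dwi.mask] = params[:, 0]
    return TensorField(coeffs, ln_s0, dwi.mask.copy(), dwi.affine.copy())


def tensor_maps(t: TensorField) -> dict[str, ScalarMap]:
    """ADC / FA / AD / RD maps from the tensor eigenvalues.

    Eigenvalues are sorted descending; negative ones are clamped to zero
    (count logged).  ``FA = sqrt(3/2) ||lam - mean|| / ||lam||``.
    """
    lam = np.linalg.eigvalsh(t.tensors()[t.mask])[:, ::-1]
    n_neg = int((lam < 0).sum())
    if n_neg:
        log.info("tensor_maps: clamped %d negative eigenvalues to 0", n_neg)
    lam = np.clip(lam, 0.0, None)
    mean = lam.mean(axis=1)
    norm = np.linalg.norm(lam, axis=1)
    dev = np.linalg.norm(lam - mean[:, None], axis=1)
    fa = np.where(norm > 0, np.sqrt(1.5) * dev / np.where(norm > 0, norm, 1.0), 0.0)
    out = {}
    for name, vals in (
        ("ADC", mean),
        ("FA", fa),
        ("AD", lam[:, 0]),
        ("RD", 0.5 * (lam[:, 1] + lam[:, 2])),
    ):
        vol = np.zeros(t.mask.shape)
        vol[t.mask] = vals
        out[name] = ScalarMap(vol, t.affine.copy(), name)
    return out


def fit_sh(
    signals: np.ndarray, directions: np.ndarray, order: int, lam: float
) -> np.ndarray:
    """Regularized least-squares SH fit of signals sampled on the sphere.

    ``c = (B^T B + lam * L²)^-1 B^T s`` with ``L = diag(l(l+1))``
    (Laplace-Beltrami smoothness penalty).
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    b = real_sym_sh_basis(order, directions)
    if b.shape[0] < b.shape[1]:
        raise ValueError(
            f"{b.shape[0]} directions cannot determine {b.shape[1]} coefficients"
        )
    l = sh_degrees(order)
    reg = np.diag((l * (l + 1.0)) ** 2)
    m = np.linalg.solve(b.T @ b + lam * reg, b.T)
    return np.atleast_2d(signals) @ m.T


def fit_aqbi(dwi: DWIStack, order: int = 8, lam: float = 0.006) -> SHCoeffField:
    """Analytical Q-ball: per-voxel ODF SH coefficients inside the mask.

    Steps per voxel: normalize the diffusion-weighted signal by the mean
    b=0 intensity, fit the SH coefficients with Laplace-Beltrami
    regularization, then apply the Funk-Radon transform analytically.
    """
    dirs = dwi.scheme.directions  # single shell enforced by GradientScheme
    sig = dwi.data[dwi.mask][:, ~dwi.scheme.b0_mask]
    s0 = dwi.mean_b0()[dwi.mask]
    s0 = np.where(s0 > 0, s0, 1.0)
    csig = fit_sh(sig / s0[:, None], dirs, order, lam)
    codf = csig * frt_scaling(order)
    coeffs = np.zeros(dwi.data.shape[:3] + (n_coeffs(order),))
    coeffs[dwi.mask] = codf
    return SHCoeffField(coeffs, order, dwi.mask.copy(), dwi.affine.copy())


def sample_odf(field: SHCoeffField, vertices: np.ndarray) -> np.ndarray:
    """Evaluate the ODF on a tessellation, for masked voxels only.

    Returns ``(n_mask_voxels, n_vertices)`` in mask scan order.
    """
    b = real_sym_sh_basis(field.order, vertices)
    return field.coeffs[field.mask] @ b.T


def gfa_from_samples(values: np.ndarray) -> np.ndarray:
    """Generalized fractional anisotropy of ODF samples (last axis).

    ``GFA = std / rms`` with the sample (n-1) standard deviation; zero
    for an all-zero ODF.  Values are min-shifted to be non-negative
    first, since the Funk-Radon transform can produce small negatives.
    """
    v = np.asarray(values, dtype=float)
    shift = np.clip(v.min(axis=-1, keepdims=True), None, 0.0)
    v = v - shift
    rms = np.sqrt((v**2).mean(axis=-1))
    std = v.std(axis=-1, ddof=1)
    return np.where(rms > 0, std / np.where(rms > 0, rms, 1.0), 0.0)


def gfa_map(field: SHCoeffField, tessellation: np.ndarray | None = None) -> ScalarMap:
    """GFA map of an ODF field, sampled on a dense quasi-uniform sphere."""
    if tessellation is None:
        tessellation = icosphere(4)[0]
    if len(tessellation) < 100:
        raise ValueError("tessellation must have at least 100 points")
    vals = sample_odf(field, tessellation)
    out = np.zeros(field.mask.shape)
    out[field.mask] = gfa_from_samples(vals)
    return ScalarMap(out, field.affine.copy(), "GFA")


def peak_directions(
    odf_values: np.ndarray,
    vertices: np.ndarray,
    neighbors: np.ndarray,
    rel_threshold: float = 0.25,
    min_sep_deg: float = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """ODF maxima on a tessellation with non-max suppression.

    Local maxima (value >= every tessellation neighbor) are min-shifted,
    thresholded at ``rel_threshold`` of the global maximum and greedily
    deduplicated so that retained peak axes are at least ``min_sep_deg``
    apart (antipodal directions count as one axis).  Returns unit
    directions and their ODF values, strongest first.
    """
    v = np.asarray(odf_values, dtype=float)
    v = v - min(v.min(), 0.0)
    pad = np.where(neighbors >= 0, v[np.clip(neighbors, 0, None)], -np.inf)
    is_max = v >= pad.max(axis=1)
    is_max &= v >= rel_threshold * v.max()
    idx = np.flatnonzero(is_max)
    idx = idx[np.argsort(v[idx])[::-1]]
    cos_sep = np.cos(np.deg2rad(min_sep_deg))
    dirs: list[np.ndarray] = []
    vals: list[float] = []
    for i in idx:
        d = vertices[i]
        if any(abs(d @ e) >= cos_sep for e in dirs):
            continue
        dirs.append(d)
        vals.append(v[i])
    return np.asarray(dirs).reshape(-1, 3), np.asarray(vals)


def ced_map(field: SHCoeffField, gfa: ScalarMap, tess_subdiv: int = 4) -> np.ndarray:
    """Color-encoded direction map: RGB = |principal ODF axis| * GFA."""
    verts, _ = icosphere(tess_subdiv)
    nbrs = vertex_neighbors(tess_subdiv)
    vals = sample_odf(field, verts)
    rgb = np.zeros(field.mask.shape + (3,))
    coords = np.argwhere(field.mask)
    for row, (i, j, k) in enumerate(coords):
        dirs, _ = peak_directions(vals[row], verts, nbrs)
        if len(dirs):
            rgb[i, j, k] = np.abs(dirs[0]) * gfa.data[i, j, k]
    return rgb


def percentile_threshold(map_: ScalarMap, mask: np.ndarray, pct: float) -> float:
    """Value below which ``pct`` % of in-mask voxels fall (linear CDF).

    This is the rule used both for the 98% GFA threshold that sets the
    tracking regularization factor and (on pooled fiber lengths) for the
    population length window.
    """
    if not (0.0 < pct < 100.0):
        raise ValueError("pct must lie strictly between 0 and 100")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(np.percentile(map_.data[mask], pct))
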