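"""Synthetic ex vivo DWI phantom: tissue grid, planted bundles, signal model.

Emulates the statistical structure of the quail acquisition the pipeline
was designed for: a single-shell HARDI scheme (75 directions + 5 b=0 at
b = 4500 s/mm²), a 0.2 mm isotropic grid, three tissue ADC modes
(GM/WM/CSF) and Rician noise, with tube-shaped white-matter bundles of
known geometry providing ground-truth streamlines for every downstream
stage.

ADC defaults are on the 1e-4 mm²/s scale, the physically sensible ex
vivo regime at this b-value (b·D of order 1-3).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Tractogram, points_to_voxels, resample_streamline, voxel_affine
from .gradients import GradientScheme

__all__ = [
    "REGION_LH",
    "REGION_RH",
    "REGION_INT",
    "REGION_CBL",
    "TissueCompartment",
    "BundleGeometry",
    "PhantomSpec",
    "GroundTruth",
    "default_compartments",
    "default_phantom_spec",
    "build_phantom",
    "simulate_dwi",
    "single_tensor_signal",
    "wm_eigenvalues",
]

# region label codes used throughout the clustering stages
REGION_LH, REGION_RH, REGION_INT, REGION_CBL = 1, 2, 3, 4

# tissue codes inside the phantom grid
_BG, _GM, _WM, _CSF = 0, 1, 2, 3


@dataclass
class TissueCompartment:
    """One diffusion compartment: label, mean diffusivity and anisotropy."""

    label: str  # "GM" | "WM" | "CSF"
    adc: float  # mm^2/s
    fa: float = 0.0
    principal_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.adc <= 0:
            raise ValueError("adc must be positive")
        if not (0.0 <= self.fa < 1.0):
            raise ValueError("fa must lie in [0, 1)")
        if self.principal_direction is None and self.fa != 0.0:
            raise ValueError("isotropic compartments must have fa = 0")


@dataclass
class BundleGeometry:
    """A planted tube bundle: centerline, radius and fiber population."""

    name: str
    centerline: np.ndarray  # (k, 3) mm
    radius: float  # mm
    fiber_count: int
    region: str = "LH"  # {"LH", "RH", "INT", "CBL"}

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.fiber_count < 1:
            raise ValueError("fiber_count must be >= 1")


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 0.2  # mm, isotropic
    compartments: list[TissueCompartment] = field(default_factory=lambda: default_compartments())
    bundles: list[BundleGeometry] = field(default_factory=list)
    snr: float | None = 30.0  # at b=0; None or inf -> noiseless
    seed: int = 0
    s0: float = 1000.0
    wm_axial_ratio: float = 5.0  # lambda_par / lambda_perp at fixed trace
    mask_radii_mm: tuple[float, float, float] | None = None  # ellipsoid; None -> full grid
    csf_balls: list[tuple[tuple[float, float, float], float]] = field(default_factory=list)
    cbl_y_frac: float = 0.68  # y >= frac * extent -> cerebellum label

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def affine(self) -> np.ndarray:
        return voxel_affine(self.voxel_size)

    def compartment(self, label: str) -> TissueCompartment:
        for c in self.compartments:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass
class GroundTruth:
    """Planted truth of one subject: streamlines, labels, mask, tissue grid."""

    streamlines: Tractogram
    bundle_of_streamline: np.ndarray  # (n_streamlines,) bundle index
    region_labels: np.ndarray  # int volume, 0 = unlabeled
    brain_mask: np.ndarray  # bool volume
    tissue: np.ndarray  # int volume (0 bg, 1 GM, 2 WM, 3 CSF)
    fiber_dirs: np.ndarray  # (X, Y, Z, 2, 3) unit dirs, NaN where absent
    n_fiber_dirs: np.ndarray  # (X, Y, Z) count of planted dirs (0..2)
    affine: np.ndarray


def default_compartments() -> list[TissueCompartment]:
    """The three ADC tissue modes (GM / WM / CSF) in mm²/s."""
    return [
        TissueCompartment("GM", 3.0e-4),
        TissueCompartment("WM", 2.3e-4),
        TissueCompartment("CSF", 6.5e-4),
    ]


def wm_eigenvalues(adc: float, axial_ratio: float) -> tuple[float, float]:
    """(lambda_parallel, lambda_perp) of the axially symmetric WM tensor.

    Trace is fixed at ``3 * adc`` and the axial/radial ratio at
    ``axial_ratio``.
    """
    lam_perp = 3.0 * adc / (axial_ratio + 2.0)
    return axial_ratio * lam_perp, lam_perp


def default_phantom_spec(seed: int = 0, snr: float | None = 30.0) -> PhantomSpec:
    """The package's reference synthetic subject.

    32³ grid at 0.2 mm with an ellipsoidal brain mask, three
    well-separated bundles (one per hemisphere plus one in the
    cerebellar slab), a small CSF pocket and Rician noise at the given
    SNR.
    """
    b_lh = BundleGeometry(
        "lh_long", np.array([[2.2, 1.4, 3.2], [2.2, 4.0, 3.2]]), 0.3, 60, "LH"
    )
    b_rh = BundleGeometry(
        "rh_long", np.array([[4.2, 1.4, 3.2], [4.2, 4.0, 3.2]]), 0.3, 60, "RH"
    )
    b_cbl = BundleGeometry(
        "cbl_trans", np.array([[2.2, 4.6, 3.2], [4.2, 4.6, 3.2]]), 0.3, 60, "CBL"
    )
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        voxel_size=0.2,
        bundles=[b_lh, b_rh, b_cbl],
        snr=snr,
        seed=seed,
        mask_radii_mm=(2.0, 2.2, 1.6),
        csf_balls=[((3.2, 2.2, 3.2), 0.4)],
    )


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.grid_shape).reshape(3, -1).T
    return (idx + 0.5) * spec.voxel_size


def _densify(centerline: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    n = max(2, int(np.ceil(seg.sum() / spacing)) + 1)
    return resample_streamline(centerline, n)


def _closest_on_polyline(points: np.ndarray, poly: np.ndarray):
    """Distance to a polyline and unit tangent at the closest segment."""
    a, b = poly[:-1], poly[1:]
    ab = b - a
    ab2 = (ab**2).sum(axis=1)
    # projection parameter of every point on every segment, clipped
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    k = d.argmin(axis=1)
    tang = ab[k] / np.sqrt(ab2[k])[:, None]
    return d[np.arange(len(points)), k], tang


def _parallel_frames(poly: np.ndarray):
    """Parallel-transported normal frames (n1, n2) along a polyline."""
    t = np.diff(poly, axis=0)
    t = np.vstack([t, t[-1]])
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = np.empty_like(t)
    n1[0] = np.cross(t[0], ref)
    n1[0] /= np.linalg.norm(n1[0])
    for i in range(1, len(t)):
        v = n1[i - 1] - (n1[i - 1] @ t[i]) * t[i]
        n1[i] = v / np.linalg.norm(v)
    n2 = np.cross(t, n1)
    return t, n1, n2


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Rasterize the spec's bundles into a tissue grid with ground truth.

    Tube voxels become WM with the local centerline tangent as planted
    direction; voxels claimed by two bundles with distinct directions
    become crossings carrying both.  ``fiber_count`` streamlines per
    bundle run parallel to the centerline inside the tube radius with a
    seeded jitter.
    """
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_size
    extent = np.asarray(shape) * vs
    for b in spec.bundles:
        if np.any(b.centerline < 0) or np.any(b.centerline >= extent):
            raise ValueError(f"bundle '{b.name}' centerline leaves the grid")

    centers = _voxel_centers(spec)
    if spec.mask_radii_mm is None:
        mask = np.ones(shape, dtype=bool)
    else:
        c0 = extent / 2.0
        r = np.asarray(spec.mask_radii_mm, dtype=float)
        mask = (((centers - c0) / r) ** 2).sum(axis=1).reshape(shape) <= 1.0

    tissue = np.where(mask, _GM, _BG).astype(np.int16)
    for (cx, cy, cz), rad in spec.csf_balls:
        ball = np.linalg.norm(centers - [cx, cy, cz], axis=1).reshape(shape) <= rad
        tissue[ball & mask] = _CSF

    fiber_dirs = np.full(shape + (2, 3), np.nan)
    n_dirs = np.zeros(shape, dtype=np.int8)

    rng = np.random.default_rng([spec.seed, 0xA11])
    streamlines: list[np.ndarray] = []
    bundle_idx: list[int] = []

    for bi, b in enumerate(spec.bundles):
        poly = _densify(b.centerline, vs / 4.0)
        near = np.abs(centers - (poly.min(0) + poly.max(0)) / 2.0)
        box = (near <= (poly.max(0) - poly.min(0)) / 2.0 + b.radius + vs).all(axis=1)
        d, tang = _closest_on_polyline(centers[box], poly)
        inside = d <= b.radius
        flat = np.flatnonzero(box)[inside]
        for v, t in zip(flat, tang[inside]):
            ijk = np.unravel_index(v, shape)
            _add_direction(tissue, fiber_dirs, n_dirs, ijk, t)

        # streamlines: centerline offset within the tube cross-section
        t, n1, n2 = _parallel_frames(poly)
        fine = _densify(b.centerline, vs / 2.0)
        tf, nf1, nf2 = _parallel_frames(fine)
        u = rng.random(b.fiber_count)
        ang = rng.random(b.fiber_count) * 2 * np.pi
        rr = b.radius * 0.9 * np.sqrt(u)
        for i in range(b.fiber_count):
            off1, off2 = rr[i] * np.cos(ang[i]), rr[i] * np.sin(ang[i])
            sl = fine + off1 * nf1 + off2 * nf2
            streamlines.append(sl)
            bundle_idx.append(bi)

    # guarantee the mask (and a planted direction) under every streamline point
    for sl, bi in zip(streamlines, bundle_idx):
        vox = points_to_voxels(sl, spec.affine)
        vox = np.clip(vox, 0, np.asarray(shape) - 1)
        segs = np.diff(sl, axis=0)
        segs = np.vstack([segs, segs[-1]])
        segs /= np.linalg.norm(segs, axis=1, keepdims=True)
        for (i, j, k), t in zip(vox, segs):
            mask[i, j, k] = True
            if tissue[i, j, k] in (_BG, _GM, _CSF) and n_dirs[i, j, k] == 0:
                _add_direction(tissue, fiber_dirs, n_dirs, (i, j, k), t)

    region = np.zeros(shape, dtype=np.int16)
    y_mm = centers[:, 1].reshape(shape)
    x_mm = centers[:, 0].reshape(shape)
    region[mask] = np.where(x_mm[mask] < extent[0] / 2.0, REGION_LH, REGION_RH)
    region[mask & (y_mm >= spec.cbl_y_frac * extent[1])] = REGION_CBL

    tg = Tractogram(streamlines, spec.affine, {"source": "phantom", "seed": spec.seed})
    return GroundTruth(
        streamlines=tg,
        bundle_of_streamline=np.asarray(bundle_idx, dtype=int),
        region_labels=region,
        brain_mask=mask,
        tissue=tissue,
        fiber_dirs=fiber_dirs,
        n_fiber_dirs=n_dirs,
        affine=spec.affine,
    )


def _add_direction(tissue, fiber_dirs, n_dirs, ijk, t) -> None:
    """Record a planted fiber direction, promoting the voxel to WM.

    A voxel already holding a (anti)parallel direction keeps it; a
    genuinely different direction is stored as a second population
    (crossing voxel), never an error.
    """
    i, j, k = ijk
    tissue[i, j, k] = _WM
    n = n_dirs[i, j, k]
    for q in range(n):
        if abs(fiber_dirs[i, j, k, q] @ t) > np.cos(np.deg2rad(15.0)):
            return
    if n < 2:
        fiber_dirs[i, j, k, n] = t
        n_dirs[i, j, k] = n + 1


def single_tensor_signal(
    scheme: GradientScheme,
    adc: float,
    direction: np.ndarray | None = None,
    axial_ratio: float = 1.0,
    s0: float = 1000.0,
) -> np.ndarray:
    """Noiseless signal of one compartment for every volume of a scheme.

    ``S(g, b) = S0 * exp(-b g^T D g)`` with an isotropic tensor when
    ``direction`` is None, else an axially symmetric one at fixed trace.
    """
    sig = np.full(len(scheme), float(s0))
    dw = ~scheme.b0_mask
    g = scheme.bvecs[dw]
    if direction is None or axial_ratio == 1.0:
        q = np.full(dw.sum(), adc)
    else:
        lam_par, lam_perp = wm_eigenvalues(adc, axial_ratio)
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        q = lam_perp + (lam_par - lam_perp) * (g @ u) ** 2
    sig[dw] = s0 * np.exp(-scheme.bvals[dw] * q)
    return sig


def simulate_dwi(
    truth: GroundTruth, spec: PhantomSpec, scheme: GradientScheme
) -> np.ndarray:
    """Multi-tensor DWI simulation with Rician noise.

    Per voxel, ``S(g,b) = S0 * sum_i f_i exp(-b g^T D_i g)`` over the
    voxel's compartments (equal volume fractions in crossing voxels);
    b=0 volumes carry S0.  Rician noise is ``|S + n1 + i n2|`` with
    ``n1, n2 ~ N(0, S0/snr)``, deterministic given ``spec.seed``.
    """
    if spec.snr is not None and not np.isinf(spec.snr) and spec.snr <= 0:
        raise ValueError("snr must be positive (None or inf for noiseless)")
    shape = truth.tissue.shape
    nvol = len(scheme)
    dw = ~scheme.b0_mask
    g = scheme.bvecs[dw]
    b = scheme.bvals[dw]
    s0 = spec.s0

    signal = np.zeros(shape + (nvol,))
    signal[..., scheme.b0_mask] = np.where(truth.tissue > 0, s0, 0.0)[..., None]

    for code, label in ((_GM, "GM"), (_CSF, "CSF")):
        sel = truth.tissue == code
        if sel.any():
            adc = spec.compartment(label).adc
            sig = signal[..., dw]
            sig[sel] = s0 * np.exp(-b * adc)
            signal[..., dw] = sig

    wm = truth.tissue == _WM
    if wm.any():
        adc = spec.compartment("WM").adc
        lam_par, lam_perp = wm_eigenvalues(adc, spec.wm_axial_ratio)
        dirs = truth.fiber_dirs[wm]  # (n, 2, 3)
        counts = truth.n_fiber_dirs[wm]  # (n,)
        att = np.zeros((wm.sum(), len(g)))
        for q in range(2):
            has = counts > q
            if not has.any():
                continue
            u = dirs[has, q]
            quad = lam_perp + (lam_par - lam_perp) * (g @ u.T) ** 2  # (ndir, n)
            att[has] += np.exp(-b[:, None] * quad).T
        att[counts > 0] /= counts[counts > 0, None]
        # WM voxels with no recorded direction fall back to isotropic
        att[counts == 0] = np.exp(-b * adc)
        sig = signal[..., dw]
        sig[wm] = s0 * att
        signal[..., dw] = sig

    if spec.snr is None or np.isinf(spec.snr):
        return signal
    sigma = s0 / float(spec.snr)
    rng = np.random.default_rng([spec.seed, 0x0D1])
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)
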