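"""Readers/writers for the standard neuroimaging formats.

NIfTI-1 volumes, FSL-style bvec/bval text files and TrackVis TRK /
MRtrix TCK tractograms, all through nibabel; streamlines are kept in mm
(RAS) coordinates in memory.
"""
from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import streamlines as nibs

from .core import Tractogram
from .gradients import GradientScheme

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_bvals_bvecs",
    "read_bvals_bvecs",
    "save_tractogram",
    "load_tractogram",
]

log = logging.getLogger(__name__)


def save_nifti(path, data: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_bvals_bvecs(prefix, scheme: GradientScheme) -> tuple[Path, Path]:
    """Write FSL-style ``<prefix>.bval`` (1 x N) and ``<prefix>.bvec`` (3 x N)."""
    prefix = Path(prefix)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.17g")
    return bval_path, bvec_path


def read_bvals_bvecs(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL bval/bvec pair; non-unit directions are renormalized."""
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.shape != (len(bvals), 3):
        raise ValueError("bvec shape does not match bval count")
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(norms == 0):
        raise ValueError("zero diffusion direction at nonzero b-value")
    if np.any(np.abs(norms - 1.0) > 1e-9):
        log.warning("read_bvals_bvecs: non-unit directions renormalized")
        bvecs = bvecs.copy()
        bvecs[dw] /= norms[:, None]
    bvecs[~dw] = 0.0
    return GradientScheme(bvals, bvecs)


def save_tractogram(
    path, t: Tractogram, shape: tuple[int, int, int] | None = None
) -> None:
    """Write a tractogram as TRK (``.trk``) or TCK (``.tck``).

    TRK embeds the voxel-to-RAS affine (and needs the grid shape); TCK
    stores plain mm coordinates.
    """
    path = Path(path)
    sls = [np.asarray(s, dtype=np.float32) for s in t.streamlines]
    tg = nibs.Tractogram(sls, affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        if shape is None:
            raise ValueError("TRK output needs the reference grid shape")
        header = {
            nibs.trk.Field.VOXEL_TO_RASMM: t.affine.astype(np.float32),
            nibs.trk.Field.VOXEL_SIZES: np.diag(t.affine)[:3].astype(np.float32),
            nibs.trk.Field.DIMENSIONS: np.asarray(shape, dtype=np.int16),
        }
        nibs.save(nibs.trk.TrkFile(tg, header), str(path))
    elif path.suffix == ".tck":
        nibs.save(nibs.tck.TckFile(tg), str(path))
    else:
        raise ValueError(f"unsupported tractogram format: {path.suffix}")


def load_tractogram(path, affine: np.ndarray | None = None) -> Tractogram:
    """Load a TRK/TCK file into mm space."""
    path = Path(path)
    f = nibs.load(str(path))
    sls = [np.asarray(s, dtype=np.float64) for s in f.tractogram.streamlines]
    if affine is None:
        if path.suffix == ".trk":
            affine = np.asarray(f.header[nibs.trk.Field.VOXEL_TO_RASMM], dtype=float)
        else:
            affine = np.eye(4)
    return Tractogram(sls, affine, {"source": str(path)})
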