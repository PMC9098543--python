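"""Single-shell diffusion gradient schemes (HARDI acquisition geometry)."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphere import disperse_directions

__all__ = ["GradientScheme", "make_gradient_scheme"]


@dataclass
class GradientScheme:
    """Diffusion sensitizations and encoding directions of one acquisition.

    ``bvals`` holds one b-value (s/mm²) per volume, zero for T2 (b=0)
    volumes; ``bvecs`` one unit direction per volume (zero rows for b=0).
    A single nonzero shell is enforced.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if len(self.bvals) != len(self.bvecs):
            raise ValueError("bvals and bvecs length mismatch")
        if self.n_b0 < 1:
            raise ValueError("scheme needs at least one b=0 volume")
        shells = np.unique(self.bvals[~self.b0_mask])
        if len(shells) > 1:
            raise ValueError(f"multi-shell scheme not supported (b = {shells})")
        norms = np.linalg.norm(self.bvecs[~self.b0_mask], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("diffusion-encoding directions must be unit vectors")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def directions(self) -> np.ndarray:
        """Unit directions of the diffusion-weighted volumes only."""
        return self.bvecs[~self.b0_mask]

    @property
    def b(self) -> float:
        """The single shell b-value in s/mm²."""
        return float(self.bvals[~self.b0_mask][0])

    def __len__(self) -> int:
        return len(self.bvals)


def make_gradient_scheme(
    n_dirs: int = 75, n_b0: int = 5, b: float = 4500.0, seed: int = 0
) -> GradientScheme:
    """Build a single-shell scheme with quasi-uniform directions.

    Directions are spread by electrostatic repulsion treating antipodal
    pairs as identical.  b=0 volumes come first, then ``n_dirs``
    diffusion-weighted volumes at b-value ``b``.
    """
    if n_dirs < 6:
        raise ValueError("at least 6 directions are required to fit a tensor")
    if b <= 0:
        raise ValueError("b must be positive")
    dirs = disperse_directions(n_dirs, seed=seed)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals, bvecs)
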