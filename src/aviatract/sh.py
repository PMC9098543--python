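"""Real symmetric spherical harmonics for single-shell ODF reconstruction.

The basis is the even-degree real symmetric (antipodally symmetric)
orthonormal basis commonly used for analytical Q-ball imaging, indexed
``j(l, m)`` with ``l`` even ascending and ``m = -l..l`` ascending inside
each degree, giving ``(L+1)(L+2)/2`` functions at order ``L``.
"""
from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "n_coeffs",
    "sh_degrees",
    "cart_to_sphere",
    "real_sym_sh_basis",
    "legendre_p0",
    "frt_scaling",
]


def n_coeffs(order: int) -> int:
    """Number of even-degree basis functions up to ``order``."""
    return (order + 1) * (order + 2) // 2


def sh_degrees(order: int) -> np.ndarray:
    """Degree ``l`` of each coefficient in j(l, m) ordering."""
    ls = []
    for l in range(0, order + 1, 2):
        ls += [l] * (2 * l + 1)
    return np.asarray(ls, dtype=int)


def cart_to_sphere(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors -> (polar angle theta, azimuth phi)."""
    xyz = np.asarray(xyz, dtype=float)
    theta = np.arccos(np.clip(xyz[..., 2], -1.0, 1.0))
    phi = np.arctan2(xyz[..., 1], xyz[..., 0])
    return theta, phi


def real_sym_sh_basis(order: int, directions: np.ndarray) -> np.ndarray:
    """Design matrix ``(n_points, n_coeffs)`` of the real symmetric basis.

    For m < 0 the function is ``sqrt(2) * Im(Y_l^|m|)``, for m = 0 it is
    ``Y_l^0`` and for m > 0 ``sqrt(2) * Re(Y_l^m)``; only even degrees
    appear, so every basis function is antipodally symmetric.
    """
    if order % 2 != 0 or order < 0:
        raise ValueError("order must be a non-negative even integer")
    theta, phi = cart_to_sphere(np.atleast_2d(directions))
    cols = []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * y.real)
    return np.stack(cols, axis=-1)


def legendre_p0(l: int | np.ndarray) -> np.ndarray:
    """Legendre polynomial evaluated at zero, ``P_l(0)``."""
    return eval_legendre(l, 0.0)


def frt_scaling(order: int) -> np.ndarray:
    """Per-coefficient Funk–Radon transform factors ``2*pi*P_l(0)``.

    Applying these to the SH coefficients of the signal on the shell
    yields the SH coefficients of the Q-ball diffusion ODF analytically.
    """
    return 2.0 * np.pi * legendre_p0(sh_degrees(order))
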