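"""Shared fixtures: gradient scheme and small noiseless phantoms."""
import numpy as np
import pytest

import aviatract as av
from aviatract.local_models import fit_aqbi, gfa_map
from aviatract.phantom import BundleGeometry, PhantomSpec
from aviatract.preprocess import DWIStack


@pytest.fixture(scope="session")
def scheme():
    """The reference 75-direction + 5 b=0 shell at b = 4500 s/mm²."""
    return av.make_gradient_scheme(75, 5, 4500.0, seed=0)


def _fit(truth, spec, scheme):
    data = av.simulate_dwi(truth, spec, scheme)
    dwi = DWIStack(data, spec.affine, scheme, truth.brain_mask)
    odf = fit_aqbi(dwi)
    return odf, gfa_map(odf)


@pytest.fixture(scope="session")
def straight_tube(scheme):
    """Noiseless straight x-axis tube (radius 1 voxel) with fitted fields."""
    b = BundleGeometry(
        "tube", np.array([[0.8, 3.2, 3.2], [5.6, 3.2, 3.2]]), 0.2, 30, "LH"
    )
    spec = PhantomSpec(grid_shape=(32, 32, 32), bundles=[b], snr=None, seed=0)
    truth = av.build_phantom(spec)
    odf, gfa = _fit(truth, spec, scheme)
    return spec, truth, odf, gfa


@pytest.fixture(scope="session")
def oblique_tube_spec():
    """Oblique single-fiber tube whose axis avoids tessellation vertices."""
    u = np.array([1.0, 0.7, 0.4])
    u /= np.linalg.norm(u)
    c = np.array([3.2, 3.2, 3.2])
    b = BundleGeometry("obl", np.array([c - 2.2 * u, c + 2.2 * u]), 0.3, 30, "LH")
    return PhantomSpec(grid_shape=(32, 32, 32), bundles=[b], snr=None, seed=1), u


@pytest.fixture(scope="session")
def crossing_phantom(scheme):
    """Two orthogonal tubes crossing at the grid center, noiseless."""
    b1 = BundleGeometry("bx", np.array([[0.8, 3.2, 3.2], [5.6, 3.2, 3.2]]), 0.3, 30, "LH")
    b2 = BundleGeometry("by", np.array([[3.2, 0.8, 3.2], [3.2, 5.6, 3.2]]), 0.3, 30, "LH")
    spec = PhantomSpec(grid_shape=(32, 32, 32), bundles=[b1, b2], snr=None, seed=0)
    truth = av.build_phantom(spec)
    odf, gfa = _fit(truth, spec, scheme)
    return spec, truth, odf, gfa
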