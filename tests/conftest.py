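import numpy as np
import pytest

from conetrack import (
    PeakField,
    PhantomSpec,
    SeedBox,
    make_icosphere,
    make_phantom,
)
from conetrack.synthetic import analytic_alpha


@pytest.fixture(scope="session")
def mesh():
    """642-vertex symmetric icosphere used everywhere."""
    return make_icosphere(3)


@pytest.fixture(scope="session")
def straight_phantom(mesh):
    return make_phantom(PhantomSpec(geometry="straight"), mesh)


@pytest.fixture(scope="session")
def curved_phantom(mesh):
    return make_phantom(PhantomSpec(geometry="curved"), mesh)


@pytest.fixture(scope="session")
def crossing_phantom(mesh):
    return make_phantom(PhantomSpec(geometry="crossing"), mesh)


@pytest.fixture(scope="session")
def phantoms(straight_phantom, curved_phantom, crossing_phantom):
    return {
        "straight": straight_phantom,
        "curved": curved_phantom,
        "crossing": crossing_phantom,
    }


def seed_box(phantom, half_voxels=1.0):
    """2x2x2-voxel seed box centered on the bundle."""
    h = half_voxels * phantom.spec.voxel_size
    return SeedBox(phantom.seed_center(), np.full(3, h))


def with_fraction(phantom, k):
    """The phantom's peak field with alphas recomputed at fraction ``k``
    (analytic, so no re-extraction is needed)."""
    dirs = phantom.peaks.directions().copy()
    present = np.linalg.norm(dirs, axis=-1) > 0
    alpha = min(
        np.deg2rad(analytic_alpha(phantom.spec.kernel_sigma, k)), np.pi / 2
    )
    alphas = np.where(present, alpha, 0.0)
    return PeakField.from_arrays(dirs, alphas, phantom.peaks.affine)
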