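import numpy as np
import pytest

from tumorcut.core_types import LabelMask, SeedPoint, Volume
from tumorcut.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def ramp_volume():
    """Linear ramp along z on an anisotropic grid."""
    nx, ny, nz = 8, 8, 10
    data = np.broadcast_to(np.arange(nz, dtype=float) * 2.0, (nx, ny, nz)).copy()
    return Volume(data, spacing=(1.0, 1.0, 2.0))


@pytest.fixture
def small_phantom():
    """A compact noisy phantom with a single 12 mm lesion (fast to segment)."""
    spec = PhantomSpec(
        size=(72, 64, 28),
        spacing=(1.0, 1.0, 2.5),
        lesions=[((35.0, 31.0, 33.0), (6.0, 6.0, 6.0))],
        edge_blur_sigma_mm=1.0,
        noise_sigma_hu=8.0,
        rng_seed=7,
    )
    return generate_phantom(spec)


def disk_slice(shape=(40, 40), center=(20, 20), radius=10, fg=0.0, bg=100.0):
    ii, jj = np.ogrid[: shape[0], : shape[1]]
    inside = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2
    return np.where(inside, fg, bg), inside


def enumerate_mincut_energy(graph):
    """Vectorized exhaustive minimum of the labeling energy over all
    assignments of the unknown voxels (seeds pinned to their side)."""
    n = int(np.prod(graph.shape))
    fg_seed = np.isinf(graph.cap_sink)
    bg_seed = np.isinf(graph.cap_source)
    free = np.flatnonzero(~fg_seed & ~bg_seed)
    u = len(free)
    labs = ((np.arange(2**u)[:, None] >> np.arange(u)) & 1).astype(np.uint8)
    L = np.broadcast_to(fg_seed.astype(np.uint8), (2**u, n)).copy()
    L[:, free] = labs
    cap_t = np.where(fg_seed | bg_seed, 0.0, graph.cap_sink)
    cap_s = np.where(fg_seed | bg_seed, 0.0, graph.cap_source)
    e_t = L @ cap_s + (1 - L) @ cap_t
    diff = L[:, graph.n_edges[:, 0]] != L[:, graph.n_edges[:, 1]]
    e_n = diff @ graph.n_caps
    return float((e_t + e_n).min())


@pytest.fixture
def two_blob_mask():
    data = np.zeros((20, 20, 8), dtype=np.uint8)
    data[2:5, 2:5, 2:4] = 1  # small blob
    data[10:18, 10:18, 2:7] = 1  # large blob
    return LabelMask(data), SeedPoint(index=(3, 3, 2))
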