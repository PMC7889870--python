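import numpy as np
import pytest

from radphantom.image import ImageVolume, ROIMask
from radphantom.preprocess import QuantizedROI


def make_quantized(levels_3d, n_levels=None, mask=None):
    """Build a QuantizedROI directly from a 3D integer level array (0 = outside)."""
    lev = np.asarray(levels_3d, dtype=np.int32)
    if lev.ndim == 2:
        lev = lev[:, :, None]
    if mask is None:
        mask = lev > 0
    if n_levels is None:
        n_levels = int(lev.max())
    return QuantizedROI(lev, mask, int(n_levels), 0.0, float(n_levels))


def make_volume(values_3d, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(values_3d, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return ImageVolume(arr, spacing)


def full_mask(vol, label=1):
    return ROIMask(np.ones(vol.shape, dtype=bool), label, vol.spacing, vol.origin)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_phantom():
    """One ground-truth phantom build shared across tests (session-scoped)."""
    from radphantom.phantom import PhantomSpec, build_phantom

    spec = PhantomSpec()
    truth, masks = build_phantom(spec, seed=424242)
    return spec, truth, masks
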