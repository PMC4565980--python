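import numpy as np
import pytest

from telolamina import MultiChannelVolume, NoiseParams, SyntheticParams

NOISE_OFF = NoiseParams(poisson_scale=0.0, gaussian_sd=0.0)


@pytest.fixture
def small_params() -> SyntheticParams:
    """A small, fast nucleus for unit tests (≈0.1 s to generate)."""
    return SyntheticParams(
        nucleus_radii_nm=(1000.0, 1500.0, 1500.0),
        n_telomeres=12,
        voxel_size_nm=(125.0, 50.0, 50.0),
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def ball_volume(
    radius_nm: float = 2000.0,
    voxel_size_nm=(125.0, 80.0, 80.0),
    amplitude: float = 100.0,
    interior: float = 25.0,
    channel: str = "lamin",
) -> MultiChannelVolume:
    """A noise-free spherical nucleus-like test volume built by hand."""
    voxel = np.asarray(voxel_size_nm)
    half = np.ceil(radius_nm / voxel).astype(int) + 3
    shape = tuple(2 * half + 1)
    zz, yy, xx = [
        (np.arange(n) - h) * v for n, h, v in zip(shape, half, voxel)
    ]
    r2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2
        + xx[None, None, :] ** 2
    )
    inside = r2 <= radius_nm**2
    img = np.where(inside, interior, 0.0)
    shell = inside & (r2 >= (radius_nm - 150.0) ** 2)
    img[shell] = amplitude
    return MultiChannelVolume(img[None], [channel], tuple(voxel_size_nm))
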