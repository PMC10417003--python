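import numpy as np
import pytest

from pigcloud import CameraIntrinsics, SceneConfig, generate_scene


@pytest.fixture
def test_cam() -> CameraIntrinsics:
    """Small pinhole camera whose unit-tangent pixel (cx+fx) stays in frame."""
    return CameraIntrinsics(fx=100.0, fy=100.0, cx=160.0, cy=120.0, width=320, height=240)


@pytest.fixture
def tiny_cam() -> CameraIntrinsics:
    return CameraIntrinsics(fx=10.0, fy=10.0, cx=4.0, cy=4.0, width=8, height=8)


@pytest.fixture(scope="session")
def clean_scene():
    """A deterministic noise-free scene with three well-separated animals."""
    return generate_scene(SceneConfig(n_animals=3, seed=11))


@pytest.fixture(scope="session")
def noisy_scene():
    return generate_scene(SceneConfig(n_animals=3, noise_sigma_mm=8.0, seed=11))


def _small_config(**kwargs) -> SceneConfig:
    """Quarter-scale camera so brute-force per-pixel oracles stay fast."""
    cam = CameraIntrinsics(fx=106.0, fy=106.0, cx=105.5, cy=59.5, width=212, height=120)
    return SceneConfig(
        n_animals=2,
        intrinsics=cam,
        semi_major_px=(15.0, 27.0),
        semi_minor_px=(7.0, 12.0),
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(_small_config(seed=3))


@pytest.fixture(scope="session")
def small_noisy_scene():
    return generate_scene(_small_config(seed=3, noise_sigma_mm=8.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
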