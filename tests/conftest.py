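import numpy as np
import pytest

from sishdetect.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene shared across read-only tests."""
    return generate_scene(SceneConfig(seed=42))


@pytest.fixture(scope="session")
def quiet_scene():
    """Noise-free scene for stain-estimation tests."""
    return generate_scene(SceneConfig(seed=42, noise_sd=0))


def make_disk(radius: float, pad: int = 3) -> np.ndarray:
    """Rasterized disk instance mask (label 1) centred on a pixel."""
    n = 2 * int(np.ceil(radius)) + 2 * pad + 1
    rr, cc = np.mgrid[0:n, 0:n]
    c = n // 2
    return (np.hypot(rr - c, cc - c) <= radius).astype(np.int32)
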