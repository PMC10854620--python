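import numpy as np
import pytest

from nbisim import SynthConfig, make_mucosa_image, make_nbi_reference


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    return SynthConfig(seed=7, size=64, n_images=6)


@pytest.fixture(scope="session")
def wli_image(small_cfg) -> np.ndarray:
    return make_mucosa_image(small_cfg, 0)


@pytest.fixture(scope="session")
def nbi_reference_image(small_cfg) -> np.ndarray:
    return make_nbi_reference(small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
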