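import numpy as np
import pytest

from epispec import (
    BaselineDrift,
    GeneratorConfig,
    NOISE_FREE_FTIR,
    Spectrum,
    cd_catalog,
    ftir_catalog,
)


@pytest.fixture(scope="session")
def oligo_catalog():
    return ftir_catalog("synthetic_oligo")


@pytest.fixture(scope="session")
def cellular_catalog():
    return ftir_catalog("cellular")


@pytest.fixture(scope="session")
def cd_unmeth_catalog():
    return cd_catalog("synthetic_unmethylated")


@pytest.fixture
def noise_free():
    """Noise- and drift-free FT-IR generator settings."""
    return NOISE_FREE_FTIR


@pytest.fixture(scope="session")
def ftir_grid():
    """Default acquisition grid, 4000 -> 800 cm^-1 descending, step 2."""
    return NOISE_FREE_FTIR.grid()


def make_spectrum(axis, values, state="raw", **meta):
    meta = {"processing_state": state, **meta}
    return Spectrum(np.asarray(axis, float), np.asarray(values, float), meta)


@pytest.fixture
def make_raw():
    return make_spectrum


@pytest.fixture
def noisy_cfg():
    def _cfg(noise, seed, drift=False):
        if drift:
            return GeneratorConfig.ftir(noise_sd_rel=noise, seed=seed)
        return GeneratorConfig.ftir(
            noise_sd_rel=noise, seed=seed, baseline=BaselineDrift()
        )
    return _cfg
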