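import numpy as np
import pytest

import leafspec as ls


@pytest.fixture(scope="session")
def small_dataset():
    """60-sample synthetic dataset under default generator conditions."""
    cfg = ls.default_config(n_samples=60, seed=42)
    traits, spectra = ls.make_dataset(cfg)
    return cfg, traits, spectra


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_spectrum_set():
    """Five random spectra on the full 401-2400 nm grid."""
    rng = np.random.default_rng(7)
    wl = np.arange(401.0, 2401.0)
    refl = rng.uniform(0.05, 0.95, size=(5, wl.size))
    ids = [f"T{i}" for i in range(5)]
    return ls.SpectrumSet(ids, wl, refl)
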