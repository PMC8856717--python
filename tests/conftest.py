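import numpy as np
import pytest

from swdpredict import (band_energy_series, gaers_spec, generate_recording,
                        make_combination)
from swdpredict.spectral import channel_product


@pytest.fixture(scope="session")
def short_gaers():
    """20-min GAERS-like record with a raised SWD rate (for event counts)."""
    spec = gaers_spec(duration_s=1200.0, fs=128.0, base_swd_rate_per_h=40.0)
    record, annotation = generate_recording(spec, rng_seed=42)
    return spec, record, annotation


@pytest.fixture(scope="session")
def short_energies(short_gaers):
    _, record, _ = short_gaers
    return band_energy_series(record, stride_s=0.05)


@pytest.fixture(scope="session")
def s1_triple():
    return make_combination(["S1_L4", "S1_L5", "S1_L6"])


@pytest.fixture(scope="session")
def short_products(short_energies, s1_triple):
    return channel_product(short_energies, s1_triple.sites)


def separable_features(n_per_class: int, rng_seed: int = 0,
                       tp_mean: float = 3.0, fp_mean: float = 1.0,
                       sd: float = 0.5):
    """Synthetic 9-dim feature sets: precursor-band features differ in
    mean between classes, other bands are identical noise."""
    rng = np.random.default_rng(rng_seed)
    def block(mean):
        prec = rng.normal(mean, sd, size=(n_per_class, 3))
        rest = rng.normal(1.0, sd, size=(n_per_class, 6))
        return np.abs(np.concatenate([prec, rest], axis=1))
    X = np.vstack([block(tp_mean), block(fp_mean)])
    y = np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    return X, y
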