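import numpy as np
import pytest

from scpriq import (
    Peak,
    SpectrumRecord,
    single_cell_9plex,
    two_proteome_9plex,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sc_design():
    return single_cell_9plex()


@pytest.fixture
def std_design():
    return two_proteome_9plex()


def make_spectrum(rng, n_peaks=50, spectrum_id="s0", mz_range=(100.0, 1700.0)):
    mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
    inten = rng.exponential(100.0, size=n_peaks) + 1
    return SpectrumRecord(
        spectrum_id=spectrum_id,
        precursor_mz=float(rng.uniform(400, 1200)),
        charge=2,
        retention_time=float(rng.uniform(0, 1800)),
        inv_k0=float(rng.uniform(0.8, 1.3)),
        peaks=[Peak(float(m), float(i)) for m, i in zip(mz, inten)],
    )


@pytest.fixture
def random_spectrum(rng):
    return make_spectrum(rng)
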