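import numpy as np
import pytest

import sirqmt as sq


@pytest.fixture(scope="session")
def scheme():
    """The optimized four-point low-tD acquisition scheme (seconds)."""
    return sq.AcquisitionScheme.default()


@pytest.fixture(scope="session")
def wm_params():
    """A representative white-matter voxel."""
    return sq.TissueParams(psr=0.15, r1f=1.0, sf=-1.0, sm=0.83, m0f=1.0, kmf=12.5)


@pytest.fixture(scope="session")
def small_phantom_fit(scheme):
    """A 12x12 noisy phantom fit shared by evaluation-layer tests."""
    truth = sq.make_phantom(shape=(12, 12))
    noise_free = sq.simulate_series(truth, scheme, kmf=12.5, sm=0.83)
    noisy = sq.add_rician_noise(noise_free, sq.NoiseSpec(snr=250, seed=7))
    series = sq.SirSeries(data=noisy, scheme=scheme)
    maps = sq.fit_image(series, sq.FitConfig(kmf=12.5))
    return truth, series, maps


def random_valid_params(rng, n):
    """Draw n parameter sets spanning the physical box."""
    draws = []
    for _ in range(n):
        draws.append(
            sq.TissueParams(
                psr=rng.uniform(0.0, 0.6),
                r1f=rng.uniform(0.2, 3.0),
                r1m=rng.uniform(0.2, 3.0),
                sf=rng.uniform(-1.0, 1.0),
                sm=rng.uniform(0.5, 1.0),
                m0f=rng.uniform(0.1, 5.0),
                kmf=rng.uniform(0.0, 60.0),
            )
        )
    return draws
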