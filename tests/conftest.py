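import numpy as np
import pytest

from physiocoh import SampledSeries, build_scale_grid
from physiocoh.wavelet import morlet


def direct_cwt(values: np.ndarray, dt: float, grid) -> np.ndarray:
    """Literal double-sum Morlet transform (the independent slow oracle)."""
    n = values.size
    out = np.empty((grid.n_scales, n), complex)
    idx = np.arange(n)
    for j, s in enumerate(grid.scales):
        psi = np.conj(morlet((idx[None, :] - idx[:, None]) * dt / s, grid.omega0))
        out[j] = np.sqrt(dt / s) * psi @ values
    return out


@pytest.fixture(scope="session")
def frame_dt() -> float:
    return 0.72


@pytest.fixture(scope="session")
def small_grid(frame_dt):
    return build_scale_grid(frame_dt, 400, dj=1.0 / 8.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def lagged_sine_pair(f: float, tau: float, n: int = 1200, dt: float = 0.72,
                     noise_sd: float = 0.05, seed: int = 0):
    """(leading, trailing) noisy sinusoids: second series delayed by tau seconds."""
    r = np.random.default_rng(seed)
    t = dt * np.arange(n)
    lead = SampledSeries(np.sin(2 * np.pi * f * t) + noise_sd * r.normal(size=n), dt=dt)
    trail = SampledSeries(np.sin(2 * np.pi * f * (t - tau)) + noise_sd * r.normal(size=n),
                          dt=dt)
    return lead, trail
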