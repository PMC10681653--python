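"""Monte-Carlo significance of coherence magnitude.

Each observed signal is modeled as an AR(p) process (order 1 by default,
order 9 supported for the physiological signals); pairs of independent
surrogate series are simulated from the two fitted models, wavelet coherence
is computed for each pair, and the out-of-cone R^2 values are pooled per
scale across time and across pairs.  The 95th percentile per scale is the
significance threshold.  Because the surrogates are simulated independently,
exceedances of the threshold mark coherence beyond what two unrelated
signals with the observed autocorrelation produce.

Spectrum-preserving surrogates (`make_phase_shuffled_null`) keep the Fourier
amplitudes of a signal bin-for-bin and randomize the phases, destroying any
phase alignment with a partner while preserving power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from .series import DegenerateSignalError, SampledSeries
from .wavelet import ScaleGrid, wtc


class NonstationaryModelError(ValueError):
    """AR/VAR fit outside the stationary region."""


@dataclass
class ARModel:
    """Autoregressive model x_t = sum_k a_k x_{t-k} + eps, eps ~ N(0, sd^2)."""

    coefficients: np.ndarray
    noise_sd: float

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, float))
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise NonstationaryModelError(f"AR companion spectral radius {rho:.3f} >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def order(self) -> int:
        return self.coefficients.size

    def spectral_radius(self) -> float:
        p = self.order
        if p == 1:
            return abs(float(self.coefficients[0]))
        comp = np.zeros((p, p))
        comp[0, :] = self.coefficients
        comp[1:, :-1] = np.eye(p - 1)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def simulate(self, n: int, rng: np.random.Generator, burn_in: int = 500) -> np.ndarray:
        """Simulate n samples after a burn-in from a zero start."""
        p = self.order
        total = n + burn_in
        eps = rng.normal(0.0, self.noise_sd, size=total)
        x = np.zeros(total)
        if p == 1:
            from scipy.signal import lfilter
            x = lfilter([1.0], np.r_[1.0, -self.coefficients], eps)
        else:
            a = self.coefficients
            for t in range(total):
                past = x[max(0, t - p):t][::-1]
                x[t] = a[: past.size] @ past + eps[t]
        return x[burn_in:]


def fit_ar(x: SampledSeries, order: int = 1) -> ARModel:
    """Yule-Walker AR(p) fit of a series (demeaned first)."""
    v = x.values
    if np.ptp(v) == 0:
        raise DegenerateSignalError("cannot fit AR to a constant series")
    if v.size <= 10 * order:
        raise ValueError("series too short for the requested AR order")
    rho, sigma = yule_walker(v - v.mean(), order=order, method="mle")
    return ARModel(coefficients=rho, noise_sd=float(sigma))


def simulate_ar1(phi: float, sigma: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """AR(1) sample path started from the stationary distribution."""
    if abs(phi) >= 1:
        raise NonstationaryModelError("|phi| must be < 1")
    if n < 2:
        raise ValueError("need n >= 2")
    eps = rng.normal(0.0, sigma, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma / np.sqrt(1 - phi**2)) if sigma > 0 else 0.0
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


@dataclass
class ThresholdProfile:
    """Per-scale 95% coherence-magnitude thresholds from an AR bootstrap."""

    thresholds: np.ndarray          # (n_scales,), NaN where no out-of-cone points
    grid: ScaleGrid
    alpha: float
    n_boot: int
    seed: int
    model_x: ARModel | None = None
    model_y: ARModel | None = None
    meta: dict = field(default_factory=dict)


def bootstrap_thresholds(model_x: ARModel, model_y: ARModel, n: int, dt: float,
                         grid: ScaleGrid, n_boot: int = 300, alpha: float = 0.05,
                         seed: int = 0, strict: bool = True) -> ThresholdProfile:
    """Per-scale (1 - alpha) R^2 quantiles from independent AR surrogate pairs.

    R^2 values are pooled per scale over out-of-cone time points and over all
    ``n_boot`` pairs.  Scales whose period exceeds the cone everywhere get a
    NaN threshold (no trustworthy point exists there at this record length).
    """
    if strict and n_boot < 50:
        raise ValueError("n_boot < 50 gives unstable thresholds")
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    oc = None
    for _ in range(n_boot):
        sx = SampledSeries(model_x.simulate(n, rng), dt=dt)
        sy = SampledSeries(model_y.simulate(n, rng), dt=dt)
        coh = wtc(sx, sy, grid)
        if oc is None:
            oc = coh.outside_cone()
        pooled.append(coh.r2[oc])
    counts = oc.sum(axis=1)
    thr = np.full(grid.n_scales, np.nan)
    stacked = np.stack([p for p in pooled])  # (n_boot, n_oc_points)
    # re-split pooled vector back into per-scale blocks
    edges = np.r_[0, np.cumsum(counts)]
    for j in range(grid.n_scales):
        if counts[j] == 0:
            continue
        block = stacked[:, edges[j]:edges[j + 1]].ravel()
        thr[j] = np.quantile(block, 1.0 - alpha)
    return ThresholdProfile(thresholds=thr, grid=grid, alpha=alpha, n_boot=n_boot,
                            seed=seed, model_x=model_x, model_y=model_y,
                            meta={"n": n, "dt": dt})


def make_phase_shuffled_null(x: SampledSeries, seed: int = 0) -> SampledSeries:
    """Surrogate with the exact amplitude spectrum of ``x`` and random phases.

    Positive-frequency phases are i.i.d. uniform(-pi, pi); the DC and (for
    even length) Nyquist bins are left untouched so the output is real.
    """
    v = x.values
    n = v.size
    if n < 8:
        raise ValueError("series too short to phase-shuffle")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(v)
    k = spec.size
    inner = slice(1, k - 1 if n % 2 == 0 else k)
    phases = rng.uniform(-np.pi, np.pi, size=spec[inner].size)
    out_spec = spec.copy()
    out_spec[inner] = np.abs(spec[inner]) * np.exp(1j * phases)
    surro = np.fft.irfft(out_spec, n)
    return x.with_values(surro, label=f"{x.label}-phase-shuffled" if x.label else "phase-shuffled")
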