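"""Temporal variability of coherence against a stationary VAR(1) null.

The complex coherence z(t) = R^2(t) * exp(i*phi(t)) at each scale is reduced
to its complex variance

    sigma^2(s) = < (z - mu_z)(z - mu_z)* >,   mu_z = <z>,

over out-of-cone times — a real, non-negative scalar that is zero iff the
coherence magnitude and phase are constant in time.  The null preserves the
*stationary* cross-dependence between the two signals: a VAR(1) model is fit
to the observed pair, many surrogate pairs are simulated from it, and the
95th percentile of their per-scale sigma^2 is the significance threshold.
A flagged scale varies in time more than any fixed linear coupling of that
strength would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import DegenerateSignalError, SampledSeries
from .significance import NonstationaryModelError
from .wavelet import CoherenceField, ScaleGrid, wtc

MIN_POINTS_PER_SCALE = 8


@dataclass
class VARModel:
    """First-order vector autoregression z_t = A z_{t-1} + e_t, e ~ N(0, Sigma)."""

    coef: np.ndarray            # (2, 2)
    innovation_cov: np.ndarray  # (2, 2), PSD
    singular: bool = False      # rank-deficient innovation covariance

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, float)
        self.innovation_cov = np.asarray(self.innovation_cov, float)
        if self.coef.shape != (2, 2) or self.innovation_cov.shape != (2, 2):
            raise ValueError("VAR(1) model for a signal pair needs 2x2 matrices")
        rho = float(np.max(np.abs(np.linalg.eigvals(self.coef))))
        if rho >= 1.0:
            raise NonstationaryModelError(f"VAR spectral radius {rho:.3f} >= 1")

    def simulate(self, n: int, rng: np.random.Generator,
                 burn_in: int = 200) -> tuple[np.ndarray, np.ndarray]:
        total = n + burn_in
        # eigendecomposition handles singular covariances gracefully
        w, V = np.linalg.eigh(self.innovation_cov)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        eps = rng.standard_normal((total, 2)) @ L.T
        z = np.zeros((total, 2))
        for t in range(1, total):
            z[t] = self.coef @ z[t - 1] + eps[t]
        return z[burn_in:, 0], z[burn_in:, 1]


def fit_var1(x: SampledSeries, y: SampledSeries) -> VARModel:
    """OLS VAR(1) fit to a demeaned signal pair."""
    if x.n != y.n:
        raise ValueError("series must have equal length")
    if x.n <= 20:
        raise ValueError("series too short for a VAR(1) fit")
    if np.ptp(x.values) == 0 or np.ptp(y.values) == 0:
        raise DegenerateSignalError("cannot fit VAR to a constant series")
    Z = np.column_stack([x.values - x.values.mean(), y.values - y.values.mean()])
    Z0, Z1 = Z[:-1], Z[1:]
    A, *_ = np.linalg.lstsq(Z0, Z1, rcond=None)
    A = A.T
    resid = Z1 - Z0 @ A.T
    cov = resid.T @ resid / (resid.shape[0] - 2)
    # rank deficiency (e.g. x == y) leaves a ~zero eigenvalue
    w = np.linalg.eigvalsh(cov)
    singular = bool(w[0] <= 1e-12 * max(w[-1], 1e-300))
    return VARModel(coef=A, innovation_cov=cov, singular=singular)


def complex_wtc_variance(coh: CoherenceField,
                         min_points: int = MIN_POINTS_PER_SCALE) -> np.ndarray:
    """Per-scale complex variance of z = R^2 exp(i phi) over out-of-cone times.

    Scales with fewer than ``min_points`` trustworthy time points are NaN
    (reported missing, never zero).
    """
    z = coh.r2 * np.exp(1j * coh.phase)
    oc = coh.outside_cone()
    out = np.full(coh.grid.n_scales, np.nan)
    for j in range(coh.grid.n_scales):
        zj = z[j, oc[j]]
        if zj.size < min_points:
            continue
        mu = zj.mean()
        out[j] = float(np.mean(np.abs(zj - mu) ** 2))
    return out


@dataclass
class VariabilityProfile:
    """Observed per-scale coherence variance with VAR-bootstrap thresholds."""

    sigma2: np.ndarray            # observed, NaN where insufficient points
    thresholds: np.ndarray        # 95th percentile under the VAR(1) null
    significant: np.ndarray       # boolean; False where either side is NaN
    grid: ScaleGrid
    n_boot: int
    alpha: float
    seed: int
    model: VARModel | None = None
    meta: dict = field(default_factory=dict)

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies


def variability_test(x: SampledSeries, y: SampledSeries, grid: ScaleGrid,
                     n_boot: int = 1000, alpha: float = 0.05,
                     seed: int = 0) -> VariabilityProfile:
    """Flag scales whose coherence varies in time beyond a stationary VAR(1) null."""
    model = fit_var1(x, y)
    coh = wtc(x, y, grid)
    observed = complex_wtc_variance(coh)
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, grid.n_scales), np.nan)
    for b in range(n_boot):
        bx, by = model.simulate(x.n, rng)
        bcoh = wtc(SampledSeries(bx, dt=x.dt), SampledSeries(by, dt=y.dt), grid)
        boots[b] = complex_wtc_variance(bcoh)
    thr = np.full(grid.n_scales, np.nan)
    has_data = ~np.all(np.isnan(boots), axis=0)
    with np.errstate(invalid="ignore"):
        thr[has_data] = np.nanquantile(boots[:, has_data], 1.0 - alpha, axis=0)
    sig = np.zeros(grid.n_scales, dtype=bool)
    ok = ~np.isnan(observed) & ~np.isnan(thr)
    sig[ok] = observed[ok] > thr[ok]
    return VariabilityProfile(sigma2=observed, thresholds=thr, significant=sig,
                              grid=grid, n_boot=n_boot, alpha=alpha, seed=seed,
                              model=model, meta={"n": x.n, "dt": x.dt})


def percent_participants_significant(profiles: list[VariabilityProfile]) -> np.ndarray:
    """Per-frequency percentage of participants flagged as temporally variable."""
    if not profiles:
        raise ValueError("need at least one participant profile")
    g0 = profiles[0].grid
    for p in profiles[1:]:
        if not np.allclose(p.grid.scales, g0.scales):
            raise ValueError("all profiles must share one scale grid")
    flags = np.stack([p.significant for p in profiles])
    return 100.0 * flags.mean(axis=0)
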