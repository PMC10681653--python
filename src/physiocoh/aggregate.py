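"""Summary metrics over coherence fields.

Percent time with significant coherence — per frequency and averaged over
named frequency bands — with cone-of-influence exclusion; the same metric
split by phase-offset category (in-phase, physio-leading, anti-phase,
BOLD-leading quarter-circle arcs); and a band-limited peak cross-correlation
lag between the raw series.

Phase convention: coherence phase is arg(W_physio * conj(W_BOLD)), so
+pi/2 means the physiological signal leads the BOLD cycle by a quarter
period and -pi/2 means BOLD leads.  The convention is pinned by a
constructed-lag test rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .series import SampledSeries
from .significance import ThresholdProfile
from .wavelet import CoherenceField

#: default frequency bands (Hz): dominant bands of HBI and RVT fluctuations
DEFAULT_BANDS = (("HBI-low", 0.05, 0.15), ("HBI-high", 0.15, 0.40),
                 ("RVT", 0.02, 0.04))

PHASE_BIN_NAMES = ("in_phase", "physio_leads", "anti_phase", "bold_leads")
PHASE_BIN_CENTERS = (0.0, np.pi / 2, np.pi, -np.pi / 2)


@dataclass(frozen=True)
class BandSpec:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("band requires 0 < f_lo < f_hi")


def default_bands() -> list[BandSpec]:
    return [BandSpec(*b) for b in DEFAULT_BANDS]


def phase_bin_index(phase: np.ndarray) -> np.ndarray:
    """Assign each phase to one of four half-open arcs [center-pi/4, center+pi/4).

    Returns indices into PHASE_BIN_NAMES.  The arcs partition the circle
    exactly: every angle lands in exactly one bin.
    """
    ph = np.mod(np.asarray(phase) + np.pi, 2 * np.pi) - np.pi  # wrap to [-pi, pi)
    return (np.floor((ph + np.pi / 4) / (np.pi / 2)).astype(int)) % 4


@dataclass
class BandProfile:
    """Percent time with significant coherence, per frequency and per band."""

    frequencies: np.ndarray                 # Hz, per scale
    pct_significant: np.ndarray             # %, per frequency (NaN if no valid points)
    n_valid: np.ndarray                     # out-of-cone point count per frequency
    band_pct: dict = field(default_factory=dict)       # band name -> mean %
    phase_split: np.ndarray | None = None   # (4, n_freq) %, summing to pct_significant
    band_phase_pct: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {"frequency_hz": self.frequencies, "pct_sig": self.pct_significant,
             "n_points": self.n_valid}
        if self.phase_split is not None:
            for i, name in enumerate(PHASE_BIN_NAMES):
                d[f"pct_{name}"] = self.phase_split[i]
        return pd.DataFrame(d)


def significance_mask(coh: CoherenceField, thr: ThresholdProfile) -> np.ndarray:
    """True where R^2 exceeds the per-scale threshold outside the cone."""
    if thr.thresholds.size != coh.grid.n_scales or not np.allclose(
            thr.grid.scales, coh.grid.scales):
        raise ValueError("threshold profile does not match the coherence grid")
    t = thr.thresholds[:, None]
    with np.errstate(invalid="ignore"):
        exceed = coh.r2 > t
    return exceed & coh.outside_cone()


def percent_time_significant(mask: np.ndarray, coh: CoherenceField,
                             bands: list[BandSpec] | None = None,
                             pooled_band_counts: bool = False) -> BandProfile:
    """Per-frequency and per-band percent of out-of-cone points that are significant.

    Band value defaults to the mean of per-frequency percentages over scales
    whose frequency lies in the band, so fine and coarse scale grids weight
    frequencies equally; ``pooled_band_counts=True`` pools raw point counts
    across the band's scales instead.
    """
    bands = default_bands() if bands is None else bands
    oc = coh.outside_cone()
    n_valid = oc.sum(axis=1)
    n_sig = (mask & oc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_valid > 0, 100.0 * n_sig / np.maximum(n_valid, 1), np.nan)
    freqs = coh.grid.frequencies
    band_pct = {}
    for b in bands:
        in_band = (freqs >= b.f_lo) & (freqs <= b.f_hi)
        if not np.any(in_band):
            raise ValueError(f"band {b.name} contains no grid frequency")
        if pooled_band_counts:
            tot = n_valid[in_band].sum()
            band_pct[b.name] = 100.0 * n_sig[in_band].sum() / tot if tot else np.nan
        else:
            band_pct[b.name] = float(np.nanmean(pct[in_band]))
    return BandProfile(frequencies=freqs, pct_significant=pct,
                       n_valid=n_valid, band_pct=band_pct)


def categorize_phase(coh: CoherenceField, mask: np.ndarray,
                     bands: list[BandSpec] | None = None) -> BandProfile:
    """Split percent time significant into the four phase-offset categories.

    Each significant out-of-cone point is assigned to exactly one quarter-
    circle arc by its phase; the per-bin percentages sum to the unsplit
    percentage at every frequency.
    """
    prof = percent_time_significant(mask, coh, bands)
    oc = coh.outside_cone()
    sig = mask & oc
    bins = phase_bin_index(coh.phase)
    split = np.zeros((4, coh.grid.n_scales))
    for k in range(4):
        n_k = (sig & (bins == k)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            split[k] = np.where(prof.n_valid > 0,
                                100.0 * n_k / np.maximum(prof.n_valid, 1), np.nan)
    prof.phase_split = split
    freqs = coh.grid.frequencies
    for b in (default_bands() if bands is None else bands):
        in_band = (freqs >= b.f_lo) & (freqs <= b.f_hi)
        prof.band_phase_pct[b.name] = {
            name: float(np.nanmean(split[k][in_band]))
            for k, name in enumerate(PHASE_BIN_NAMES)}
    return prof


def xcorr_peak_lag(reference: SampledSeries, target: SampledSeries, band: BandSpec,
                   max_lag: float, filter_order: int = 4) -> float:
    """Lag (s) of ``target`` relative to ``reference`` at peak band-limited correlation.

    With reference = BOLD and target = the physiological series, a positive
    lag means the physiological signal trails the BOLD signal.  Both series
    are band-passed to [f_lo, f_hi] with a zero-phase Butterworth filter,
    then the normalized cross-correlation is scanned over [-max_lag, +max_lag].
    """
    if reference.n != target.n or not np.isclose(reference.dt, target.dt):
        raise ValueError("series must share length and sampling step")
    dt = reference.dt
    if max_lag >= reference.n * dt / 2:
        raise ValueError("max_lag must be below half the record duration")
    nyq = 0.5 / dt
    if band.f_hi >= nyq:
        raise ValueError("band extends beyond the Nyquist frequency")
    sos = sps.butter(filter_order, [band.f_lo / nyq, band.f_hi / nyq],
                     btype="bandpass", output="sos")
    r = sps.sosfiltfilt(sos, reference.values - reference.values.mean())
    g = sps.sosfiltfilt(sos, target.values - target.values.mean())
    max_k = int(np.floor(max_lag / dt))
    full = sps.correlate(g, r, mode="full")  # index n-1+k  <->  sum r[t] g[t+k]
    n = reference.n
    lags_k = np.arange(-max_k, max_k + 1)
    vals = full[n - 1 + lags_k]
    return float(lags_k[np.argmax(vals)] * dt)
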