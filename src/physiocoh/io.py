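"""Plain-text writers for every stage's outputs (TSV matrices + JSON sidecars)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import PHASE_BIN_NAMES, BandProfile
from .series import SampledSeries
from .significance import ThresholdProfile
from .variability import VariabilityProfile
from .wavelet import CoherenceField


def write_frame_series(path, series: SampledSeries, qc_flags=None) -> None:
    """Frame-aligned series as (frame_time_s, value, qc_flag)."""
    flags = qc_flags
    if flags is None:
        flags = getattr(series, "qc_flags", np.zeros(series.n, dtype=bool))
    df = pd.DataFrame({"frame_time_s": series.times, "value": series.values,
                       "qc_flag": np.asarray(flags, dtype=int)})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_coherence_field(prefix, coh: CoherenceField) -> None:
    """R^2, phase and cone mask matrices plus a JSON axis sidecar."""
    prefix = Path(prefix)
    np.savetxt(f"{prefix}_r2.tsv", coh.r2, fmt="%.6f", delimiter="\t")
    np.savetxt(f"{prefix}_phase.tsv", coh.phase, fmt="%.6f", delimiter="\t")
    np.savetxt(f"{prefix}_conemask.tsv", coh.outside_cone().astype(int),
               fmt="%d", delimiter="\t")
    sidecar = {"times_s": coh.times.tolist(),
               "scales_s": coh.grid.scales.tolist(),
               "fourier_periods_s": coh.grid.fourier_periods.tolist(),
               "frequencies_hz": coh.grid.frequencies.tolist(),
               "coi_period_s": coh.coi_period.tolist(),
               "params": coh.params}
    Path(f"{prefix}_axes.json").write_text(json.dumps(sidecar))


def write_thresholds(path, thr: ThresholdProfile) -> None:
    df = pd.DataFrame({"scale_s": thr.grid.scales,
                       "frequency_hz": thr.grid.frequencies,
                       "r2_threshold": thr.thresholds})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {"alpha": thr.alpha, "n_boot": thr.n_boot, "seed": thr.seed,
               "ar_x": None if thr.model_x is None else
               {"coefficients": thr.model_x.coefficients.tolist(),
                "noise_sd": thr.model_x.noise_sd},
               "ar_y": None if thr.model_y is None else
               {"coefficients": thr.model_y.coefficients.tolist(),
                "noise_sd": thr.model_y.noise_sd},
               "meta": thr.meta}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def write_band_profile(path, prof: BandProfile) -> None:
    df = prof.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    summary = {"band_pct": prof.band_pct}
    if prof.band_phase_pct:
        summary["band_phase_pct"] = prof.band_phase_pct
    Path(str(path) + ".json").write_text(json.dumps(summary))


def write_variability_profile(path, prof: VariabilityProfile) -> None:
    df = pd.DataFrame({"frequency_hz": prof.frequencies, "sigma2": prof.sigma2,
                       "threshold": prof.thresholds,
                       "significant": prof.significant.astype(int)})
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")


def plot_coherence_map(coh: CoherenceField, mask=None, ax=None,
                       arrow_stride: tuple[int, int] = (6, 40)):
    """Figure-style coherence map: R^2 heat map, phase arrows, cone shading.

    Returns the matplotlib axes.  Plotting is a convenience; all quantitative
    outputs go through the TSV writers.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    t = coh.times
    periods = coh.grid.fourier_periods
    pcm = ax.pcolormesh(t, periods, coh.r2, cmap="viridis", vmin=0, vmax=1,
                        shading="nearest")
    ax.set_yscale("log")
    ax.invert_yaxis()
    ax.fill_between(t, periods[-1], coh.coi_period, where=coh.coi_period < periods[-1],
                    color="white", alpha=0.4, hatch="x", edgecolor="gray", linewidth=0)
    js, ks = arrow_stride
    jj, kk = np.meshgrid(np.arange(0, periods.size, js), np.arange(0, t.size, ks),
                         indexing="ij")
    oc = coh.outside_cone()
    keep = oc[jj, kk]
    ax.quiver(t[kk[keep]], periods[jj[keep]], np.cos(coh.phase[jj, kk][keep]),
              np.sin(coh.phase[jj, kk][keep]), scale=40, width=0.002, color="black")
    if mask is not None:
        ax.contour(t, periods, mask.astype(float), levels=[0.5], colors="black",
                   linewidths=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("Fourier period (s)")
    plt.colorbar(pcm, ax=ax, label="$R^2$")
    return ax
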