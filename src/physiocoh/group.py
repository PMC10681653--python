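"""Cohort assembly and group statistics.

``run_pipeline`` drives the full chain — raw physio traces -> frame-aligned
HBI/RVT -> wavelet coherence with each network's BOLD series -> AR-bootstrap
significance -> percent time with significant coherence per band — for every
subject in a study directory, producing one tidy row per (subject, signal,
network, band).

Group comparisons mirror the standard analysis of such tables: a one-way
repeated-measures ANOVA over networks (subject as the repeated factor,
uncorrected and Greenhouse-Geisser p-values both reported) and post-hoc
paired t-tests with Bonferroni correction (family of 21 network pairs, or 7
per-network contrasts when comparing two frequency bands).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import aggregate as agg
from .physio import (compute_hbi, compute_rvt, detect_breath_extrema,
                     detect_pulse_peaks, mean_normalize)
from .series import SampledSeries
from .significance import bootstrap_thresholds, fit_ar
from .synth import NETWORKS, StudyBundle, read_bold_table, read_two_col
from .variability import variability_test
from .wavelet import build_scale_grid, wtc

TABLE_COLUMNS = ("subject", "signal", "network", "band", "pct_time_sig")


@dataclass
class PipelineConfig:
    """Every numeric default of the full analysis in one place."""

    dt_frames: float = 0.72
    hbi_window: float = 6.0          # seconds
    dj: float = 1.0 / 12.0
    max_period: float | None = None  # seconds; None = half the record
    ar_order: int = 1
    n_boot: int = 300
    alpha: float = 0.05
    seed: int = 0
    bands: tuple = agg.DEFAULT_BANDS
    signals: tuple = ("HBI", "RVT")
    run_variability: bool = False
    variability_n_boot: int = 1000

    def band_specs(self) -> list[agg.BandSpec]:
        return [agg.BandSpec(*b) for b in self.bands]


def preprocess_subject(bundle: StudyBundle, sub: str,
                       cfg: PipelineConfig) -> dict[str, SampledSeries]:
    """Raw recordings -> mean-normalized, frame-aligned HBI, RVT and BOLD series."""
    bold = read_bold_table(bundle.bold_path(sub))
    n_frames = next(iter(bold.values())).n
    frame_times = cfg.dt_frames * np.arange(n_frames)
    pulse = read_two_col(bundle.pulse_path(sub))
    resp = read_two_col(bundle.resp_path(sub))
    hbi = compute_hbi(detect_pulse_peaks(pulse), frame_times, window=cfg.hbi_window)
    maxima, minima = detect_breath_extrema(resp)
    rvt = compute_rvt(maxima, minima, frame_times)
    out = {"HBI": mean_normalize(hbi), "RVT": mean_normalize(rvt)}
    for net, series in bold.items():
        series.dt = cfg.dt_frames
        out[net] = mean_normalize(series)
    return out


def run_pipeline(bundle: StudyBundle, cfg: PipelineConfig | None = None,
                 networks: tuple = NETWORKS) -> tuple[pd.DataFrame, dict]:
    """Execute the full per-subject analysis over a study; returns (table, artifacts).

    The table has one row per (subject, signal, network, band) with percent
    time significant; artifacts hold per-pair band profiles and (optionally)
    variability profiles keyed by (subject, signal, network).
    """
    cfg = cfg or PipelineConfig()
    rows: list[dict] = []
    artifacts: dict = {}
    bands = cfg.band_specs()
    pair_counter = 0
    for sub in bundle.subjects:
        series = preprocess_subject(bundle, sub, cfg)
        n = series["HBI"].n
        grid = build_scale_grid(cfg.dt_frames, n, dj=cfg.dj, max_period=cfg.max_period)
        for signal in cfg.signals:
            model_sig = fit_ar(series[signal], order=cfg.ar_order)
            for net in networks:
                pair_counter += 1
                model_net = fit_ar(series[net], order=cfg.ar_order)
                coh = wtc(series[signal], series[net], grid)
                thr = bootstrap_thresholds(model_sig, model_net, n, cfg.dt_frames,
                                           grid, n_boot=cfg.n_boot, alpha=cfg.alpha,
                                           seed=cfg.seed + 104729 * pair_counter)
                mask = agg.significance_mask(coh, thr)
                prof = agg.categorize_phase(coh, mask, bands)
                art = {"profile": prof}
                if cfg.run_variability:
                    art["variability"] = variability_test(
                        series[signal], series[net], grid,
                        n_boot=cfg.variability_n_boot, alpha=cfg.alpha,
                        seed=cfg.seed + 104729 * pair_counter + 1)
                artifacts[(sub, signal, net)] = art
                for b in bands:
                    rows.append({"subject": sub, "signal": signal, "network": net,
                                 "band": b.name, "pct_time_sig": prof.band_pct[b.name]})
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS)), artifacts


def _pivot(tbl: pd.DataFrame, signal: str, band: str) -> pd.DataFrame:
    sel = tbl[(tbl["signal"] == signal) & (tbl["band"] == band)]
    if sel.empty:
        raise ValueError(f"no rows for signal={signal}, band={band}")
    wide = sel.pivot(index="subject", columns="network", values="pct_time_sig")
    if wide.isna().any().any():
        raise ValueError("incomplete subject x network crossing")
    return wide


@dataclass
class RMAnovaResult:
    F: float
    p_uncorrected: float
    p_gg: float
    df1: float
    df2: float
    eps: float = 1.0


def rm_anova(tbl: pd.DataFrame, signal: str, band: str) -> RMAnovaResult:
    """One-way repeated-measures ANOVA of percent time significant over networks."""
    wide = _pivot(tbl, signal, band)
    data = wide.to_numpy()
    centered = data - data.mean(axis=1, keepdims=True)  # remove subject means
    if np.allclose(centered, 0.0, atol=1e-12):
        # no between-condition variance: F = 0 by construction
        return RMAnovaResult(F=0.0, p_uncorrected=1.0, p_gg=1.0,
                             df1=data.shape[1] - 1,
                             df2=(data.shape[0] - 1) * (data.shape[1] - 1))
    import pingouin as pg
    long = wide.reset_index().melt(id_vars="subject", var_name="network",
                                   value_name="pct")
    res = pg.rm_anova(data=long, dv="pct", within="network", subject="subject",
                      correction=True, detailed=False)
    row = res.iloc[0]
    p_unc = float(row["p_unc"])
    p_gg = float(row["p_GG_corr"]) if "p_GG_corr" in res.columns and np.isfinite(
        row["p_GG_corr"]) else p_unc
    eps = float(row["eps"]) if "eps" in res.columns and np.isfinite(row["eps"]) else 1.0
    return RMAnovaResult(F=float(row["F"]), p_uncorrected=p_unc, p_gg=p_gg,
                         df1=float(row["ddof1"]), df2=float(row["ddof2"]), eps=eps)


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Paired t-test with a degenerate-variance guard."""
    d = a - b
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, 1.0, False
        return (np.inf if d[0] > 0 else -np.inf), float(np.nextafter(0, 1)), True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False


def paired_tests_bonferroni(tbl: pd.DataFrame, signal: str, band: str,
                            alpha: float = 0.05) -> pd.DataFrame:
    """All 21 network-pair paired t-tests with Bonferroni-adjusted decisions."""
    wide = _pivot(tbl, signal, band)
    nets = list(wide.columns)
    pairs = list(itertools.combinations(nets, 2))
    m = len(pairs)
    rows = []
    for n1, n2 in pairs:
        t, p, degen = _paired_t(wide[n1].to_numpy(), wide[n2].to_numpy())
        rows.append({"rsn1": n1, "rsn2": n2, "t": t, "p": p,
                     "p_bonferroni": min(1.0, p * m),
                     "significant": p < alpha / m, "degenerate": degen})
    return pd.DataFrame(rows)


def band_contrast_tests(tbl: pd.DataFrame, signal: str, band_a: str, band_b: str,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-network paired t-tests between two bands, Bonferroni family = n networks."""
    wa = _pivot(tbl, signal, band_a)
    wb = _pivot(tbl, signal, band_b).loc[wa.index, wa.columns]
    m = len(wa.columns)
    rows = []
    for net in wa.columns:
        t, p, degen = _paired_t(wa[net].to_numpy(), wb[net].to_numpy())
        rows.append({"network": net, "band_a": band_a, "band_b": band_b, "t": t,
                     "p": p, "p_bonferroni": min(1.0, p * m),
                     "significant": p < alpha / m, "degenerate": degen})
    return pd.DataFrame(rows)
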