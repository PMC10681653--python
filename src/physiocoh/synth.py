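"""Synthetic raw-sensor and BOLD-like inputs with known ground-truth coupling.

The generator emulates the acquisition geometry of a 15-minute resting-state
scan: ~1200 imaging frames at TR = 0.72 s with seven network-average BOLD
series, plus pulse-oximeter and respiratory-bellow traces at 400 Hz.  Each
BOLD series is an AR(1) background; coupling is injected additively as a
band-limited shared sinusoid (configurable frequency, amplitude ratio, phase
lag, and on/off epochs), so every downstream estimate has an exact truth to
be checked against.  Pulse waveforms are raised-cosine pulse trains (only
the systolic peak times matter downstream) and bellows traces are 0.25 Hz
breathing oscillations whose amplitude tracks a target RVT profile.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .series import SampledSeries
from .significance import NonstationaryModelError, simulate_ar1

NETWORKS = ("DAN", "DMN", "FPN", "LN", "SMN", "VAN", "VN")

BREATH_RATE_HZ = 0.25           # base breathing rate
PULSE_WIDTH_S = 0.25            # raised-cosine systolic pulse width
SUBJECT_SEED_STRIDE = 7919      # per-subject seed offset (prime)


@dataclass
class CouplingScenario:
    """Ground-truth description of one synthetic recording session."""

    n_frames: int = 1200
    dt_frames: float = 0.72
    physio_rate: float = 400.0
    coupling_freq: float = 0.1
    coupling_strength: float = 1.0   # sinusoid amplitude / AR background sd
    phase_lag: float = 0.0           # radians, physio relative to BOLD (+ = physio trails)
    coupling_epochs: tuple | None = None   # (start_s, end_s) pairs; None = whole record
    ar_coeff_bold: float = 0.5
    ar_coeff_physio: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 64:
            raise ValueError("n_frames must be >= 64")
        nyq = 1.0 / (2.0 * self.dt_frames)
        if not 0 < self.coupling_freq < nyq:
            raise ValueError("coupling_freq must lie in (0, frame Nyquist)")
        for phi in (self.ar_coeff_bold, self.ar_coeff_physio):
            if abs(phi) >= 1:
                raise NonstationaryModelError("AR coefficients must satisfy |phi| < 1")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be non-negative")
        dur = self.n_frames * self.dt_frames
        if self.coupling_epochs is not None:
            for a, b in self.coupling_epochs:
                if not (0 <= a < b <= dur):
                    raise ValueError("coupling epochs must lie within the record")

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt_frames

    def epoch_mask(self, times: np.ndarray) -> np.ndarray:
        if self.coupling_epochs is None:
            return np.ones(times.size)
        m = np.zeros(times.size)
        for a, b in self.coupling_epochs:
            m[(times >= a) & (times < b)] = 1.0
        return m


def gen_ar1_series(phi: float, sigma: float, n: int, dt: float, seed: int = 0,
                   x0: float | None = None) -> SampledSeries:
    """Stationary-start AR(1) sample path x_t = phi x_{t-1} + eps_t."""
    rng = np.random.default_rng(seed)
    x = simulate_ar1(phi, sigma, n, rng)
    if x0 is not None:
        x = np.empty(n)
        x[0] = x0
        eps = np.random.default_rng(seed).normal(0.0, sigma, size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
    return SampledSeries(values=x, dt=dt, label=f"ar1(phi={phi})")


def gen_pulse_recording(beat_interval_profile: SampledSeries, physio_rate: float = 400.0,
                        seed: int = 0, noise_sd: float = 0.0) -> SampledSeries:
    """Pulse-oximeter-like waveform whose peak spacings follow the interval profile.

    The profile gives the instantaneous beat interval (s) as a function of
    time; beats are placed sequentially with the local interval, each a
    raised-cosine pulse.  Peak times are recoverable by peak detection to
    within one sample period.
    """
    prof = beat_interval_profile
    if prof.n == 0:
        raise ValueError("empty beat-interval profile")
    if np.any(prof.values < 0.3) or np.any(prof.values > 2.0):
        raise ValueError("beat intervals must lie in [0.3, 2.0] s")
    t_end = prof.t0 + prof.duration
    ptimes = []
    t = prof.t0 + 0.5  # lead-in so the first pulse is complete
    while t < t_end - PULSE_WIDTH_S:
        ptimes.append(t)
        t += float(np.interp(t, prof.times, prof.values))
    dt = 1.0 / physio_rate
    tt = np.arange(prof.t0, t_end, dt)
    wave = np.zeros(tt.size)
    half = PULSE_WIDTH_S / 2.0
    for tk in ptimes:
        sel = slice(max(0, int((tk - half - prof.t0) / dt)),
                    min(tt.size, int((tk + half - prof.t0) / dt) + 2))
        u = tt[sel] - tk
        inside = np.abs(u) < half
        wave[sel] += np.where(inside, 0.5 * (1 + np.cos(np.pi * u / half)), 0.0)
    if noise_sd > 0:
        wave += np.random.default_rng(seed).normal(0.0, noise_sd, wave.size)
    return SampledSeries(values=wave, dt=dt, t0=prof.t0, label="pulse")


def gen_respiration_recording(rvt_profile: SampledSeries, physio_rate: float = 400.0,
                              seed: int = 0, breath_rate: float = BREATH_RATE_HZ,
                              noise_sd: float = 0.0) -> SampledSeries:
    """Bellows-like oscillation whose per-breath RVT tracks the target profile.

    Breathing is a fixed-rate (default 0.25 Hz) cosine whose slowly varying
    amplitude A(t) = RVT(t) * period / 2 makes per-breath
    (peak - trough)/period equal the profile value at the breath.
    """
    prof = rvt_profile
    if prof.n == 0:
        raise ValueError("empty RVT profile")
    if np.any(prof.values <= 0):
        raise ValueError("RVT profile must be strictly positive")
    if physio_rate < 2.0 * breath_rate:
        raise ValueError("physio_rate below twice the breathing rate aliases breaths")
    period = 1.0 / breath_rate
    dt = 1.0 / physio_rate
    tt = np.arange(prof.t0, prof.t0 + prof.duration, dt)
    amp = np.interp(tt, prof.times, prof.values) * period / 2.0
    wave = amp * np.cos(2 * np.pi * breath_rate * (tt - prof.t0))
    if noise_sd > 0:
        wave += np.random.default_rng(seed).normal(0.0, noise_sd, wave.size)
    return SampledSeries(values=wave, dt=dt, t0=prof.t0, label="respiration")


def gen_coupled_pair(scn: CouplingScenario) -> tuple[SampledSeries, SampledSeries, dict]:
    """Frame-rate (BOLD-like, physio-like) pair with additive sinusoidal coupling.

    Both series are independent AR(1) backgrounds; inside the coupling epochs
    a shared sinusoid at ``coupling_freq`` is added to both, the physio copy
    delayed by phase_lag/(2*pi*f) seconds.  Amplitude = coupling_strength
    times the AR background's stationary sd.  Returns the pair plus the
    ground-truth metadata.
    """
    rng = np.random.default_rng(scn.seed)
    n, dt, f = scn.n_frames, scn.dt_frames, scn.coupling_freq
    t = dt * np.arange(n)
    bold_bg = simulate_ar1(scn.ar_coeff_bold, scn.noise_sd, n, rng)
    phys_bg = simulate_ar1(scn.ar_coeff_physio, scn.noise_sd, n, rng)
    sd_b = scn.noise_sd / np.sqrt(1 - scn.ar_coeff_bold**2)
    sd_p = scn.noise_sd / np.sqrt(1 - scn.ar_coeff_physio**2)
    mask = scn.epoch_mask(t)
    tau = scn.phase_lag / (2 * np.pi * f)
    bold = bold_bg + scn.coupling_strength * sd_b * mask * np.sin(2 * np.pi * f * t)
    phys = phys_bg + scn.coupling_strength * sd_p * mask * np.sin(2 * np.pi * f * (t - tau))
    truth = {"coupling_freq": f, "phase_lag": scn.phase_lag, "lag_seconds": tau,
             "coupling_epochs": scn.coupling_epochs, "coupling_strength": scn.coupling_strength}
    return (SampledSeries(bold, dt=dt, label="bold"),
            SampledSeries(phys, dt=dt, label="physio"), truth)


@dataclass
class StudyBundle:
    """Paths and ground truth of a generated multi-subject study."""

    root: Path
    subjects: list[str]
    manifest: dict = field(default_factory=dict)

    def pulse_path(self, sub: str) -> Path:
        return self.root / f"{sub}_pulse.tsv"

    def resp_path(self, sub: str) -> Path:
        return self.root / f"{sub}_resp.tsv"

    def bold_path(self, sub: str) -> Path:
        return self.root / f"{sub}_bold.tsv"


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def gen_study(n_subjects: int, scn_template: CouplingScenario, out_dir,
              between_subject_jitter: dict | None = None, seed: int = 0,
              coupled_networks: tuple = ("SMN", "VAN", "VN"),
              hbi_gain: float = 0.05, rvt_gain: float = 0.3) -> StudyBundle:
    """Write a synthetic cohort: raw physio traces + network BOLD tables + manifest.

    Per subject, one shared band-limited oscillation is injected into the
    coupled networks' BOLD series and (delayed by the scenario phase lag)
    into the fluctuation profiles that drive the pulse and bellows traces,
    so the full raw-sensor -> HBI/RVT -> coherence pipeline has a known
    answer.  ``between_subject_jitter`` maps scenario field names to sd's of
    additive Gaussian jitter.  Same seed => byte-identical outputs.
    """
    if n_subjects < 2:
        raise ValueError("a study needs at least 2 subjects")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jitter = between_subject_jitter or {}
    manifest = {"seed": seed, "template": _scenario_json(scn_template),
                "coupled_networks": list(coupled_networks), "networks": list(NETWORKS),
                "subjects": {}}
    bundle = StudyBundle(root=out, subjects=[])
    for s in range(n_subjects):
        sub = f"sub-{s + 1:02d}"
        sub_seed = seed + SUBJECT_SEED_STRIDE * (s + 1)
        rng = np.random.default_rng(sub_seed)
        scn = scn_template
        for name, sd in jitter.items():
            scn = replace(scn, **{name: getattr(scn, name) + rng.normal(0.0, sd)})
        scn = replace(scn, seed=sub_seed)
        n, dt, f = scn.n_frames, scn.dt_frames, scn.coupling_freq
        t = dt * np.arange(n)
        mask = scn.epoch_mask(t)
        tau = scn.phase_lag / (2 * np.pi * f)
        osc_bold = mask * np.sin(2 * np.pi * f * t)
        osc_phys = mask * np.sin(2 * np.pi * f * (t - tau))
        sd_b = scn.noise_sd / np.sqrt(1 - scn.ar_coeff_bold**2)

        bold = np.empty((n, len(NETWORKS)))
        for k, net in enumerate(NETWORKS):
            bg = simulate_ar1(scn.ar_coeff_bold, scn.noise_sd, n,
                              np.random.default_rng(sub_seed + 13 * (k + 1)))
            bold[:, k] = bg + (scn.coupling_strength * sd_b * osc_bold
                               if net in coupled_networks else 0.0)

        def physio_profile(offset: int) -> np.ndarray:
            bg = simulate_ar1(scn.ar_coeff_physio, scn.noise_sd, n,
                              np.random.default_rng(sub_seed + offset))
            sd_p = scn.noise_sd / np.sqrt(1 - scn.ar_coeff_physio**2)
            return _standardize(bg + scn.coupling_strength * sd_p * osc_phys)

        intervals = 1.0 / (1.0 + hbi_gain * np.clip(physio_profile(101), -3, 3))
        pulse = gen_pulse_recording(SampledSeries(intervals, dt=dt),
                                    scn.physio_rate, seed=sub_seed + 201)
        rvt = 0.5 * (1.0 + rvt_gain * np.clip(physio_profile(102), -3, 3))
        resp = gen_respiration_recording(SampledSeries(rvt, dt=dt),
                                         scn.physio_rate, seed=sub_seed + 202)

        _write_two_col(bundle.pulse_path(sub), pulse)
        _write_two_col(bundle.resp_path(sub), resp)
        _write_bold(bundle.bold_path(sub), bold)
        manifest["subjects"][sub] = {**_scenario_json(scn), "lag_seconds": tau,
                                     "hbi_gain": hbi_gain, "rvt_gain": rvt_gain}
        bundle.subjects.append(sub)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle.manifest = manifest
    return bundle


def _scenario_json(scn: CouplingScenario) -> dict:
    d = asdict(scn)
    if d["coupling_epochs"] is not None:
        d["coupling_epochs"] = [list(e) for e in d["coupling_epochs"]]
    return d


def _write_two_col(path: Path, rec: SampledSeries) -> None:
    arr = np.column_stack([rec.times, rec.values])
    np.savetxt(path, arr, fmt="%.6f", delimiter="\t",
               header="time_s\tvalue", comments="")


def _write_bold(path: Path, bold: np.ndarray) -> None:
    np.savetxt(path, bold, fmt="%.6f", delimiter="\t",
               header="\t".join(NETWORKS), comments="")


def read_two_col(path) -> SampledSeries:
    """Read a two-column (time_s, value) physio recording."""
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    t, v = arr[:, 0], arr[:, 1]
    dt = float(np.median(np.diff(t)))
    return SampledSeries(values=v, dt=dt, t0=float(t[0]), label=Path(path).stem)


def read_bold_table(path) -> dict[str, SampledSeries]:
    """Read a frames x networks BOLD table; returns one series per network.

    The frame spacing is not stored in the table; the caller's scenario or
    config supplies it via the returned series' dt (set to 0.72 by default).
    """
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    return {c: SampledSeries(values=df[c].to_numpy(), dt=0.72, label=c)
            for c in df.columns}
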