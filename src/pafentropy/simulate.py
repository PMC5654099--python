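"""Synthetic RR-interval and ECG generators with ground truth.

The generators emulate the statistical structure the classifier relies
on, at the study's nominal recording conditions (5-minute records, ECG at
128 Hz):

* ``NORMAL`` — sinus rhythm: mean RR with respiratory sinus arrhythmia
  (an HF oscillation, default 0.25 Hz), a slower LF oscillation (default
  0.1 Hz) and small beat-to-beat Gaussian jitter.
* ``DISTANT`` — records far from any fibrillation episode: the sinus
  process with moderately elevated jitter, reflecting the subtler
  autonomic disturbance seen away from episodes.
* ``PAF`` — the sinus process overlaid with a seeded two-state
  semi-Markov regime switch: runs of short, highly irregular intervals
  (mean reduced 25%, jitter doubled) interrupted by occasional long
  compensatory pauses (+60%), reproducing the fast-irregular-plus-pauses
  signature of paroxysmal atrial fibrillation.

ECG is synthesized by placing a sum-of-Gaussians PQRST beat template at
the cumulative RR times, plus configurable baseline wander, 50 Hz
powerline tone and white noise; exact R-peak sample positions are carried
as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError
from .hrv import RRSeries
from .preprocess import EcgRecord

__all__ = ["RRGenConfig", "EcgGenConfig", "simulate_rr", "simulate_ecg",
           "make_benchmark", "CLASS_TAGS"]

CLASS_TAGS = ("NORMAL", "PAF", "DISTANT")


@dataclass
class RRGenConfig:
    """Tachogram generator settings for one record."""

    class_tag: str = "NORMAL"
    duration_s: float = 300.0
    mean_rr_s: float = 0.8
    rsa_amp: float = 0.03     # HF (respiratory) modulation depth, s
    rsa_freq: float = 0.25    # Hz
    lf_amp: float = 0.04      # LF (baroreflex) modulation depth, s
    lf_freq: float = 0.1      # Hz
    noise_sd: float = 0.015   # beat-to-beat jitter SD, s
    distant_jitter_factor: float = 2.0   # DISTANT: jitter multiplier
    # PAF regime-switch parameters
    paf_mean_drop: float = 0.25       # AF-run mean RR reduction (fraction)
    paf_jitter_factor: float = 2.0    # AF-run jitter multiplier
    paf_pause_factor: float = 1.6     # long-pause multiplier
    paf_pause_prob: float = 0.08      # pause probability per AF beat
    paf_run_mean_beats: float = 20.0  # mean AF-run length (beats)
    paf_gap_mean_beats: float = 25.0  # mean sinus-run length (beats)
    artifact_rate: float = 0.0        # spike-injection probability per beat
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_tag not in CLASS_TAGS:
            raise ParameterError(f"unknown class tag {self.class_tag!r}")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if not 0.3 <= self.mean_rr_s <= 2.0:
            raise ParameterError("mean_rr_s outside physiologic [0.3, 2.0] s")
        for name in ("rsa_amp", "lf_amp", "noise_sd", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class EcgGenConfig:
    """ECG synthesis settings: beat morphology and noise terms."""

    fs: float = 128.0
    # (amplitude, offset from R in s, Gaussian width in s) per wave
    p_wave: tuple[float, float, float] = (0.12, -0.20, 0.025)
    q_wave: tuple[float, float, float] = (-0.10, -0.025, 0.010)
    r_wave: tuple[float, float, float] = (1.00, 0.0, 0.012)
    s_wave: tuple[float, float, float] = (-0.15, 0.025, 0.010)
    t_wave: tuple[float, float, float] = (0.30, 0.26, 0.045)
    noise_sd: float = 0.02
    baseline_wander_amp: float = 0.10
    baseline_wander_freq: float = 0.30
    powerline_amp: float = 0.02
    powerline_freq: float = 50.0

    def __post_init__(self) -> None:
        if self.fs < 60:
            raise ParameterError("fs must be >= 60 Hz")
        # need at least ~one sample per R-wave sigma to resolve the QRS
        if self.fs * self.r_wave[2] < 1.0:
            raise ParameterError("fs too low to resolve the QRS width")
        for name in ("noise_sd", "baseline_wander_amp", "powerline_amp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def simulate_rr(config: RRGenConfig) -> tuple[RRSeries, np.ndarray]:
    """Generate one RR series; returns (series, injected-artifact indices).

    Beat times advance by the generated intervals, so modulations are
    sampled at true beat onsets.  Reproducible bit-exactly from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    intervals: list[float] = []
    times: list[float] = []
    t = 0.0
    in_af = False
    run_left = 0

    # PAF starts in a sinus gap so episodes are intermittent
    if config.class_tag == "PAF":
        run_left = max(1, int(rng.exponential(config.paf_gap_mean_beats)))

    while t < config.duration_s:
        base = (config.mean_rr_s
                + config.rsa_amp * np.sin(2 * np.pi * config.rsa_freq * t)
                + config.lf_amp * np.sin(2 * np.pi * config.lf_freq * t))
        sd = config.noise_sd
        if config.class_tag == "DISTANT":
            sd *= config.distant_jitter_factor
        if config.class_tag == "PAF":
            if run_left <= 0:
                in_af = not in_af
                mean_beats = (config.paf_run_mean_beats if in_af
                              else config.paf_gap_mean_beats)
                run_left = max(1, int(rng.exponential(mean_beats)))
            run_left -= 1
            if in_af:
                base *= 1.0 - config.paf_mean_drop
                sd *= config.paf_jitter_factor
                if rng.random() < config.paf_pause_prob:
                    base *= config.paf_pause_factor
        rr = base + rng.normal(0.0, sd)
        rr = float(np.clip(rr, 0.25, 2.5))
        times.append(t)
        intervals.append(rr)
        t += rr

    intervals_arr = np.asarray(intervals)
    times_arr = np.asarray(times)
    injected = np.array([], dtype=int)
    if config.artifact_rate > 0:
        mask = rng.random(intervals_arr.size) < config.artifact_rate
        injected = np.flatnonzero(mask)
        # spikes well outside the physiologic window (missed/false beats)
        intervals_arr[injected] = rng.choice([3.0, 0.1], size=injected.size)
    series = RRSeries(times_arr, intervals_arr,
                      record_id=f"{config.class_tag.lower()}-{config.seed}",
                      label=config.class_tag)
    return series, injected


def _beat_template(t_rel: np.ndarray, cfg: EcgGenConfig) -> np.ndarray:
    out = np.zeros_like(t_rel)
    for amp, mu, width in (cfg.p_wave, cfg.q_wave, cfg.r_wave, cfg.s_wave,
                           cfg.t_wave):
        out += amp * np.exp(-0.5 * ((t_rel - mu) / width) ** 2)
    return out


def simulate_ecg(rr: RRSeries, config: EcgGenConfig | None = None,
                 seed: int = 0) -> EcgRecord:
    """Render an RR series into a raw ECG trace with ground-truth R peaks."""
    cfg = config or EcgGenConfig()
    rng = np.random.default_rng(seed)
    # R-peak times: onset of each interval shifted so the first R is at the
    # first onset; the final interval closes with one more beat
    r_times = np.concatenate([rr.times_s, [rr.times_s[-1]
                                           + rr.intervals_s[-1]]])
    duration = r_times[-1] + 0.4
    n = int(np.ceil(duration * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs
    ecg = np.zeros(n)
    half_window = 0.45  # beat template support, s
    for rt in r_times:
        lo = max(0, int((rt - half_window) * cfg.fs))
        hi = min(n, int((rt + half_window) * cfg.fs) + 1)
        ecg[lo:hi] += _beat_template(t[lo:hi] - rt, cfg)
    if cfg.baseline_wander_amp:
        ecg += cfg.baseline_wander_amp * np.sin(
            2 * np.pi * cfg.baseline_wander_freq * t + rng.uniform(0, 2 * np.pi))
    if cfg.powerline_amp and cfg.powerline_freq < cfg.fs / 2:
        ecg += cfg.powerline_amp * np.sin(2 * np.pi * cfg.powerline_freq * t)
    if cfg.noise_sd:
        ecg += rng.normal(0.0, cfg.noise_sd, n)
    true_r = np.round(r_times * cfg.fs).astype(int)
    true_r = true_r[(true_r >= 0) & (true_r < n)]
    return EcgRecord(ecg, cfg.fs, rr.record_id, true_r)


def make_benchmark(n_paf: int = 25, n_distant: int = 25, n_normal: int = 50,
                   seed: int = 0, duration_s: float = 300.0,
                   **overrides) -> list[RRSeries]:
    """Deterministic labeled benchmark mirroring the 25/25/50 study design.

    Per-record seeds are spawned from the master seed, so the dataset is a
    pure function of its arguments.  Returns the RR series; pair them as
    (PAF vs DISTANT) and (PAF vs NORMAL) for the two experiments.
    """
    counts = {"PAF": n_paf, "DISTANT": n_distant, "NORMAL": n_normal}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(sum(counts.values())) % (2 ** 31)
    records: list[RRSeries] = []
    i = 0
    for tag, n in counts.items():
        for k in range(n):
            cfg = RRGenConfig(class_tag=tag, duration_s=duration_s,
                              seed=int(child_seeds[i]), **overrides)
            series, _ = simulate_rr(cfg)
            series.record_id = f"{tag.lower()}{k:03d}"
            records.append(series)
            i += 1
    return records
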