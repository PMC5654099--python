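"""Comparison HRV feature families: time-domain, frequency-domain,
sample entropy and wavelet energy.

These are the four standard feature sets the wavelet-entropy method is
benchmarked against; each returns a small named feature vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import (
    DegenerateLevelError,
    InsufficientDataError,
    ParameterError,
    UndefinedEntropyError,
)
from .hrv import HrvSignal, RRSeries
from .wavelet import WaveletDecomposition

__all__ = ["BaselineFeatureSet", "time_domain", "freq_domain",
           "sample_entropy", "wavelet_energy", "HRV_BANDS"]

#: standard HRV spectral bands in Hz
HRV_BANDS = {"VLF": (0.0, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}


@dataclass
class BaselineFeatureSet:
    name: str  # TIME | FREQ | SAMPEN | WAVELET_ENERGY
    values: dict[str, float]
    record_id: str = ""
    label: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def time_domain(rr: RRSeries) -> BaselineFeatureSet:
    """Mean RR, SDNN, RMSSD and pNN50.

    SDNN is the sample standard deviation of RR; RMSSD the RMS of
    successive differences; pNN50 the fraction of successive differences
    exceeding 50 ms in magnitude.
    """
    if len(rr) < 3:
        raise InsufficientDataError("need >= 3 intervals")
    x = rr.intervals_s
    d = np.diff(x)
    return BaselineFeatureSet("TIME", {
        "mean_rr_s": float(np.mean(x)),
        "sdnn_s": float(np.std(x, ddof=1)),
        "rmssd_s": float(np.sqrt(np.mean(d ** 2))),
        "pnn50": float(np.mean(np.abs(d) > 0.050)),
    }, rr.record_id, rr.label)


def freq_domain(signal: HrvSignal, nperseg: int = 128) -> BaselineFeatureSet:
    """Relative band powers pVLF/pLF/pHF and the LF/HF ratio.

    Welch periodogram (Hann window, 50% overlap); band powers are
    integrated over the standard HRV bands and normalized by total power
    in (0, 0.4] Hz.
    """
    x = signal.values
    if x.size / signal.fs_hrv < 60:
        raise InsufficientDataError("need >= 60 s of uniformly sampled HRV")
    nperseg = min(nperseg, x.size)
    f, pxx = sps.welch(x - np.mean(x), fs=signal.fs_hrv, window="hann",
                       nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(lo: float, hi: float) -> float:
        m = (f > lo) & (f <= hi)
        return float(np.trapezoid(pxx[m], f[m])) if m.sum() > 1 else float(
            np.sum(pxx[m]))

    total = band_power(0.0, 0.4)
    vlf, lf, hf = (band_power(*HRV_BANDS[b]) for b in ("VLF", "LF", "HF"))
    if total == 0:
        raise DegenerateLevelError("zero spectral power in (0, 0.4] Hz")
    if hf == 0:
        warnings.warn("HF power is zero; LF/HF reported as +inf")
        ratio = float("inf")
    else:
        ratio = lf / hf
    return BaselineFeatureSet("FREQ", {
        "pVLF": vlf / total, "pLF": lf / total, "pHF": hf / total,
        "lf_hf_ratio": ratio,
    }, signal.record_id, signal.label)


def sample_entropy(rr: RRSeries, m: int = 2,
                   r_factor: float = 0.5) -> BaselineFeatureSet:
    """Sample entropy SampEn(m, r) of the RR tachogram.

    r = ``r_factor`` x sample SD of the series (the conventional half-SD
    tolerance by default); Chebyshev distance, self-matches excluded.
    SampEn = -ln(A/B) with B the number of ordered template pairs matching
    at length m and A those matching at length m+1.
    """
    x = rr.intervals_s
    if len(rr) < m + 2:
        raise InsufficientDataError(f"need >= {m + 2} intervals")
    if r_factor <= 0:
        raise ParameterError("r_factor must be > 0")
    sd = np.std(x, ddof=1)
    r = r_factor * sd if sd > 0 else r_factor  # constant series: any r works

    # both counts use the first N-m templates so A/B is a conditional
    # probability (canonical SampEn convention)
    n_tpl = x.size - m
    b = _chebyshev_pair_matches(x, m, n_tpl, r)
    a = _chebyshev_pair_matches(x, m + 1, n_tpl, r)
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            "no template matches; SampEn undefined for this series")
    return BaselineFeatureSet("SAMPEN", {"sampen": float(-np.log(a / b))},
                              rr.record_id, rr.label)


def _chebyshev_pair_matches(x: np.ndarray, length: int, n_templates: int,
                            r: float) -> int:
    """Count ordered template pairs (i < j) with Chebyshev distance <= r."""
    tpl = np.lib.stride_tricks.sliding_window_view(x, length)[:n_templates]
    count = 0
    for i in range(tpl.shape[0] - 1):
        d = np.max(np.abs(tpl[i + 1:] - tpl[i]), axis=1)
        count += int(np.sum(d <= r))
    return count


def wavelet_energy(decomp: WaveletDecomposition) -> BaselineFeatureSet:
    """Relative detail-energy per scale, E_j = ||D_j||^2 / sum_j ||D_j||^2."""
    if decomp.levels != 8:
        raise ParameterError("wavelet-energy baseline expects 8 levels")
    e = np.array([float(np.sum(d ** 2)) for d in decomp.details])
    total = e.sum()
    if total == 0:
        raise DegenerateLevelError("zero total detail energy")
    rel = e / total
    return BaselineFeatureSet(
        "WAVELET_ENERGY",
        {f"E{j}": float(rel[j - 1]) for j in range(1, 9)})
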