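"""RR-interval (tachogram) handling and HRV signal construction.

Converts R-peak trains into RR series, removes artifacts, and resamples
the irregular tachogram onto a uniform grid so that dyadic wavelet bands
carry their usual Hz interpretation.  The default resampling rate of 2 Hz
makes the finest detail band span 0.5-1 Hz, matching the convention that
the HRV signal's top frequency is 1 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import EmptySeriesError, InsufficientDataError, ParameterError
from .preprocess import RPeakList

__all__ = ["RRSeries", "HrvSignal", "rr_from_peaks", "clean_rr",
           "resample_uniform", "RR_FLOOR_S", "RR_CEIL_S"]

log = logging.getLogger(__name__)

#: physiologic RR window: 30-200 bpm
RR_FLOOR_S = 0.3
RR_CEIL_S = 2.0


@dataclass
class RRSeries:
    """Event-based RR intervals.

    ``times_s[i]`` is the onset time of interval ``i`` (the time of the
    R peak opening it); ``intervals_s[i]`` its duration in seconds.
    """

    times_s: np.ndarray
    intervals_s: np.ndarray
    record_id: str = ""
    label: str | None = None
    quality_warning: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intervals_s = np.asarray(self.intervals_s, dtype=float)
        if self.times_s.size != self.intervals_s.size:
            raise ParameterError("times_s and intervals_s must align")
        if self.times_s.size:
            if np.any(np.diff(self.times_s) <= 0):
                raise ParameterError("times_s must be strictly increasing")
            if np.any(self.intervals_s <= 0):
                raise ParameterError("all intervals must be positive")

    def __len__(self) -> int:
        return int(self.intervals_s.size)


@dataclass
class HrvSignal:
    """Uniformly resampled HRV signal f(t): RR magnitude vs time."""

    values: np.ndarray
    fs_hrv: float
    record_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_hrv <= 0:
            raise ParameterError("fs_hrv must be positive")

    def __len__(self) -> int:
        return int(self.values.size)


def rr_from_peaks(peaks: RPeakList) -> RRSeries:
    """RR intervals as distances between adjacent R peaks."""
    if len(peaks) < 2:
        raise InsufficientDataError("need >= 2 peaks to form RR intervals")
    idx = peaks.indices.astype(float)
    intervals = np.diff(idx) / peaks.fs
    times = idx[:-1] / peaks.fs
    return RRSeries(times, intervals, peaks.record_id)


def clean_rr(rr: RRSeries, floor_s: float = RR_FLOOR_S,
             ceil_s: float = RR_CEIL_S, median_window: int = 11,
             median_tol: float = 0.20) -> RRSeries:
    """Remove artifacts and outliers from an RR series.

    An interval is dropped when it falls outside the physiologic window
    ``[floor_s, ceil_s]`` or deviates from the ``median_window``-beat
    running median by more than ``median_tol`` (fractional).  Intervals are
    deleted, not imputed; onset times of surviving beats are retained.  The
    rule is iterated to a fixed point so the operation is idempotent.

    Sets ``quality_warning`` when more than 20% of intervals are removed;
    raises :class:`EmptySeriesError` when nothing survives.
    """
    if len(rr) == 0:
        raise InsufficientDataError("empty RR series")
    times = rr.times_s.copy()
    ivals = rr.intervals_s.copy()
    n_orig = ivals.size

    for _ in range(10):
        if ivals.size == 0:
            raise EmptySeriesError("all intervals removed by cleaning")
        half = median_window // 2
        padded = np.pad(ivals, half, mode="edge")
        runmed = np.array([np.median(padded[i:i + median_window])
                           for i in range(ivals.size)])
        ok = ((ivals >= floor_s) & (ivals <= ceil_s)
              & (np.abs(ivals - runmed) <= median_tol * runmed))
        if ok.all():
            break
        times, ivals = times[ok], ivals[ok]
    if ivals.size == 0:
        raise EmptySeriesError("all intervals removed by cleaning")

    removed = n_orig - ivals.size
    frac = removed / n_orig
    if removed:
        log.info("clean_rr[%s]: removed %d/%d intervals (%.1f%%)",
                 rr.record_id, removed, n_orig, 100 * frac)
    return RRSeries(times, ivals, rr.record_id, rr.label,
                    quality_warning=frac > 0.20)


def resample_uniform(rr: RRSeries, fs_hrv: float = 2.0) -> HrvSignal:
    """Cubic-spline resampling of the tachogram onto a uniform grid.

    The spline interpolates RR value against interval-onset time and is
    evaluated every ``1/fs_hrv`` seconds from the first onset; the output
    has ``floor(duration * fs_hrv)`` samples where duration spans first to
    last onset.
    """
    if fs_hrv <= 0:
        raise ParameterError("fs_hrv must be positive")
    if len(rr) < 4:
        raise InsufficientDataError("need >= 4 intervals for cubic spline")
    duration = rr.times_s[-1] - rr.times_s[0]
    n = int(np.floor(duration * fs_hrv))
    grid = rr.times_s[0] + np.arange(n) / fs_hrv
    spline = CubicSpline(rr.times_s, rr.intervals_s)
    return HrvSignal(spline(grid), fs_hrv, rr.record_id, rr.label)
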