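"""Raw accelerometer stream -> per-day overall activity intensity.

The chain, applied independently per calendar day and restricted to the
daytime window (default 07:00-22:00):

1. a short centred moving-average filter (0.12 s, i.e. 3 samples at 25 Hz)
   to suppress high-frequency noise;
2. a 4th-order Butterworth high-pass filter (1 Hz cutoff) to remove the
   gravity component;
3. the signal magnitude area (SMA): the summed area under the absolute
   filtered acceleration of all three axes, normalised by the epoch duration
   so day values remain comparable when in-window durations differ.  With the
   normalisation the SMA is the mean of |ax|+|ay|+|az| over the epoch (units
   of g).

The Butterworth filter is run forward-only (causal) per day segment with its
internal state initialised to the steady state of the first sample, so a
constant (gravity-only) input maps to an exactly-zero output and missing days
stay harmless.  A Gaussian-weighted moving average over the daily series is
provided for visualisation / pattern-rating support; it is not part of the
feature path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps


@dataclass(frozen=True)
class FilterConfig:
    ma_window_seconds: float = 0.12
    butter_order: int = 4
    butter_cutoff_hz: float = 1.0
    fs_hz: float = 25.0
    day_start_hour: float = 7.0
    day_end_hour: float = 22.0

    def __post_init__(self) -> None:
        if self.butter_cutoff_hz >= self.fs_hz / 2:
            raise ValueError("cutoff must be below the Nyquist frequency")
        if self.ma_window_samples < 1:
            raise ValueError("moving-average window must span at least one sample")
        if not self.day_start_hour < self.day_end_hour:
            raise ValueError("day window must be nonempty")

    @property
    def ma_window_samples(self) -> int:
        # nearest odd number of samples (0.12 s at 25 Hz -> 3)
        n = max(1, int(round(self.ma_window_seconds * self.fs_hz)))
        return n if n % 2 == 1 else n + 1


def moving_average(signal: np.ndarray, config: FilterConfig) -> np.ndarray:
    """Centred moving average; edges use shrinking windows (constants preserved)."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    w = config.ma_window_samples
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def butterworth_highpass(signal: np.ndarray, config: FilterConfig) -> np.ndarray:
    """Causal Butterworth high-pass; steady-state init zeroes constant inputs."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    b, a = sps.butter(config.butter_order, config.butter_cutoff_hz,
                      btype="highpass", fs=config.fs_hz)
    zi = sps.lfilter_zi(b, a) * x[0]
    y, _ = sps.lfilter(b, a, x, zi=zi)
    return y


def signal_magnitude_area(axes, epoch_seconds: float | None = None,
                          fs: float = 25.0) -> np.ndarray | float:
    """Per-epoch SMA of a triaxial signal.

    ``axes`` is a sequence of three equal-length arrays.  The SMA of an epoch
    of duration T is (1/T) * sum over axes of the integral of |a(t)| dt, i.e.
    the time-mean of |ax|+|ay|+|az|.  With ``epoch_seconds=None`` a single
    value over the whole stream is returned.
    """
    arrs = [np.asarray(a, dtype=float) for a in axes]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("all three axes must have the same length")
    if n == 0:
        raise ValueError("empty signal")
    total = np.abs(arrs[0]) + np.abs(arrs[1]) + np.abs(arrs[2])
    if epoch_seconds is None:
        return float(total.mean())
    ep = int(round(epoch_seconds * fs))
    if ep > n:
        raise ValueError("epoch longer than stream")
    n_epochs = n // ep
    return total[: n_epochs * ep].reshape(n_epochs, ep).mean(axis=1)


def daily_intensity(stream: pd.DataFrame, config: FilterConfig | None = None,
                    patient_id: str | None = None) -> tuple[pd.DataFrame, list[int]]:
    """Per-calendar-day overall intensity from a raw stream.

    Returns ``(daily, missing_days)`` where ``daily`` has columns
    ``rehab_day`` (1-based, contiguous over the covered span) and
    ``intensity``; days with no in-window samples are flagged missing and
    omitted from ``daily`` rather than reported as zero.
    """
    if config is None:
        config = FilterConfig()
    ts = pd.to_datetime(stream["timestamp"])
    order = np.argsort(ts.to_numpy(), kind="stable")
    ts = ts.iloc[order].reset_index(drop=True)
    data = stream.iloc[order].reset_index(drop=True)

    dates = ts.dt.normalize()
    first, last = dates.iloc[0], dates.iloc[-1]
    span = pd.date_range(first, last, freq="D")
    hours = (ts - dates).dt.total_seconds() / 3600.0
    in_window = (hours >= config.day_start_hour) & (hours < config.day_end_hour)

    rows, missing = [], []
    for day_idx, date in enumerate(span, start=1):
        m = in_window & (dates == date).to_numpy()
        if not m.any():
            missing.append(day_idx)
            continue
        filtered = []
        for axis in ("ax", "ay", "az"):
            x = data.loc[m, axis].to_numpy(dtype=float)
            x = moving_average(x, config)
            x = butterworth_highpass(x, config)
            filtered.append(x)
        rows.append((day_idx, signal_magnitude_area(filtered, fs=config.fs_hz)))
    daily = pd.DataFrame(rows, columns=["rehab_day", "intensity"])
    if patient_id is not None:
        daily.insert(0, "patient_id", patient_id)
    return daily, missing


def gaussian_smooth(series: np.ndarray, window_days: int = 5,
                    std: float | None = None) -> np.ndarray:
    """Gaussian-weighted moving average of a daily series.

    The kernel is a normalised Gaussian over ``window_days`` days (default
    sigma = (window-1)/4); edge weights are renormalised, so a constant series
    is preserved exactly and the interior of a linear ramp is unchanged.
    """
    x = np.asarray(series, dtype=float)
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if x.size == 0:
        raise ValueError("empty series")
    if std is None:
        std = max((window_days - 1) / 4.0, 1e-12)
    kernel = sps.windows.gaussian(window_days, std)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
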