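"""Calcium-trace processing for freely-moving and immobilized paradigms.

Freely-moving path: background subtraction, 10-frame (1 s at 10 fps) moving
median, baseline = 5th percentile of the smoothed trace, dF/F0 =
(smoothed - baseline)/baseline, peak detection with FWHM durations, and
binning of the signal by the animal's signed distance to the lawn boundary
(0.5 mm bins) with a two-way feeding-state x distance-bin ANOVA.

Immobilized (microfluidic odor-delivery) path: F0 = mean fluorescence over
seconds 2-3 of the trial, percent change = (F/F0 - 1) * 100, and epoch
maxima over Pre (0.0-4.9 s), Stim (5.0-15.0 s) and Post (15.1-29.9 s)
windows, bounds inclusive as printed; samples in the 4.9-5.0 s gap belong to
neither epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import stats
from .synthetic_data import LawnGeometry, Recording


@dataclass
class DffTrace:
    """dF/F0 trace with the smoothed series and scalar baseline it used."""

    time: np.ndarray
    dff: np.ndarray
    baseline: float
    smoothed: np.ndarray


@dataclass(frozen=True)
class Peak:
    """Detected transient: peak time/amplitude, FWHM duration, frame span."""

    time: float
    amplitude: float
    duration: float
    start: int
    end: int


@dataclass(frozen=True)
class EpochConfig:
    """Trial epoch windows (seconds), bounds inclusive."""

    pre: tuple[float, float] = (0.0, 4.9)
    stim: tuple[float, float] = (5.0, 15.0)
    post: tuple[float, float] = (15.1, 29.9)
    f0_window: tuple[float, float] = (2.0, 3.0)


def subtract_background(rec: Recording) -> np.ndarray:
    """Elementwise neuron minus background fluorescence (may dip negative)."""
    if rec.f_neuron.size != rec.f_background.size:
        raise ValueError("neuron and background series lengths differ")
    return rec.f_neuron - rec.f_background


def moving_median(series, window: int = 10) -> np.ndarray:
    """Centered sliding-window median; edge windows truncate to available samples.

    For window w the sample at index i uses indices
    [i - (w-1)//2, i + w//2] clipped to the series; output length equals
    input length.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    left = (window - 1) // 2
    right = window // 2
    n = x.size
    return np.array([
        np.median(x[max(0, i - left):min(n, i + right + 1)]) for i in range(n)
    ])


def percentile_baseline(series, q: float = 5.0) -> float:
    """q-th percentile of the series (linear interpolation between order stats).

    Raises if the result is not positive, since dF/F0 would be undefined.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    baseline = float(np.percentile(x, q))
    if baseline <= 0:
        raise ValueError(f"baseline {baseline:.3g} is not positive; "
                         "dF/F0 undefined")
    return baseline


def compute_dff(rec: Recording, window: int = 10, q: float = 5.0) -> DffTrace:
    """Full freely-moving dF/F0 pipeline on one recording.

    Background-subtract, smooth with a ``window``-frame moving median, take
    the ``q``-th percentile of the smoothed trace as baseline, and return
    (smoothed - baseline) / baseline.
    """
    sub = subtract_background(rec)
    smoothed = moving_median(sub, window=window)
    baseline = percentile_baseline(smoothed, q=q)
    dff = (smoothed - baseline) / baseline
    return DffTrace(time=rec.time, dff=dff, baseline=baseline, smoothed=smoothed)


def detect_peaks(
    trace: DffTrace, min_amplitude: float = 0.2, min_separation: float = 2.0
) -> list[Peak]:
    """Local dF/F0 maxima above ``min_amplitude``, >= ``min_separation`` s apart.

    Duration is the full width at half maximum: the extent of the contiguous
    region around the peak where dff >= amplitude / 2.
    """
    if min_amplitude <= 0 or min_separation <= 0:
        raise ValueError("thresholds must be positive")
    dff = trace.dff
    if dff.size < 3:
        return []
    dt = float(np.median(np.diff(trace.time)))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(dff, height=min_amplitude, distance=distance)
    peaks = []
    for i in idx:
        half = dff[i] / 2.0
        start = i
        while start > 0 and dff[start - 1] >= half:
            start -= 1
        end = i
        while end < dff.size - 1 and dff[end + 1] >= half:
            end += 1
        peaks.append(Peak(time=float(trace.time[i]), amplitude=float(dff[i]),
                          duration=float((end - start + 1) * dt),
                          start=int(start), end=int(end)))
    return peaks


def microfluidic_percent_change(
    f, time=None, cfg: EpochConfig = EpochConfig(), frame_rate: float = 10.0
) -> tuple[np.ndarray, float, float, float]:
    """Percent fluorescence change and Pre/Stim/Post epoch maxima.

    F0 is the mean fluorescence over ``cfg.f0_window``; the percent series is
    (F / F0 - 1) * 100. Epoch maxima are taken over the inclusive windows; a
    sample at exactly 5.0 s counts toward Stim, not Pre.
    """
    f = np.asarray(f, dtype=float)
    if time is None:
        time = np.arange(f.size) / frame_rate
    time = np.asarray(time, dtype=float)
    lo, hi = cfg.f0_window
    in_f0 = (time >= lo) & (time <= hi)
    if not in_f0.any():
        raise ValueError("f0_window contains no samples")
    f0 = float(f[in_f0].mean())
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    percent = (f / f0 - 1.0) * 100.0

    def _epoch_max(window):
        m = (time >= window[0]) & (time <= window[1])
        return float(percent[m].max()) if m.any() else float("nan")

    return percent, _epoch_max(cfg.pre), _epoch_max(cfg.stim), _epoch_max(cfg.post)


def distance_to_lawn(position, lawn: LawnGeometry) -> np.ndarray:
    """Signed Euclidean distance (mm) to the lawn boundary.

    Positive outside the lawn, zero on the boundary, negative inside, so
    pre- and post-encounter frames share one continuous axis.
    """
    pos = np.asarray(position, dtype=float)
    return np.hypot(pos[:, 0] - lawn.center[0], pos[:, 1] - lawn.center[1]) - lawn.radius


def bin_dff_by_distance(dff, distance, bin_width: float = 0.5) -> pd.DataFrame:
    """Mean, SEM and frame count of dF/F0 per half-open distance bin [d, d+w).

    Bins span the occupied range; bins with no frames are reported with
    n = 0 and NaN mean/SEM.
    """
    dff = np.asarray(dff, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if dff.size != distance.size:
        raise ValueError("dff and distance lengths differ")
    if dff.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "mean", "sem", "n"])
    idx = np.floor(distance / bin_width).astype(int)
    rows = []
    for b in range(idx.min(), idx.max() + 1):
        sel = dff[idx == b]
        n = sel.size
        rows.append({
            "bin_left": b * bin_width,
            "bin_right": (b + 1) * bin_width,
            "mean": float(sel.mean()) if n else float("nan"),
            "sem": float(sel.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            "n": n,
        })
    return pd.DataFrame(rows)


def state_effect_anova(binned: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Two-way fixed-effects ANOVA of per-animal bin means: state x bin.

    ``binned`` is long format with columns animal, state, bin, value (one row
    per animal per distance bin). Returns {"state": (F, p), "bin": (F, p),
    "interaction": (F, p)}.
    """
    required = {"animal", "state", "bin", "value"}
    if not required <= set(binned.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if binned["state"].nunique() < 2 or binned["bin"].nunique() < 2:
        raise ValueError("need >= 2 states and >= 2 bins")
    return stats.two_way_anova(binned, value="value", factor_a="state",
                               factor_b="bin")
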