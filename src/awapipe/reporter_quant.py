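"""Fluorescence reporter quantification from confocal z-stacks.

The scoring scheme mirrors common practice for transcriptional reporters in
*C. elegans* neurons: maximum-intensity z-projection, a box ROI around the
soma, score = mean of the top 5% of ROI pixels (neural signal) minus mean of
the bottom 5% (background), then per-session normalization to the mean of a
fed wild-type control group imaged the same day, and two-tailed t-tests with
Bonferroni correction between groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import stats
from .synthetic_data import ImageStack


@dataclass(frozen=True)
class ROI:
    """Half-open bounding box (y0:y1, x0:x1) in pixel coordinates."""

    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self):
        if not (self.y1 > self.y0 and self.x1 > self.x0):
            raise ValueError("ROI must have positive extent")

    def extract(self, image: np.ndarray) -> np.ndarray:
        return image[self.y0:self.y1, self.x0:self.x1]

    @property
    def center(self) -> tuple[float, float]:
        return ((self.y0 + self.y1 - 1) / 2.0, (self.x0 + self.x1 - 1) / 2.0)


def max_projection(stack) -> np.ndarray:
    """Maximum-intensity projection along z; pixel (y, x) = max over z."""
    arr = stack.intensities if isinstance(stack, ImageStack) else np.asarray(stack)
    if arr.ndim != 3 or arr.size == 0:
        raise ValueError("expected a non-empty 3-D stack")
    return arr.max(axis=0)


def locate_soma_roi(image: np.ndarray, box_halfwidth: int = 10) -> ROI:
    """Box ROI centred on the brightest connected component of the image.

    The image is median-filtered (3x3), thresholded at median + 5 * robust
    sigma (MAD-based), and the centroid of the connected component containing
    the brightest filtered pixel becomes the box center. The box is clipped
    to the image bounds.

    Raises
    ------
    ValueError
        If no pixel rises above the background (flat image).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    filt = ndimage.median_filter(img, size=3)
    med = np.median(filt)
    sigma = 1.4826 * np.median(np.abs(filt - med))
    thr = med + 5.0 * sigma
    mask = filt > thr
    if not mask.any():
        raise ValueError("no soma detected: image is flat above background")
    labels, _ = ndimage.label(mask)
    bright_label = labels[np.unravel_index(np.argmax(np.where(mask, filt, -np.inf)),
                                           filt.shape)]
    comp = labels == bright_label
    # centroid weighted by background-subtracted intensity; weighting with
    # the flat offset included would drag the center toward the component's
    # geometric middle
    cy, cx = ndimage.center_of_mass(np.clip(filt - med, 0, None) * comp)
    cy, cx = int(round(cy)), int(round(cx))
    ny, nx = img.shape
    y0 = max(0, cy - box_halfwidth)
    y1 = min(ny, cy + box_halfwidth + 1)
    x0 = max(0, cx - box_halfwidth)
    x1 = min(nx, cx + box_halfwidth + 1)
    return ROI(y0, y1, x0, x1)


def percentile_score(roi_pixels) -> float:
    """mean(top 5% of pixels) - mean(bottom 5% of pixels).

    Tail size is ceil(0.05 * n); at least 20 pixels are required so both
    tails are non-empty. The score is order-invariant and non-negative.
    """
    px = np.sort(np.asarray(roi_pixels, dtype=float).ravel())
    n = px.size
    if n < 20:
        raise ValueError(f"need >= 20 pixels for 5% tails, got {n}")
    k = math.ceil(0.05 * n)
    return float(px[-k:].mean() - px[:k].mean())


def score_stack(stack, box_halfwidth: int = 10) -> float:
    """Full single-stack pipeline: project, locate soma, percentile score."""
    image = max_projection(stack)
    roi = locate_soma_roi(image, box_halfwidth=box_halfwidth)
    return percentile_score(roi.extract(image))


def normalize_by_control(scores: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Divide each raw score by its session's control-group mean raw score.

    ``scores`` needs columns sample, session, group, raw. Every session must
    contain at least one control animal with a positive mean raw score.
    Returns a copy with a ``normalized`` column; within each session the
    control group's normalized values average to 1 by construction.
    """
    out = scores.copy()
    control_means = {}
    for session, sub in out.groupby("session"):
        ctrl = sub.loc[sub["group"] == control_group, "raw"]
        if ctrl.empty:
            raise ValueError(f"session {session!r} has no {control_group!r} controls")
        mean = float(ctrl.mean())
        if mean <= 0:
            raise ValueError(f"session {session!r} control mean is not positive")
        control_means[session] = mean
    out["normalized"] = out["raw"] / out["session"].map(control_means)
    return out


def compare_conditions(
    scores: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    value: str = "normalized",
) -> pd.DataFrame:
    """Two-tailed t-tests between groups, Bonferroni over requested pairs."""
    results = []
    m = len(comparisons)
    for g1, g2 in comparisons:
        a = scores.loc[scores["group"] == g1, value].to_numpy()
        b = scores.loc[scores["group"] == g2, value].to_numpy()
        res = stats.two_sample_t(a, b, n_comparisons=m)
        results.append({"group_a": g1, "group_b": g2, "t": res.statistic,
                        "p_raw": res.p_raw, "p_adj": res.p_adj})
    return pd.DataFrame(results)
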