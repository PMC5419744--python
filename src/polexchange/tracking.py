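"""Fork tracking and rate/processivity quantification from kymographs.

The fork is the leading bright spot in each kymograph column; deposited
(stationary) spots trail behind it, so the tracker takes the furthest spot
above threshold that does not backtrack by more than a small tolerance.
Rates are measured per constant-slope trajectory segment found by exact
penalized piecewise-linear change-point fitting.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .changepoint import LinearCost, estimate_noise_sd_linear, optimal_partition
from .datatypes import (Kymograph, ProcessivityFit, RateFit,
                        ReplicationTrajectory, SegmentFit)

__all__ = ["track_fork", "PiecewiseLinearSegmenter", "segment_trajectory",
           "fit_rate_distribution", "fit_processivity", "TrackingError"]


class TrackingError(RuntimeError):
    pass


def track_fork(kymo: Kymograph, threshold: float | None = None,
               backtrack_px: float = 2.0) -> ReplicationTrajectory:
    """Track the moving fork tip through a kymograph.

    Per column, candidate rows are those at or beyond the previous fork
    position minus ``backtrack_px``; the brightest candidate above
    ``threshold`` is taken and refined to sub-pixel precision by an
    intensity-weighted centroid over a +-2 px window.  Columns with no spot
    above threshold become gaps (interpolated, flagged); more than 50% gaps
    aborts.
    """
    img = np.asarray(kymo.image, dtype=float)
    n_rows, n_frames = img.shape
    if threshold is None:
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med))) * 1.4826
        threshold = med + 6.0 * max(mad, 1e-12)

    rows = np.full(n_frames, np.nan)
    prev = float(np.argmax(img[:, 0]))
    for j in range(n_frames):
        lo = max(0, int(np.floor(prev - backtrack_px)))
        col = img[:, j]
        cand = col[lo:]
        if cand.size == 0 or cand.max() < threshold:
            continue
        # the fork is the LEADING spot: take the furthest local maximum
        # above threshold, not the brightest (deposits trail the fork)
        above = cand >= threshold
        interior = np.zeros_like(above)
        interior[1:-1] = above[1:-1] & (cand[1:-1] >= cand[:-2]) \
            & (cand[1:-1] >= cand[2:])
        interior[0] = above[0] and (cand.size == 1 or cand[0] >= cand[1])
        interior[-1] = above[-1] and (cand.size == 1 or cand[-1] >= cand[-2])
        peaks = np.flatnonzero(interior)
        peak = lo + int(peaks[-1]) if len(peaks) else lo + int(np.argmax(cand))
        w0, w1 = max(0, peak - 2), min(n_rows, peak + 3)
        weights = np.clip(col[w0:w1] - np.median(col), 0, None)
        if weights.sum() > 0:
            rows[j] = float(np.sum(np.arange(w0, w1) * weights) / weights.sum())
        else:
            rows[j] = float(peak)
        prev = rows[j]

    gaps = np.isnan(rows)
    if gaps.mean() > 0.5:
        raise TrackingError(f"{gaps.mean():.0%} of columns have no spot above threshold")
    if gaps.any():
        idx = np.arange(n_frames)
        rows[gaps] = np.interp(idx[gaps], idx[~gaps], rows[~gaps])

    times = np.arange(n_frames) * kymo.frame_interval_s
    return ReplicationTrajectory(times=times, length_bp=np.asarray(kymo.row_to_bp(rows)),
                                 gaps=gaps)


class PiecewiseLinearSegmenter(BaseEstimator):
    """Exact penalized piecewise-linear segmentation of a trajectory.

    Total cost = residual sum of squares + ``penalty`` x (number of change
    points); ``penalty=None`` uses ``4 * sigma^2 * ln(n)`` with a robust
    noise estimate from second differences.

    Attributes (after fit)
    ----------------------
    breakpoints_ : list of int
        Segment start frames (excluding 0).
    segments_ : list of SegmentFit
    cost_ : float
    """

    def __init__(self, penalty: float | None = None, min_duration_s: float = 2.0):
        self.penalty = penalty
        self.min_duration_s = min_duration_s

    def fit(self, times, length_bp):
        t = np.asarray(times, dtype=float)
        y = np.asarray(length_bp, dtype=float)
        if len(t) < 4:
            raise ValueError("need at least 4 frames to segment")
        dt = float(np.median(np.diff(t)))
        if dt <= 0 or np.ptp(t) == 0:
            raise ValueError("degenerate (constant-time) trajectory")
        min_size = max(2, int(np.ceil(self.min_duration_s / dt)))
        penalty = self.penalty
        if penalty is None:
            sigma = max(estimate_noise_sd_linear(y), 1e-9)
            penalty = 4.0 * sigma ** 2 * np.log(len(y))
        cost = LinearCost(t, y)
        bps, total = optimal_partition(cost, len(y), penalty, min_size=min_size)
        bounds = [0] + list(bps) + [len(y)]
        segs = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            slope, intercept = cost.line(a, b)
            resid = y[a:b] - (slope * t[a:b] + intercept)
            segs.append(SegmentFit(t_start=float(t[a]), t_end=float(t[b - 1]),
                                   slope_bp_s=float(slope),
                                   intercept_bp=float(intercept),
                                   residual_sd_bp=float(resid.std())))
        self.breakpoints_ = list(bps)
        self.segments_ = segs
        self.cost_ = float(total)
        self.penalty_ = float(penalty)
        return self


def segment_trajectory(traj: ReplicationTrajectory, min_duration_s: float = 2.0,
                       penalty: float | None = None) -> list[SegmentFit]:
    """Segment a trajectory into constant-slope pieces (thin wrapper)."""
    seg = PiecewiseLinearSegmenter(penalty=penalty, min_duration_s=min_duration_s)
    seg.fit(traj.times, traj.length_bp)
    return seg.segments_


def _freedman_diaconis_bins(x: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(x, [75, 25])
    width = 2 * (q75 - q25) / len(x) ** (1 / 3)
    if width <= 0:
        width = max(1e-9, np.ptp(x) / 10 or 1.0)
    nbins = max(3, int(np.ceil(np.ptp(x) / width)) if np.ptp(x) > 0 else 3)
    return np.linspace(x.min() - width / 2, x.max() + width / 2, nbins + 1)


def fit_rate_distribution(slopes) -> RateFit:
    """Gaussian fit of the segment-rate histogram (Freedman-Diaconis bins).

    Reported error is the standard error of the mean.  With fewer than five
    segments the sample mean is returned, flagged.
    """
    x = np.asarray(list(slopes), dtype=float)
    n = len(x)
    if n < 1:
        raise ValueError("no slopes provided")
    sem = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    if n < 5:
        return RateFit(mean_bp_s=float(x.mean()), sem_bp_s=sem, n=n,
                       flagged=True, note="n < 5: sample mean reported")
    if np.allclose(x, x[0]):
        return RateFit(mean_bp_s=float(x[0]), sem_bp_s=0.0, n=n)
    edges = _freedman_diaconis_bins(x)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(v, amp, mu, sd):
        return amp * np.exp(-0.5 * ((v - mu) / sd) ** 2)

    try:
        p0 = [counts.max(), x.mean(), max(x.std(), 1e-9)]
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10_000)
        mu = float(popt[1])
    except RuntimeError:
        return RateFit(mean_bp_s=float(x.mean()), sem_bp_s=sem, n=n,
                       flagged=True, note="histogram fit failed; sample mean reported")
    return RateFit(mean_bp_s=mu, sem_bp_s=sem, n=n)


def fit_processivity(final_lengths_bp) -> ProcessivityFit:
    """Exponential-mean processivity fit (maximum likelihood on lengths).

    The MLE of a single-exponential decay is the sample mean; its standard
    error is mean/sqrt(n).  Degenerate (zero-variance) inputs are flagged.
    """
    x = np.asarray(list(final_lengths_bp), dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 molecules for a processivity fit")
    if np.any(x <= 0):
        raise ValueError("processivities must be positive")
    mean = float(x.mean())
    err = mean / np.sqrt(len(x))
    if np.allclose(x, x[0]):
        return ProcessivityFit(mean_bp=mean, error_bp=err, n=len(x), flagged=True,
                               note="degenerate input: all lengths equal")
    return ProcessivityFit(mean_bp=mean, error_bp=err, n=len(x))
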