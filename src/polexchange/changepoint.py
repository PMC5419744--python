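"""Exact penalized least-squares change-point detection.

Minimizes ``sum of segment RSS + penalty * (number of change points)`` over
all partitions of the signal into contiguous segments of at least
``min_size`` frames, by O(n^2) dynamic programming with O(1) segment costs
from prefix sums.  The optimum is exact; on cost ties the lexicographically
smallest change-point sequence (earliest change points) wins.

Two segment models are provided: piecewise-constant (photobleaching steps)
and piecewise-linear in time (replication trajectory segments).
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConstantCost", "LinearCost", "optimal_partition",
           "estimate_noise_sd_const", "estimate_noise_sd_linear"]


class ConstantCost:
    """RSS of fitting a constant to y[i:j]."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        self.s1 = np.concatenate([[0.0], np.cumsum(y)])
        self.s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def __call__(self, i: int, j: int) -> float:
        m = j - i
        sy = self.s1[j] - self.s1[i]
        syy = self.s2[j] - self.s2[i]
        return max(0.0, syy - sy * sy / m)

    def vector(self, i_arr: np.ndarray, j: int) -> np.ndarray:
        m = j - i_arr
        sy = self.s1[j] - self.s1[i_arr]
        syy = self.s2[j] - self.s2[i_arr]
        return np.maximum(0.0, syy - sy * sy / m)

    def level(self, i: int, j: int) -> float:
        return (self.s1[j] - self.s1[i]) / (j - i)


class LinearCost:
    """RSS of fitting a straight line to (x, y)[i:j]."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.zeros(1)
        self.sx = np.concatenate([z, np.cumsum(x)])
        self.sy = np.concatenate([z, np.cumsum(y)])
        self.sxx = np.concatenate([z, np.cumsum(x * x)])
        self.sxy = np.concatenate([z, np.cumsum(x * y)])
        self.syy = np.concatenate([z, np.cumsum(y * y)])

    def _moments(self, i: int, j: int):
        m = j - i
        sx = self.sx[j] - self.sx[i]
        sy = self.sy[j] - self.sy[i]
        sxx_c = (self.sxx[j] - self.sxx[i]) - sx * sx / m
        sxy_c = (self.sxy[j] - self.sxy[i]) - sx * sy / m
        syy_c = (self.syy[j] - self.syy[i]) - sy * sy / m
        return m, sx, sy, sxx_c, sxy_c, syy_c

    def __call__(self, i: int, j: int) -> float:
        m, _, _, sxx_c, sxy_c, syy_c = self._moments(i, j)
        if m < 2 or sxx_c <= 0:
            return max(0.0, syy_c)
        return max(0.0, syy_c - sxy_c * sxy_c / sxx_c)

    def vector(self, i_arr: np.ndarray, j: int) -> np.ndarray:
        m = j - i_arr
        sx = self.sx[j] - self.sx[i_arr]
        sy = self.sy[j] - self.sy[i_arr]
        sxx_c = (self.sxx[j] - self.sxx[i_arr]) - sx * sx / m
        sxy_c = (self.sxy[j] - self.sxy[i_arr]) - sx * sy / m
        syy_c = (self.syy[j] - self.syy[i_arr]) - sy * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = np.where(sxx_c > 0, sxy_c * sxy_c / np.maximum(sxx_c, 1e-300), 0.0)
        return np.maximum(0.0, syy_c - fit)

    def line(self, i: int, j: int) -> tuple[float, float]:
        """(slope, intercept) of the OLS line on [i, j)."""
        m, sx, sy, sxx_c, sxy_c, _ = self._moments(i, j)
        slope = sxy_c / sxx_c if sxx_c > 0 else 0.0
        intercept = (sy - slope * sx) / m
        return slope, intercept


def optimal_partition(cost, n: int, penalty: float, min_size: int = 1,
                      max_changepoints: int | None = None):
    """Exact optimal change points for the penalized segment cost.

    Parameters
    ----------
    cost : callable
        ``cost(i, j)`` = fit cost of the half-open segment [i, j).
    n : int
        Signal length.
    penalty : float
        Cost added per change point.
    min_size : int
        Minimum segment length in frames.
    max_changepoints : int, optional
        Hard cap on the number of change points.

    Returns
    -------
    change_points : list of int
        Strictly increasing segment start indices (excluding 0).
    total_cost : float
    """
    if n < min_size:
        return [], cost(0, n) if n > 0 else 0.0
    INF = float("inf")
    best_cost = np.full(n + 1, INF)
    best_bps: list[tuple] = [()] * (n + 1)
    best_k = np.zeros(n + 1, dtype=int)
    best_cost[0] = 0.0
    use_vector = hasattr(cost, "vector") and max_changepoints is None
    for j in range(min_size, n + 1):
        cand_i = [i for i in range(0, j - min_size + 1)
                  if (i == 0 or i >= min_size) and best_cost[i] < INF]
        if not cand_i:
            continue
        i_arr = np.asarray(cand_i)
        if use_vector:
            totals = (best_cost[i_arr] + cost.vector(i_arr, j)
                      + np.where(i_arr > 0, penalty, 0.0))
        else:
            totals = np.array([best_cost[i] + cost(i, j)
                               + (penalty if i > 0 else 0.0) for i in cand_i])
            if max_changepoints is not None:
                ks = best_k[i_arr] + (i_arr > 0)
                totals[ks > max_changepoints] = INF
        kmin = int(np.argmin(totals))
        cmin = totals[kmin]
        if cmin == INF:
            continue
        # on exact cost ties the lexicographically smallest change-point
        # sequence (earliest change points) wins
        ties = np.flatnonzero(totals == cmin)
        pick = cand_i[kmin]
        if len(ties) > 1:
            pick = min((best_bps[cand_i[t]] + ((cand_i[t],) if cand_i[t] else ()), cand_i[t])
                       for t in ties)[1]
        best_cost[j] = cmin
        best_bps[j] = best_bps[pick] + ((pick,) if pick > 0 else ())
        best_k[j] = best_k[pick] + (1 if pick > 0 else 0)
    return list(best_bps[n]), float(best_cost[n])


def estimate_noise_sd_const(y: np.ndarray) -> float:
    """Robust noise sd for a piecewise-constant signal (MAD of first differences)."""
    d = np.diff(np.asarray(y, dtype=float))
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)


def estimate_noise_sd_linear(y: np.ndarray) -> float:
    """Robust noise sd for a piecewise-linear signal (MAD of second differences)."""
    d = np.diff(np.asarray(y, dtype=float), n=2)
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(6.0)
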