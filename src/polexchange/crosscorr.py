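"""Two-color cross-correlation analysis of replisome-focus traces.

Synchronized intensity fluctuations of the two labeled subunits are
quantified by the normalized cross-correlation function (CCF).  At each lag
the correlation is the Pearson coefficient of the two overlapping trace
windows, which is exactly bounded in [-1, 1], equals 1 at zero lag for
identical traces, and satisfies CCF_ab(lag) = CCF_ba(-lag).  Before
correlating, traces are background-subtracted and (by default) the shared
photobleaching trend is divided out with a per-trace single-exponential fit,
since common bleaching would otherwise induce a spurious positive peak.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import CcfCurve, ExchangeTimeFit, IntensityTrace, MechanismCall

__all__ = ["preprocess_focus_trace", "cross_correlation", "average_ccf",
           "randomized_control", "fit_ccf_decay", "classify_mechanism",
           "detrend_bleaching"]


def preprocess_focus_trace(trace: IntensityTrace, window_s: float | None = None,
                           subtract_background: bool = True) -> IntensityTrace:
    """Background-subtract and optionally moving-average a focus trace.

    ``window_s`` applies a centered moving average (display default in the
    field is 2 s; correlation analyses should leave it off).  A window of
    one frame is the identity.
    """
    dt = trace.frame_interval_s
    out = {}
    for name, y in trace.channels.items():
        y = np.asarray(y, dtype=float)
        if subtract_background:
            y = y - float(trace.metadata.get("bg_mean", 0.0))
        if window_s is not None:
            w = max(1, int(round(window_s / dt)))
            if w > len(y):
                raise ValueError("smoothing window longer than trace")
            if w > 1:
                kernel = np.ones(w) / w
                pad = np.pad(y, (w // 2, w - 1 - w // 2), mode="edge")
                y = np.convolve(pad, kernel, mode="valid")
        out[name] = y
    meta = dict(trace.metadata)
    meta["bg_mean"] = 0.0 if subtract_background else trace.metadata.get("bg_mean", 0.0)
    return IntensityTrace(times=trace.times.copy(), channels=out,
                          truth=trace.truth, metadata=meta)


def detrend_bleaching(y: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Divide out a fitted single-exponential photobleaching trend.

    Falls back to mean-normalization when the fit fails or is non-decaying.
    """
    y = np.asarray(y, dtype=float)
    mean = y.mean()
    if mean <= 0 or np.allclose(y, y[0]):
        return y - mean

    # profile the lifetime on a fixed log grid; amplitude and offset then
    # come from a linear least-squares solve (fast and derivative-free)
    span = times[-1] - times[0] if times[-1] > times[0] else 1.0
    best = None
    for tau in np.geomspace(span / 50.0, 5.0 * span, 12):
        basis = np.column_stack([np.exp(-times / tau), np.ones_like(times)])
        coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
        rss = float(res[0]) if len(res) else float(((basis @ coef - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, tau, coef)
    _, tau, (a, c) = best
    if a > 0:
        trend = a * np.exp(-times / tau) + c
        if np.all(trend > 0.05 * mean):
            return y / trend - 1.0
    return y / mean - 1.0


def _ccf_pair(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Per-lag Pearson correlation of the overlapping windows.

    Vectorized: sliding dot products come from ``np.correlate`` and window
    means/variances from prefix sums, equivalent to correlating the
    overlapping slices at each lag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    ca = np.concatenate([[0.0], np.cumsum(a)])
    cb = np.concatenate([[0.0], np.cumsum(b)])
    ca2 = np.concatenate([[0.0], np.cumsum(a * a)])
    cb2 = np.concatenate([[0.0], np.cumsum(b * b)])
    xcorr = np.correlate(b, a, mode="full")      # index n-1+lag = sum a_t b_{t+lag}
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        m = n - abs(lag)
        if lag >= 0:
            sx, sxx = ca[m], ca2[m]
            sy, syy = cb[n] - cb[lag], cb2[n] - cb2[lag]
        else:
            sx, sxx = ca[n] - ca[-lag], ca2[n] - ca2[-lag]
            sy, syy = cb[m], cb2[m]
        dot = xcorr[n - 1 + lag]
        cov = dot - sx * sy / m
        var_x = sxx - sx * sx / m
        var_y = syy - sy * sy / m
        denom = np.sqrt(max(var_x, 0.0) * max(var_y, 0.0))
        out[k] = float(cov / denom) if denom > 0 else np.nan
    return np.clip(out, -1.0, 1.0)


def cross_correlation(a: IntensityTrace, b: IntensityTrace, max_lag_s: float,
                      channel_a: str | None = None, channel_b: str | None = None
                      ) -> CcfCurve:
    """Normalized CCF of two traces over lags in [-max_lag, +max_lag].

    Raises on unequal frame grids, traces shorter than twice the maximum
    lag, or a zero-variance channel (undefined correlation).
    """
    if len(a.times) != len(b.times) or abs(a.frame_interval_s - b.frame_interval_s) > 1e-12:
        raise ValueError("traces must share one frame grid")
    dt = a.frame_interval_s
    max_lag = int(round(max_lag_s / dt))
    ya = np.asarray(a.channels[channel_a] if channel_a else a.total, dtype=float)
    yb = np.asarray(b.channels[channel_b] if channel_b else b.total, dtype=float)
    if len(ya) < 2 * max_lag:
        raise ValueError("trace shorter than twice the maximum lag")
    if np.ptp(ya) == 0 or np.ptp(yb) == 0:
        raise ValueError("zero-variance channel: correlation undefined")
    values = _ccf_pair(ya, yb, max_lag)
    lags = np.arange(-max_lag, max_lag + 1) * dt
    return CcfCurve(lags=lags, values=values, n_pairs=1,
                    metadata={"frame_interval_s": dt})


def _pair_arrays(trace: IntensityTrace, detrend: bool,
                 channels: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    key = ("_prepared", detrend, channels)
    cached = trace.metadata.get(key)
    if cached is not None:
        return cached
    ya = np.asarray(trace.channels[channels[0]], dtype=float)
    yb = np.asarray(trace.channels[channels[1]], dtype=float)
    bg = float(trace.metadata.get("bg_mean", 0.0))
    ya, yb = ya - bg, yb - bg
    if detrend:
        ya = detrend_bleaching(ya, trace.times)
        yb = detrend_bleaching(yb, trace.times)
    trace.metadata[key] = (ya, yb)      # cache: detrending dominates runtime
    return ya, yb


def average_ccf(pairs: list[IntensityTrace], max_lag_s: float,
                detrend: bool = True,
                channels: tuple[str, str] = ("ch1", "ch2")) -> CcfCurve:
    """Pointwise average CCF over two-channel focus traces.

    Pairs of unequal length are truncated to the common length (warned).
    Zero-variance pairs are skipped.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one pair")
    n_min = min(t.n_frames for t in pairs)
    if any(t.n_frames != n_min for t in pairs):
        warnings.warn("pairs of unequal length truncated to common length")
    dt = pairs[0].frame_interval_s
    max_lag = int(round(max_lag_s / dt))
    curves = []
    for tr in pairs:
        ya, yb = _pair_arrays(tr, detrend, channels)
        ya, yb = ya[:n_min], yb[:n_min]
        if np.ptp(ya) == 0 or np.ptp(yb) == 0:
            continue
        curves.append(_ccf_pair(ya, yb, max_lag))
    if not curves:
        raise ValueError("no pairs with non-zero variance")
    values = np.nanmean(np.vstack(curves), axis=0)
    return CcfCurve(lags=np.arange(-max_lag, max_lag + 1) * dt, values=values,
                    n_pairs=len(curves), metadata={"frame_interval_s": dt})


def randomized_control(traces_a: list[IntensityTrace],
                       traces_b: list[IntensityTrace],
                       cell_ids, max_lag_s: float, seed=None,
                       n_pairs: int | None = None, detrend: bool = True,
                       channels: tuple[str, str] = ("ch1", "ch2")) -> CcfCurve:
    """Average CCF of random cross-cell channel pairings (the null control).

    Pairs (i, j) are drawn uniformly among combinations with
    ``cell_ids[i] != cell_ids[j]``, pairing channel 1 of trace i with
    channel 2 of trace j, exactly as the same-cell analysis pairs channels.
    """
    cell_ids = np.asarray(list(cell_ids))
    if len(np.unique(cell_ids)) < 2:
        raise ValueError("randomized control requires traces from >= 2 cells")
    rng = np.random.default_rng(seed)
    n = len(traces_a)
    if n_pairs is None:
        n_pairs = n
    n_min = min(min(t.n_frames for t in traces_a), min(t.n_frames for t in traces_b))
    dt = traces_a[0].frame_interval_s
    max_lag = int(round(max_lag_s / dt))
    curves = []
    guard = 0
    while len(curves) < n_pairs and guard < 50 * n_pairs:
        guard += 1
        i = int(rng.integers(n))
        j = int(rng.integers(len(traces_b)))
        if cell_ids[i] == cell_ids[j]:
            continue
        ya, _ = _pair_arrays(traces_a[i], detrend, channels)
        _, yb = _pair_arrays(traces_b[j], detrend, channels)
        ya, yb = ya[:n_min], yb[:n_min]
        if np.ptp(ya) == 0 or np.ptp(yb) == 0:
            continue
        curves.append(_ccf_pair(ya, yb, max_lag))
    if not curves:
        raise ValueError("no usable randomized pairs")
    return CcfCurve(lags=np.arange(-max_lag, max_lag + 1) * dt,
                    values=np.nanmean(np.vstack(curves), axis=0),
                    n_pairs=len(curves), metadata={"frame_interval_s": dt})


def randomized_null(traces_a: list[IntensityTrace],
                    traces_b: list[IntensityTrace],
                    cell_ids, max_lag_s: float, n_draws: int = 100,
                    seed=None, n_pairs: int | None = None,
                    detrend: bool = True,
                    channels: tuple[str, str] = ("ch1", "ch2")) -> list[CcfCurve]:
    """``n_draws`` independent randomized-control average CCFs (the null set)."""
    rng = np.random.default_rng(seed)
    return [randomized_control(traces_a, traces_b, cell_ids, max_lag_s,
                               seed=rng, n_pairs=n_pairs, detrend=detrend,
                               channels=channels)
            for _ in range(n_draws)]


def fit_ccf_decay(curve: CcfCurve) -> ExchangeTimeFit:
    """Exponential decay fit ``A * exp(-lag/tau)`` to the non-negative-lag branch."""
    mask = curve.lags >= 0
    ell = curve.lags[mask]
    v = curve.values[mask]
    if len(ell) < 6:
        raise ValueError("positive-lag branch needs at least 6 points")
    if v[0] <= 0:
        return ExchangeTimeFit(tau_s=np.inf, tau_err_s=np.inf, amplitude=float(v[0]),
                               offset=0.0, flagged=True, note="no decay to fit")

    def model(x, amp, tau):
        return amp * np.exp(-x / tau)

    span = ell[-1] - ell[0] if ell[-1] > ell[0] else 1.0
    try:
        popt, pcov = curve_fit(model, ell, v, p0=[v[0], span / 3.0],
                               bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                               maxfev=20_000)
    except (RuntimeError, ValueError):
        return ExchangeTimeFit(tau_s=np.inf, tau_err_s=np.inf, amplitude=float(v[0]),
                               offset=0.0, flagged=True, note="no decay to fit")
    perr = np.sqrt(np.diag(pcov))
    return ExchangeTimeFit(tau_s=float(popt[1]), tau_err_s=float(perr[1]),
                           amplitude=float(popt[0]), offset=0.0)


def classify_mechanism(observed: CcfCurve, null_curves: list[CcfCurve],
                       peak_lags: int = 3, quantile: float = 0.99) -> MechanismCall:
    """Call 'positive_peak' or 'flat' against a randomized null band.

    The observed maximum over lags within ``peak_lags`` frames of zero is
    compared with the ``quantile`` of the null curves' values at those lags.
    """
    if len(null_curves) < 100:
        raise ValueError("null distribution requires >= 100 randomized draws")
    dt = float(observed.metadata.get("frame_interval_s", 1.0))
    window = (np.abs(observed.lags) <= peak_lags * dt + 1e-9)
    null_vals = []
    for nc in null_curves:
        if len(nc.lags) != len(observed.lags) or not np.allclose(nc.lags, observed.lags):
            raise ValueError("null curve lag grid does not match observed")
        null_vals.append(nc.values[window])
    threshold = float(np.quantile(np.concatenate(null_vals), quantile))
    peak = float(np.nanmax(observed.values[window]))
    label = "positive_peak" if peak > threshold else "flat"
    return MechanismCall(label=label, peak_value=peak, null_threshold=threshold)
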