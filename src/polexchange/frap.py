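"""smFRAP analysis: recovery-curve extraction and exchange-time fitting.

Post-pulse intensity windows are normalized to the pre-pulse steady state
(mean of the 10 frames before the pulse, excluding pulse frames), averaged
within each trace over its pulses and then across traces, and fit with a
saturating single exponential ``I(t) = offset + amplitude * (1 - exp(-t/tau))``
whose characteristic time is the exchange time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .datatypes import ExchangeTimeFit, IntensityTrace, RecoveryCurve

__all__ = ["locate_pulses", "extract_and_average_recovery", "ExchangeTimeFitter",
           "fit_exchange_time", "exchange_vs_concentration", "PulseDetectionError"]


class PulseDetectionError(RuntimeError):
    pass


def locate_pulses(trace: IntensityTrace, use_metadata: bool = True,
                  threshold_frac: float = 0.2, median_window: int = 10) -> np.ndarray:
    """Frame indices at which FRAP pulses start.

    Uses the trace's schedule metadata when present; otherwise detects
    frames whose intensity falls below ``threshold_frac`` of the running
    median of the preceding ``median_window`` frames, grouping consecutive
    detections into one pulse.
    """
    if use_metadata and trace.metadata.get("pulse_frames"):
        return np.asarray(trace.metadata["pulse_frames"], dtype=int)
    y = trace.total - float(trace.metadata.get("bg_mean", 0.0))
    n = len(y)
    hits = np.zeros(n, dtype=bool)
    for i in range(1, n):
        lo = max(0, i - median_window)
        ref = np.median(y[lo:i])
        if ref > 0 and y[i] < threshold_frac * ref:
            hits[i] = True
    starts = np.flatnonzero(hits & ~np.roll(hits, 1))
    starts = starts[starts > 0]
    if len(starts) == 0:
        raise PulseDetectionError("no pulses found")
    return starts


def extract_and_average_recovery(traces: list[IntensityTrace],
                                 pulses: list | None = None,
                                 pre_frames: int = 10,
                                 conc_nm: float | None = None) -> RecoveryCurve:
    """Averaged normalized recovery curve across traces and pulses.

    Each post-pulse window (after the pulse frames, up to the next pulse)
    is background-subtracted and normalized to the trace's pre-pulse steady
    state — the mean of the ``pre_frames`` frames before each pulse, pooled
    over that trace's pulses (pooling reduces the noise of the normalizer);
    windows are averaged within a trace, then across traces.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    per_trace: list[np.ndarray] = []
    dt = traces[0].frame_interval_s
    for k, tr in enumerate(traces):
        starts = np.asarray(pulses[k] if pulses is not None else locate_pulses(tr),
                            dtype=int)
        if len(starts) == 0:
            continue
        y = tr.total - float(tr.metadata.get("bg_mean", 0.0))
        mask = tr.metadata.get("pulse_mask")
        if mask is None:
            mask = np.zeros(len(y), dtype=bool)
            mask[starts] = True
        windows = []
        pre_segments = []
        bounds = list(starts) + [len(y)]
        for s, nxt in zip(starts, bounds[1:]):
            # end of this pulse = first non-pulse frame at or after s
            e = s
            while e < len(y) and mask[e]:
                e += 1
            pre = y[max(0, s - pre_frames):s]
            pre = pre[~mask[max(0, s - pre_frames):s]]
            if len(pre) < 5:
                warnings.warn("pre-pulse window shorter than 5 frames; skipped")
                continue
            pre_segments.append(pre)
            if e < nxt:
                windows.append(y[e:nxt])
        if not windows or not pre_segments:
            continue
        steady = float(np.concatenate(pre_segments).mean())
        if steady <= 0:
            continue
        m = min(len(w) for w in windows)
        per_trace.append(np.mean([w[:m] for w in windows], axis=0) / steady)
    if not per_trace:
        raise ValueError("no usable post-pulse windows")
    m = min(len(w) for w in per_trace)
    avg = np.mean([w[:m] for w in per_trace], axis=0)
    return RecoveryCurve(time_s=np.arange(m) * dt, intensity=avg,
                         n_traces=len(per_trace), conc_nm=conc_nm)


class ExchangeTimeFitter(BaseEstimator):
    """Saturating-exponential fit of a FRAP recovery curve.

    Model: ``I(t) = offset + amplitude * (1 - exp(-t / tau))``.  The fit is
    flagged 'no recovery' when it does not converge, the amplitude is not
    positive, or tau exceeds ``max_tau_factor`` times the window length.

    Attributes (after fit)
    ----------------------
    tau_s_, tau_err_s_, amplitude_, offset_, flagged_, note_
    """

    def __init__(self, max_tau_factor: float = 10.0):
        self.max_tau_factor = max_tau_factor

    def fit(self, time_s, intensity):
        t = np.asarray(time_s, dtype=float)
        y = np.asarray(intensity, dtype=float)
        if len(t) < 8:
            raise ValueError("need at least 8 post-pulse points")
        span = t[-1] - t[0]

        def model(tt, off, amp, tau):
            return off + amp * (1.0 - np.exp(-tt / tau))

        self.flagged_ = False
        self.note_ = ""
        try:
            p0 = [max(y[0], 0.0), max(y[-1] - y[0], 0.1), max(span / 3.0, 1e-6)]
            popt, pcov = curve_fit(model, t, y, p0=p0,
                                   bounds=([-np.inf, -np.inf, 1e-12],
                                           [np.inf, np.inf, np.inf]),
                                   maxfev=20_000)
            off, amp, tau = popt
            tau_err = float(np.sqrt(np.diag(pcov))[2])
        except (RuntimeError, ValueError):
            off, amp, tau, tau_err = float(y.mean()), 0.0, np.inf, np.inf
            self.flagged_ = True
            self.note_ = "no recovery: fit did not converge"
        if not self.flagged_ and (amp <= 0 or tau > self.max_tau_factor * span):
            self.flagged_ = True
            self.note_ = "no recovery: flat or unresolved recovery"
        self.tau_s_ = float(tau)
        self.tau_err_s_ = float(tau_err)
        self.amplitude_ = float(amp)
        self.offset_ = float(off)
        return self

    def to_result(self) -> ExchangeTimeFit:
        return ExchangeTimeFit(tau_s=self.tau_s_, tau_err_s=self.tau_err_s_,
                               amplitude=self.amplitude_, offset=self.offset_,
                               flagged=self.flagged_, note=self.note_)


def fit_exchange_time(curve: RecoveryCurve) -> ExchangeTimeFit:
    """Fit the characteristic exchange time of a recovery curve."""
    return ExchangeTimeFitter().fit(curve.time_s, curve.intensity).to_result()


def exchange_vs_concentration(results, fit_model: bool = False):
    """Tabulate exchange time versus concentration; optionally fit the
    multisite model ``tau(C) = 1/(k_on * C) + 1/k_handoff``.

    Parameters
    ----------
    results : list of (conc_nm, ExchangeTimeFit)

    Returns
    -------
    table : pandas.DataFrame sorted by concentration, with a monotonicity
        report in ``table.attrs['monotonic_decreasing']``.
    model : dict or None
        ``{'k_on': ..., 'k_handoff': ...}`` when ``fit_model`` and at least
        two concentrations are available.
    """
    rows = []
    for conc, fitres in results:
        rows.append({"conc_nm": float(conc), "tau_s": fitres.tau_s,
                     "tau_err_s": fitres.tau_err_s, "flagged": fitres.flagged})
    df = pd.DataFrame(rows)
    dup = df.duplicated("conc_nm", keep=False)
    if dup.any():
        warnings.warn("duplicate concentrations merged (mean tau)")
        df = df.groupby("conc_nm", as_index=False).agg(
            tau_s=("tau_s", "mean"), tau_err_s=("tau_err_s", "mean"),
            flagged=("flagged", "any"))
    df = df.sort_values("conc_nm").reset_index(drop=True)
    ok = df.loc[~df["flagged"], "tau_s"].to_numpy()
    df.attrs["monotonic_decreasing"] = bool(np.all(np.diff(ok) < 0)) if len(ok) > 1 else None

    model = None
    if fit_model and len(df) >= 2:
        c = df["conc_nm"].to_numpy()
        tau = df["tau_s"].to_numpy()

        def f(cc, k_on, k_handoff):
            return 1.0 / (k_on * cc) + 1.0 / k_handoff

        popt, pcov = curve_fit(f, c, tau, p0=[1.0, 1.0],
                               bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                               maxfev=20_000)
        perr = np.sqrt(np.diag(pcov))
        model = {"k_on": float(popt[0]), "k_handoff": float(popt[1]),
                 "k_on_err": float(perr[0]), "k_handoff_err": float(perr[1])}
    return df, model
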