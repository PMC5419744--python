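"""Copy-number counting from whole-cell fluorescence and bleaching steps.

Single-molecule intensities come from change-point step fitting of focus
photobleaching traces; whole-cell fluorescence, corrected for constant
cellular autofluorescence and the exponentially bleaching coverslip
background, is fit with a single exponential whose t = 0 amplitude divided
by the single-molecule intensity gives the copy number.  Copies convert to
cellular concentration through the cell volume.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import kurtosis, skew
from sklearn.base import BaseEstimator

from .changepoint import ConstantCost, estimate_noise_sd_const, optimal_partition
from .datatypes import Calibration, CellRecord, IntensityTrace, StepFit
from .params import CellGeometry

__all__ = ["ExponentialDecayFitter", "fit_field_background", "correct_and_fit_cell",
           "ChangePointStepFitter", "detect_steps", "single_molecule_intensity",
           "copy_number", "concentration", "complex_concentration",
           "fit_bleach_lifetime"]


class ExponentialDecayFitter(BaseEstimator):
    """Least-squares fit of ``A * exp(-t/tau) + c``.

    Attributes (after fit): amplitude_, lifetime_s_, offset_, errors_,
    flagged_ (non-decaying or failed fit), note_.
    """

    def __init__(self, fit_offset: bool = True):
        self.fit_offset = fit_offset

    def fit(self, times, y):
        t = np.asarray(times, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(t) < 10:
            raise ValueError("need at least 10 frames")
        self.flagged_ = False
        self.note_ = ""
        span = t[-1] - t[0] if t[-1] > t[0] else 1.0
        head = y[: max(3, len(y) // 10)].mean()
        tail = y[-max(3, len(y) // 10):].mean()

        if self.fit_offset:
            def model(tt, a, tau, c):
                return a * np.exp(-tt / tau) + c
            p0 = [max(head - tail, 1e-6), span / 3.0, tail]
            bounds = ([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
        else:
            def model(tt, a, tau):
                return a * np.exp(-tt / tau)
            p0 = [max(head, 1e-6), span / 3.0]
            bounds = ([-np.inf, 1e-12], [np.inf, np.inf])

        try:
            popt, pcov = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20_000)
            errs = np.sqrt(np.diag(pcov))
        except (RuntimeError, ValueError):
            popt = p0 if len(p0) == 3 else list(p0)
            errs = [np.inf] * len(p0)
            self.flagged_ = True
            self.note_ = "fit did not converge"
        self.amplitude_ = float(popt[0])
        self.lifetime_s_ = float(popt[1])
        self.offset_ = float(popt[2]) if self.fit_offset else 0.0
        self.errors_ = np.asarray(errs, dtype=float)
        if not self.flagged_ and (self.amplitude_ <= 0
                                  or self.lifetime_s_ > 100.0 * span
                                  or head <= tail):
            self.flagged_ = True
            self.note_ = "non-decaying input"
        return self

    def predict(self, times):
        t = np.asarray(times, dtype=float)
        return self.amplitude_ * np.exp(-t / self.lifetime_s_) + self.offset_


def fit_field_background(times, field_trace) -> ExponentialDecayFitter:
    """Single-exponential fit of the per-field coverslip photobleaching."""
    return ExponentialDecayFitter(fit_offset=True).fit(times, field_trace)


def correct_and_fit_cell(times, cell_trace, autofluorescence: float,
                         field_fit: ExponentialDecayFitter) -> CellRecord:
    """Correct one cell trace and fit its bleaching amplitude.

    corrected = cell - autofluorescence - fitted coverslip background; the
    corrected trace is fit with a single exponential and the amplitude is
    the fitted intensity at t = 0.
    """
    t = np.asarray(times, dtype=float)
    corrected = np.asarray(cell_trace, dtype=float) - autofluorescence - field_fit.predict(t)
    fitter = ExponentialDecayFitter(fit_offset=True).fit(t, corrected)
    amp = fitter.amplitude_ + fitter.offset_      # fitted value at t = 0
    rec = CellRecord(cell_id=-1, amplitude=float(amp),
                     mean_intensity=float(corrected.mean()))
    if amp < 0:
        rec.flagged = True
        rec.note = "negative corrected amplitude"
    elif fitter.flagged_:
        rec.flagged = True
        rec.note = fitter.note_
    return rec


class ChangePointStepFitter(BaseEstimator):
    """Exact penalized piecewise-constant step fitting of a bleaching trace.

    Total cost = RSS + ``penalty`` x (number of change points); on ties the
    earliest change points win.  ``penalty=None`` uses ``3 sigma^2 ln(n)``
    with a robust noise estimate; steps smaller than ``min_step`` (default
    2x the noise sd) are merged away.

    Attributes (after fit): change_points_, levels_, step_sizes_,
    residual_var_, cost_.
    """

    def __init__(self, penalty: float | None = None,
                 min_step: float | None = None, min_size: int = 2):
        self.penalty = penalty
        self.min_step = min_step
        self.min_size = min_size

    def fit(self, y):
        y = np.asarray(y, dtype=float)
        if len(y) < 6:
            raise ValueError("need at least 6 frames")
        sigma = estimate_noise_sd_const(y)
        penalty = self.penalty if self.penalty is not None \
            else 3.0 * max(sigma, 1e-12) ** 2 * np.log(len(y))
        min_step = self.min_step if self.min_step is not None else 2.0 * sigma
        cost = ConstantCost(y)
        bps, total = optimal_partition(cost, len(y), penalty, min_size=self.min_size)

        bounds = [0] + list(bps) + [len(y)]
        levels = [cost.level(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
        # merge segments whose level change is below the threshold
        changed = True
        while changed and len(levels) > 1:
            changed = False
            diffs = np.abs(np.diff(levels))
            k = int(np.argmin(diffs))
            if diffs[k] < min_step:
                a, b = bounds[k], bounds[k + 2]
                levels[k] = cost.level(a, b)
                del levels[k + 1]
                del bounds[k + 1]
                changed = True
        self.change_points_ = np.asarray(bounds[1:-1], dtype=int)
        self.levels_ = np.asarray(levels, dtype=float)
        fitted = np.repeat(self.levels_,
                           np.diff(np.asarray(bounds)))
        self.residual_var_ = float(np.mean((y - fitted) ** 2))
        self.cost_ = float(total)
        self.penalty_ = float(penalty)
        return self

    def to_stepfit(self) -> StepFit:
        return StepFit(change_points=self.change_points_.copy(),
                       levels=self.levels_.copy(),
                       residual_var=self.residual_var_)


def detect_steps(trace, penalty: float | None = None,
                 min_step: float | None = None, min_size: int = 2) -> StepFit:
    """Change-point step fit of a focus bleaching trace (thin wrapper).

    ``trace`` may be an IntensityTrace (its total channel is used) or an
    array of intensities.
    """
    y = trace.total if isinstance(trace, IntensityTrace) else np.asarray(trace, float)
    fitter = ChangePointStepFitter(penalty=penalty, min_step=min_step,
                                   min_size=min_size).fit(y)
    return fitter.to_stepfit()


def single_molecule_intensity(step_sizes, channel: str = "") -> Calibration:
    """Gaussian mean +- sem of the bleaching step-size histogram.

    Flags multimodality (suggesting double steps) by the bimodality
    coefficient heuristic.
    """
    x = np.asarray(list(step_sizes), dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 steps")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    sem = sd / np.sqrt(len(x))
    flagged = False
    note = ""
    if sd > 0:
        g2 = kurtosis(x, fisher=False)
        if g2 > 0 and (skew(x) ** 2 + 1) / g2 > 0.555:
            flagged = True
            note = "possibly multimodal step sizes (double steps?)"
    return Calibration(unit_mean=mean, unit_sd=sem, n=len(x), channel=channel,
                       flagged=flagged, note=note)


def copy_number(cell: CellRecord | float, cal: Calibration,
                area_px: float | None = None) -> float:
    """Copies per cell = corrected total intensity / single-molecule intensity.

    Accepts a CellRecord (amplitude-based when the bleach-fit amplitude is
    available, else mean intensity x area) or a raw total intensity.
    """
    if cal.unit_mean <= 0:
        raise ValueError("calibration unit_mean must be > 0")
    if isinstance(cell, CellRecord):
        if np.isfinite(cell.amplitude):
            total = cell.amplitude
        else:
            total = cell.mean_intensity * (cell.area_px if area_px is None else area_px)
    else:
        total = float(cell) * (area_px if area_px is not None else 1.0)
    return float(total / cal.unit_mean)


def concentration(copies: float, geom: CellGeometry | None = None) -> float:
    """Cellular concentration in nM: copies / (N_A x volume)."""
    if geom is None:
        raise ValueError("cell volume not set: provide CellGeometry "
                         "(config key cells.volume_fl)")
    if copies < 0:
        raise ValueError("copies must be >= 0")
    moles = copies / geom.avogadro
    molar = moles / (geom.volume_fl * 1e-15)
    return molar * 1e9


def complex_concentration(conc_eps_nm: float, conc_tau_nm: float,
                          subunits_per_complex: int = 3,
                          estimator: str = "mean") -> tuple[int, float]:
    """Pol III* concentration implied by the two subunit concentrations.

    With every epsilon and tau in a complex carrying ``subunits_per_complex``
    of each, each subunit concentration divided by that count estimates the
    complex concentration.  ``estimator='mean'`` averages the two estimates
    (the default); ``'limiting'`` takes the minimum.  Returns
    ``(rounded nM for reports, unrounded value)``.
    """
    if conc_eps_nm < 0 or conc_tau_nm < 0:
        raise ValueError("concentrations must be >= 0")
    est = (conc_eps_nm / subunits_per_complex, conc_tau_nm / subunits_per_complex)
    value = float(np.mean(est)) if estimator == "mean" else float(min(est))
    return int(round(value)), value


def fit_bleach_lifetime(trace) -> ExponentialDecayFitter:
    """Single-exponential photobleach-lifetime fit of a decaying trace.

    ``trace`` may be an IntensityTrace or a (times, intensities) pair.
    Flat or increasing traces are flagged.
    """
    if isinstance(trace, IntensityTrace):
        t, y = trace.times, trace.total - float(trace.metadata.get("bg_mean", 0.0))
    else:
        t, y = trace
    return ExponentialDecayFitter(fit_offset=True).fit(t, y)
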