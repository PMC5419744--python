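"""Step fitting, background correction, copy numbers and concentrations."""

import itertools

import numpy as np
import pytest

from polexchange.counting import (ChangePointStepFitter, complex_concentration,
                                  concentration, copy_number,
                                  correct_and_fit_cell, detect_steps,
                                  fit_bleach_lifetime, fit_field_background,
                                  single_molecule_intensity)
from polexchange.datatypes import Calibration, CellRecord
from polexchange.params import CellGeometry
from polexchange.simulate import simulate_cell_field


def test_field_background_exact_parameters():
    t = np.arange(0, 60, 0.5)
    y = 4000.0 * np.exp(-t / 30.0) + 250.0
    fit = fit_field_background(t, y)
    assert not fit.flagged_
    assert fit.amplitude_ == pytest.approx(4000.0, abs=1e-4)
    assert fit.lifetime_s_ == pytest.approx(30.0, abs=1e-5)
    assert fit.offset_ == pytest.approx(250.0, abs=1e-4)


def test_field_background_noisy_recovery():
    rng = np.random.default_rng(1)
    t = np.arange(0, 60, 0.1)
    y = 5000.0 * np.exp(-t / 30.0) + rng.normal(0, 40, len(t))
    fit = fit_field_background(t, y)
    assert abs(fit.lifetime_s_ - 30.0) / 30.0 < 0.10


def test_constant_field_flagged_non_decaying():
    t = np.arange(0, 30, 0.5)
    assert fit_field_background(t, np.full_like(t, 900.0)).flagged_
    assert fit_field_background(t, 10.0 * t).flagged_  # increasing


def test_step_fit_noiseless_staircase_exact():
    y = np.array([300.0] * 8 + [150.0] * 8 + [0.0] * 8)
    fit = detect_steps(y, penalty=10.0, min_step=10.0)
    assert list(fit.change_points) == [8, 16]
    assert np.allclose(fit.step_sizes, [150.0, 150.0])


def _brute_force_const(y, penalty, min_size, max_cp):
    n = len(y)
    best = (np.inf, ())
    for k in range(max_cp + 1):
        for bps in itertools.combinations(range(min_size, n - min_size + 1), k):
            bounds = (0,) + bps + (n,)
            if any(b - a < min_size for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            c = sum(float(np.var(y[a:b]) * (b - a))
                    for a, b in zip(bounds[:-1], bounds[1:])) + penalty * k
            if c < best[0] - 1e-9:
                best = (c, bps)
    return best


def test_step_fitter_matches_brute_force_on_random_traces():
    """The DP optimum equals exhaustive enumeration of breakpoint placements
    minimizing the same penalized cost (earliest change point on ties)."""
    rng = np.random.default_rng(0)
    for trial in range(60):
        n = int(rng.integers(12, 31))
        k = int(rng.integers(0, 4))
        cps = np.sort(rng.choice(np.arange(2, n - 1), size=k, replace=False)) \
            if k else []
        levels = 150.0 * np.arange(k + 1)[::-1] + rng.uniform(0, 50, k + 1)
        y = np.zeros(n)
        bounds = [0] + list(cps) + [n]
        for (a, b), lev in zip(zip(bounds[:-1], bounds[1:]), levels):
            y[a:b] = lev
        y += rng.normal(0, 20.0, n)
        penalty = float(rng.uniform(4000, 12000))
        fitter = ChangePointStepFitter(penalty=penalty, min_step=0.0,
                                       min_size=2).fit(y)
        cost_bf, bps_bf = _brute_force_const(y, penalty, min_size=2, max_cp=4)
        assert len(fitter.change_points_) <= 4, "penalty too low for oracle cap"
        assert tuple(fitter.change_points_) == bps_bf, trial
        assert fitter.cost_ == pytest.approx(cost_bf, rel=1e-8)


def test_step_size_histogram_recovers_single_molecule_intensity():
    """Simulated bleaching foci with unit step 158 counts: the Gaussian mean
    of fitted step sizes lands within 5% of the generative value."""
    field = simulate_cell_field(n_cells=1, n_focus_traces=150,
                                unit_intensity=158.0, seed=3)
    steps = []
    for tr in field.focus_traces:
        fit = detect_steps(tr)
        steps.extend(s for s in fit.step_sizes if s > 0)
    cal = single_molecule_intensity(steps)
    assert abs(cal.unit_mean - 158.0) / 158.0 < 0.05


def test_single_molecule_intensity_trivial_and_gaussian():
    cal = single_molecule_intensity([130.0] * 60)
    assert cal.unit_mean == 130.0
    assert cal.unit_sd == 0.0
    rng = np.random.default_rng(4)
    cal2 = single_molecule_intensity(rng.normal(130.0, 25.0, 500))
    assert abs(cal2.unit_mean - 130.0) < 2 * cal2.unit_sd + 1e-9
    with pytest.raises(ValueError):
        single_molecule_intensity([100.0] * 10)


def test_cell_correction_recovers_truth_amplitude():
    rng = np.random.default_rng(5)
    t = np.arange(0, 40, 0.1)
    truth_amp = 16_432.0
    auto = 2000.0
    field_y = 5000.0 * np.exp(-t / 30.0)
    cell = truth_amp * np.exp(-t / 10.0) + auto + field_y + rng.normal(0, 50, len(t))
    ffit = fit_field_background(t, field_y + rng.normal(0, 10, len(t)))
    rec = correct_and_fit_cell(t, cell, auto, ffit)
    assert not rec.flagged
    assert abs(rec.amplitude - truth_amp) / truth_amp < 0.05


def test_zero_copy_cell_amplitude_near_zero():
    rng = np.random.default_rng(6)
    t = np.arange(0, 40, 0.1)
    field_y = 5000.0 * np.exp(-t / 30.0)
    cell = 2000.0 + field_y + rng.normal(0, 50, len(t))
    ffit = fit_field_background(t, field_y)
    rec = correct_and_fit_cell(t, cell, 2000.0, ffit)
    assert abs(rec.amplitude) < 200.0  # noise floor


def test_simulated_autofluorescence_is_constant():
    field = simulate_cell_field(n_cells=1, seed=7)
    auto = field.autofluorescence
    assert np.ptp(auto) / auto.mean() < 0.05


def test_copy_number_identities():
    cal = Calibration(unit_mean=158.0, unit_sd=2.0, n=500)
    rec = CellRecord(cell_id=0, amplitude=10 * 158.0)
    assert copy_number(rec, cal) == pytest.approx(10.0)
    rec2 = CellRecord(cell_id=1, amplitude=20 * 158.0)
    assert copy_number(rec2, cal) == pytest.approx(2 * copy_number(rec, cal))
    with pytest.raises(ValueError):
        copy_number(rec, Calibration(unit_mean=0.0, unit_sd=1.0, n=10))


def test_concentration_worked_examples():
    """104 copies in 2.4 fL -> 71.9 nM; 96 copies -> 66.4 nM, matching the
    measured copy/concentration pairs."""
    geom = CellGeometry(volume_fl=2.4)
    assert concentration(104, geom) == pytest.approx(71.96, abs=0.05)
    assert concentration(96, geom) == pytest.approx(66.42, abs=0.05)
    assert concentration(0, geom) == 0.0
    with pytest.raises(ValueError):
        concentration(10, None)


def test_complex_concentration_estimators():
    rounded, value = complex_concentration(72.0, 67.0)
    assert rounded == 23
    assert value == pytest.approx((24.0 + 67.0 / 3) / 2)
    assert complex_concentration(30.0, 30.0)[0] == 10
    limiting, _ = complex_concentration(72.0, 67.0, estimator="limiting")
    assert limiting == 22


def test_bleach_lifetime_exact_and_flagged():
    t = np.arange(0, 60, 0.5)
    fit = fit_bleach_lifetime((t, 1000.0 * np.exp(-t / 14.1)))
    assert fit.lifetime_s_ == pytest.approx(14.1, abs=1e-6)
    rising = fit_bleach_lifetime((t, 10.0 * t))
    assert rising.flagged_


def test_end_to_end_counting_recovers_copies_and_concentration():
    """Full pipeline on the simulated field: mean copies within 5% of the
    generative 104, concentration within 5% of copies/(N_A V)."""
    field = simulate_cell_field(n_cells=60, copies_per_cell=104,
                                n_focus_traces=120, seed=11)
    ffit = fit_field_background(field.times, field.field_background)
    auto = float(field.autofluorescence.mean())
    steps = []
    for tr in field.focus_traces:
        fit = detect_steps(tr)
        steps.extend(s for s in fit.step_sizes if s > 0)
    cal = single_molecule_intensity(steps)
    copies = []
    for trace in field.cell_traces:
        rec = correct_and_fit_cell(field.times, trace, auto, ffit)
        copies.append(copy_number(rec, cal))
    mean_copies = np.mean(copies)
    assert abs(mean_copies - 104.0) / 104.0 < 0.05
    geom = CellGeometry(volume_fl=2.4)
    conc = concentration(mean_copies, geom)
    assert abs(conc - concentration(104.0, geom)) / concentration(104.0, geom) < 0.05


def test_copy_number_invariant_under_gain_rescaling():
    """Scaling all intensities by a gain factor and refitting the
    calibration from the same data leaves copy numbers unchanged."""
    rng = np.random.default_rng(8)
    steps = rng.normal(158.0, 20.0, 200)
    amp = 104 * 158.0
    base = copy_number(CellRecord(cell_id=0, amplitude=amp),
                       single_molecule_intensity(steps))
    for gain in (0.5, 3.0):
        scaled = copy_number(CellRecord(cell_id=0, amplitude=amp * gain),
                             single_molecule_intensity(steps * gain))
        assert scaled == pytest.approx(base, rel=1e-9)
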