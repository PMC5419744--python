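"""smFRAP: pulse location, recovery averaging, exchange-time fitting."""

import numpy as np
import pytest

from polexchange import ExchangeParams, PhotoParams
from polexchange.datatypes import IntensityTrace, RecoveryCurve
from polexchange.frap import (ExchangeTimeFitter, PulseDetectionError,
                              exchange_vs_concentration,
                              extract_and_average_recovery, fit_exchange_time,
                              locate_pulses)
from polexchange.simulate import simulate_frap_experiment

FRAP_PHOTO = dict(bg_mean=50.0, bg_sd=10.0, pulse_duration_s=1.0,
                  frame_interval_s=0.5, bleach_lifetime_s=2000.0,
                  power_pulse=20000.0)


def _frap_traces(tau_res, n=100, seed=0, n_periods=14):
    """Exchange-limited configuration: mean residence 1/(k_on C) + 1/k_handoff."""
    kh = 20.0
    kon_c = 1.0 / (tau_res - 1.0 / kh)
    x = ExchangeParams(n_sites=2, k_on=kon_c, conc=1.0, k_off=0.0, k_handoff=kh)
    photo = PhotoParams(pulse_period_s=max(5 * tau_res, 20.0), **FRAP_PHOTO)
    return simulate_frap_experiment(x, photo, n_replisomes=n,
                                    duration_s=n_periods * photo.pulse_period_s,
                                    seed=seed)


def test_locate_pulses_metadata_and_detection():
    traces = _frap_traces(2.0, n=3, seed=1)
    tr = traces[0]
    meta_pulses = locate_pulses(tr)
    assert list(meta_pulses) == tr.metadata["pulse_frames"]
    detected = locate_pulses(tr, use_metadata=False)
    # every scheduled pulse found within the 2-frame pulse window (a fresh
    # arrival during the pulse can delay the intensity drop by one frame)
    for s in meta_pulses:
        assert np.min(np.abs(detected - s)) <= 2


def test_locate_pulses_constant_trace_raises():
    tr = IntensityTrace(times=np.arange(100.0),
                        channels={"total": np.full(100, 500.0)},
                        metadata={"bg_mean": 0.0})
    with pytest.raises(PulseDetectionError):
        locate_pulses(tr, use_metadata=False)


def test_average_recovery_arithmetic_identity():
    """Hand-built windows (0.2, 0.6, 0.9) and (0.4, 0.6, 0.7) average to
    (0.3, 0.6, 0.8) once each trace's steady state is 1."""
    def make(vals):
        y = np.concatenate([np.ones(10), [0.0], vals])
        return IntensityTrace(times=np.arange(len(y), dtype=float),
                              channels={"total": y},
                              metadata={"bg_mean": 0.0, "pulse_frames": [10],
                                        "frame_interval_s": 1.0})
    curve = extract_and_average_recovery([make([0.2, 0.6, 0.9]),
                                          make([0.4, 0.6, 0.7])])
    assert np.allclose(curve.intensity, [0.3, 0.6, 0.8])
    assert curve.n_traces == 2


def test_recovery_normalization_invariance():
    traces = _frap_traces(2.0, n=10, seed=3)
    base = extract_and_average_recovery(traces)
    scaled = []
    for tr in traces:
        meta = dict(tr.metadata)
        meta["bg_mean"] = tr.metadata["bg_mean"] * 7.0
        scaled.append(IntensityTrace(times=tr.times,
                                     channels={"total": tr.total * 7.0},
                                     metadata=meta))
    curve = extract_and_average_recovery(scaled)
    assert np.allclose(curve.intensity, base.intensity, atol=1e-6)


def test_no_pulse_effect_gives_flat_curve():
    """When the 'pulse' power equals normal power nothing bleaches and the
    normalized curve stays at 1."""
    x = ExchangeParams(n_sites=2, k_on=0.5, conc=1.0, k_off=0.0, k_handoff=20.0)
    photo = PhotoParams(bg_mean=50.0, bg_sd=5.0, pulse_period_s=20.0,
                        pulse_duration_s=1.0, frame_interval_s=0.5,
                        bleach_lifetime_s=1e9, power_pulse=1.0)
    traces = simulate_frap_experiment(x, photo, n_replisomes=40,
                                      duration_s=80.0, seed=5)
    curve = extract_and_average_recovery(traces)
    assert np.all(np.abs(curve.intensity - 1.0) < 0.15)


def test_fit_exact_saturating_exponential():
    t = np.arange(0, 20, 0.25)
    curve = RecoveryCurve(time_s=t, intensity=1 - np.exp(-t / 2.0), n_traces=1)
    fit = fit_exchange_time(curve)
    assert not fit.flagged
    assert fit.tau_s == pytest.approx(2.0, abs=1e-6)


def test_zero_recovery_flagged():
    t = np.arange(0, 30, 0.5)
    curve = RecoveryCurve(time_s=t, intensity=np.zeros_like(t), n_traces=1)
    fit = fit_exchange_time(curve)
    assert fit.flagged
    assert "no recovery" in fit.note


def test_frap_zero_concentration_no_recovery():
    """With no Pol III* in solution the signal stays at background after the
    pulse (pre-assembly dilution experiment)."""
    x = ExchangeParams(conc=0.0)
    photo = PhotoParams(pulse_period_s=30.0, **FRAP_PHOTO)
    traces = simulate_frap_experiment(x, photo, n_replisomes=30,
                                      duration_s=90.0, seed=9)
    post = []
    for tr in traces:
        mask = tr.metadata["pulse_mask"]
        end = int(np.flatnonzero(mask)[-1]) + 1
        post.append((tr.total[end + 4:] - photo.bg_mean).mean())
    unit = photo.unit_intensity
    assert np.mean(post) < 0.02 * unit


def test_steady_state_intensity_matches_occupancy_closed_form():
    """Pre-pulse mean = unit x label_efficiency x cores x mean occupancy
    (handoff is slow compared with auxiliary-site dynamics)."""
    x = ExchangeParams(conc=3.0)
    photo = PhotoParams(pulse_period_s=30.0, **FRAP_PHOTO)
    rng = np.random.default_rng(33)
    pre = []
    for _ in range(200):
        traces = simulate_frap_experiment(x, photo, n_replisomes=1,
                                          duration_s=30.0, seed=rng)
        tr = traces[0]
        start = tr.metadata["pulse_frames"][0] if tr.metadata["pulse_frames"] \
            else len(tr.total)
        pre.append((tr.total[10:start] - photo.bg_mean).mean())
    expected = (photo.unit_intensity * x.label_efficiency
                * x.cores_per_complex * x.mean_occupancy)
    assert abs(np.mean(pre) - expected) / expected < 0.05


def test_pulse_schedule_validation():
    x = ExchangeParams()
    with pytest.raises(ValueError):
        simulate_frap_experiment(x, PhotoParams(), 5, 60.0, seed=0)  # no pulses


@pytest.mark.parametrize("tau_res", [2.0, 10.0, 40.0])
def test_exchange_time_recovery(tau_res):
    """Fitted recovery time matches the generative residence time within 15%."""
    traces = _frap_traces(tau_res, n=100, seed=101)
    fit = fit_exchange_time(extract_and_average_recovery(traces))
    assert not fit.flagged
    assert abs(fit.tau_s - tau_res) / tau_res < 0.15


def test_exchange_vs_concentration_model_recovery():
    """tau(C) = 1/(0.55 C) + 1.7 sampled at four concentrations is inverted
    to the generative parameters within 10%."""
    from polexchange.datatypes import ExchangeTimeFit
    results = []
    for c in (0.03, 0.3, 3.0, 13.0):
        tau = 1.0 / (0.55 * c) + 1.7
        results.append((c, ExchangeTimeFit(tau_s=tau, tau_err_s=0.1,
                                           amplitude=1.0, offset=0.0)))
    df, model = exchange_vs_concentration(results, fit_model=True)
    assert df.attrs["monotonic_decreasing"] is True
    assert abs(model["k_on"] - 0.55) / 0.55 < 0.10
    assert abs(model["k_handoff"] - 1 / 1.7) / (1 / 1.7) < 0.10


def test_exchange_vs_concentration_single_point():
    from polexchange.datatypes import ExchangeTimeFit
    df, model = exchange_vs_concentration(
        [(3.0, ExchangeTimeFit(2.0, 0.1, 1.0, 0.0))], fit_model=True)
    assert model is None
    assert len(df) == 1
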