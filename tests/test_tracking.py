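"""Fork tracking, trajectory segmentation, rate and processivity fits."""

import itertools

import numpy as np
import pytest

from polexchange import ExchangeParams, PhotoParams
from polexchange.datatypes import ReplicationTrajectory
from polexchange.simulate import (deposits_from_occupancy, render_kymograph,
                                  simulate_exchange,
                                  simulate_replication_trajectory)
from polexchange.tracking import (PiecewiseLinearSegmenter, fit_processivity,
                                  fit_rate_distribution, segment_trajectory,
                                  track_fork)


def test_track_noiseless_roundtrip_within_half_pixel(noiseless_photo):
    traj = simulate_replication_trajectory(seed=3)
    kymo = render_kymograph(traj, None, noiseless_photo, seed=0)
    tracked = track_fork(kymo)
    half_px_bp = 0.5 * kymo.pixel_size_um / kymo.gamma_um_per_kb * 1000.0
    err = np.abs(tracked.length_bp - traj.length_bp[:len(tracked.length_bp)])
    assert err.max() < half_px_bp


def test_track_static_fork_zero_slope(noiseless_photo):
    t = np.arange(60) * 0.5
    traj = ReplicationTrajectory(times=t, length_bp=np.full(60, 3000.0))
    kymo = render_kymograph(traj, None, noiseless_photo, seed=0)
    tracked = track_fork(kymo)
    assert np.ptp(tracked.length_bp) < 1.0  # flat to well below one pixel


def test_tracker_follows_tip_not_deposits():
    """Stationary deposited spots behind the fork must not capture the
    tracker."""
    p = ExchangeParams(conc=6.7)
    photo = PhotoParams(bg_mean=20.0, bg_sd=5.0)
    occ = simulate_exchange(p, 50.0, seed=6)
    traj = simulate_replication_trajectory(seed=8, processivity_mean_bp=40_000)
    n = min(len(traj.times), len(occ.times))
    traj = ReplicationTrajectory(times=traj.times[:n],
                                 length_bp=traj.length_bp[:n])
    deposits = deposits_from_occupancy(occ, traj, photo)
    kymo = render_kymograph(traj, deposits, photo, seed=1)
    tracked = track_fork(kymo)
    px_bp = kymo.pixel_size_um / kymo.gamma_um_per_kb * 1000.0
    err = np.abs(tracked.length_bp - traj.length_bp)
    assert np.median(err) < 2 * px_bp


def test_segment_single_slope_exact():
    t = np.arange(50) * 0.5
    segs = segment_trajectory(ReplicationTrajectory(times=t, length_bp=400.0 * t))
    assert len(segs) == 1
    assert segs[0].slope_bp_s == pytest.approx(400.0, abs=1e-9)


def test_segment_two_slope_recovery():
    rng = np.random.default_rng(17)
    t = np.arange(200) * 0.5
    y = np.where(t < 50.0, 500.0 * t, 500.0 * 50.0 + 250.0 * (t - 50.0))
    y = y + rng.normal(0, 50.0, len(t))
    seg = PiecewiseLinearSegmenter().fit(t, y)
    assert len(seg.breakpoints_) == 1
    assert abs(seg.breakpoints_[0] - 100) <= 3
    slopes = [s.slope_bp_s for s in seg.segments_]
    assert abs(slopes[0] - 500.0) / 500.0 < 0.10
    assert abs(slopes[1] - 250.0) / 250.0 < 0.10


def _brute_force_linear(t, y, penalty, min_size, max_cp=2):
    n = len(y)

    def rss(a, b):
        if b - a < 2:
            return 0.0
        coef = np.polyfit(t[a:b], y[a:b], 1)
        return float(((np.polyval(coef, t[a:b]) - y[a:b]) ** 2).sum())

    best = (np.inf, ())
    for k in range(max_cp + 1):
        for bps in itertools.combinations(range(min_size, n - min_size + 1), k):
            bounds = (0,) + bps + (n,)
            if any(b - a < min_size for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            c = sum(rss(a, b) for a, b in zip(bounds[:-1], bounds[1:])) + penalty * k
            if c < best[0] - 1e-9:
                best = (c, bps)
    return best


def test_segmenter_matches_exhaustive_enumeration():
    """On short traces the DP must find the same penalized optimum as brute
    force over all breakpoint placements."""
    rng = np.random.default_rng(23)
    for _ in range(20):
        n = int(rng.integers(20, 51))
        t = np.arange(n) * 0.5
        k_true = int(rng.integers(0, 3))
        bps = np.sort(rng.choice(np.arange(5, n - 5), size=k_true, replace=False))
        slopes = rng.uniform(100, 600, k_true + 1)
        y = np.zeros(n)
        bounds = [0] + list(bps) + [n]
        level = 0.0
        for (a, b), sl in zip(zip(bounds[:-1], bounds[1:]), slopes):
            y[a:b] = level + sl * (t[a:b] - t[a])
            level = y[b - 1] + sl * 0.5
        y += rng.normal(0, 30.0, n)
        penalty = float(rng.uniform(20_000, 80_000))
        seg = PiecewiseLinearSegmenter(penalty=penalty, min_duration_s=2.0).fit(t, y)
        cost_bf, bps_bf = _brute_force_linear(t, y, penalty, min_size=4)
        assert len(seg.breakpoints_) <= 2, "penalty too low for the oracle cap"
        assert tuple(seg.breakpoints_) == bps_bf
        assert seg.cost_ == pytest.approx(cost_bf, rel=1e-8)


def test_segmenter_penalty_monotonicity():
    rng = np.random.default_rng(31)
    t = np.arange(120) * 0.5
    y = 400 * t + rng.normal(0, 60, len(t))
    costs, nsegs = [], []
    for pen in (1e6, 1e5, 1e4, 1e3):
        seg = PiecewiseLinearSegmenter(penalty=pen).fit(t, y)
        rss = seg.cost_ - pen * len(seg.breakpoints_)
        costs.append(rss)
        nsegs.append(len(seg.segments_))
    assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))
    assert all(a <= b for a, b in zip(nsegs, nsegs[1:]))


def test_segmenter_rejects_degenerate_input():
    with pytest.raises(ValueError):
        PiecewiseLinearSegmenter().fit([0.0, 0.0, 0.0, 0.0], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        PiecewiseLinearSegmenter().fit([0.0, 0.5], [1, 2])


def test_rate_fit_identical_slopes():
    fit = fit_rate_distribution([500.0] * 10)
    assert fit.mean_bp_s == 500.0
    assert fit.sem_bp_s == 0.0


def test_rate_fit_gaussian_recovery():
    """500 slopes from N(492, 120) recover the wild-type mean within 2 sem."""
    rng = np.random.default_rng(2)
    slopes = rng.normal(492.0, 120.0, 500)
    fit = fit_rate_distribution(slopes)
    assert abs(fit.mean_bp_s - 492.0) < 2 * fit.sem_bp_s + 1e-9
    assert abs(fit.mean_bp_s - slopes.mean()) / slopes.mean() < 0.02


def test_rate_fit_small_n_flagged():
    fit = fit_rate_distribution([100.0, 200.0, 300.0])
    assert fit.flagged
    assert fit.mean_bp_s == pytest.approx(200.0)


def test_processivity_mle_matches_sample_mean():
    rng = np.random.default_rng(3)
    lengths = rng.exponential(73_000.0, 1000)
    fit = fit_processivity(lengths)
    assert abs(fit.mean_bp - 73_000.0) / 73_000.0 < 0.10
    assert fit.mean_bp == pytest.approx(lengths.mean(), rel=1e-12)


def test_processivity_challenge_scenario():
    """Replisomes challenged by excess core have ~3.5 kb processivity; the
    fit recovers the generative mean within 15%."""
    rng = np.random.default_rng(29)
    finals = [simulate_replication_trajectory(processivity_mean_bp=3500.0,
                                              seed=rng).processivity_bp
              for _ in range(200)]
    fit = fit_processivity(finals)
    assert abs(fit.mean_bp - 3500.0) / 3500.0 < 0.15


def test_processivity_degenerate_flagged():
    fit = fit_processivity([5000.0] * 20)
    assert fit.flagged
    assert fit.mean_bp == 5000.0
    with pytest.raises(ValueError):
        fit_processivity([-1.0] * 20)


def test_roundtrip_simulate_render_track_segment():
    """Rates and processivities survive the full image pipeline."""
    photo = PhotoParams(bg_mean=20.0, bg_sd=5.0)
    rng = np.random.default_rng(41)
    slopes, finals = [], []
    for _ in range(60):
        traj = simulate_replication_trajectory(seed=rng)
        kymo = render_kymograph(traj, None, photo, seed=rng)
        tracked = track_fork(kymo)
        finals.append(tracked.final_length_bp)
        if len(tracked.times) >= 8:
            for s in segment_trajectory(tracked, min_duration_s=3.0):
                if s.slope_bp_s > 0:
                    slopes.append(s.slope_bp_s)
    rate = fit_rate_distribution(slopes)
    assert abs(rate.mean_bp_s - 561.0) / 561.0 < 0.05
    proc = fit_processivity(finals)
    true_mean = 73_000.0
    # 60 exponential draws: sampling error dominates; compare against the
    # realized sample of generative finals instead of the ensemble mean
    assert abs(proc.mean_bp - true_mean) / true_mean < 3.0 / np.sqrt(60) + 0.02
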