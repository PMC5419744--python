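"""Synthetic rolling-circle replication trajectories.

A trajectory is piecewise linear in (time, DNA length): per-segment synthesis
rates are Gaussian, segment durations exponential, and the total synthesized
length (the processivity) exponential.  Defaults reflect the measured
values for labeled Pol III* in solution: 561 bp/s mean rate and 73 kb mean
processivity.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import ReplicationTrajectory

__all__ = ["simulate_replication_trajectory"]


def simulate_replication_trajectory(rate_mean_bp_s: float = 561.0,
                                    rate_sd_bp_s: float = 120.0,
                                    processivity_mean_bp: float = 73_000.0,
                                    segment_mean_duration_s: float = 40.0,
                                    frame_interval_s: float = 0.5,
                                    seed=None,
                                    n_segments: int | None = None) -> ReplicationTrajectory:
    """Draw one piecewise-linear replication trajectory.

    Parameters
    ----------
    rate_mean_bp_s, rate_sd_bp_s : float
        Gaussian distribution of per-segment synthesis rates; negative
        samples are truncated at 0.
    processivity_mean_bp : float
        Mean of the exponential total-length distribution.
    segment_mean_duration_s : float
        Mean of the exponential per-segment duration distribution.
    n_segments : int, optional
        Force exactly this many segments (rate re-drawn per segment, total
        length still exponential); used mainly for controlled tests.
    """
    if rate_mean_bp_s <= 0:
        raise ValueError("rate_mean_bp_s must be > 0")
    if rate_sd_bp_s < 0:
        raise ValueError("rate_sd_bp_s must be >= 0")
    if processivity_mean_bp <= 0:
        raise ValueError("processivity_mean_bp must be > 0")

    rng = np.random.default_rng(seed)
    total_bp = rng.exponential(processivity_mean_bp)

    segments = []           # (t_start, t_end, slope)
    t = 0.0
    length = 0.0
    k = 0
    while length < total_bp:
        slope = max(0.0, rng.normal(rate_mean_bp_s, rate_sd_bp_s))
        if n_segments is not None and k == n_segments - 1:
            dur = np.inf
        else:
            dur = rng.exponential(segment_mean_duration_s)
        if slope > 0 and length + slope * dur >= total_bp:
            dur = (total_bp - length) / slope
            segments.append((t, t + dur, slope))
            t += dur
            length = total_bp
            break
        if not np.isfinite(dur):
            # zero-rate forced final segment cannot terminate; cap it
            dur = segment_mean_duration_s
        segments.append((t, t + dur, slope))
        t += dur
        length += slope * dur
        k += 1
        if k > 10_000:
            break

    # piecewise-linear interpolation through segment endpoints
    node_t = [0.0]
    node_len = [0.0]
    for (t0, t1, slope) in segments:
        node_t.append(t1)
        node_len.append(node_len[-1] + slope * (t1 - t0))

    duration = max(t, frame_interval_s)
    times = np.arange(0.0, duration + frame_interval_s / 2, frame_interval_s)
    bp = np.interp(times, node_t, node_len)

    return ReplicationTrajectory(times=times, length_bp=bp, segments=segments,
                                 processivity_bp=float(total_bp))
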