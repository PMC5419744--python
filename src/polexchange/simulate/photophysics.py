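"""Photophysics: irreversible photobleaching and detected intensities.

Each fluorophore bleaches irreversibly while its complex is bound (and hence
inside the evanescent excitation field).  The per-frame bleach probability is
``1 - exp(-dt * power / bleach_lifetime)``, with the rate scaling linearly in
excitation power; frames inside FRAP pulses use the elevated pulse power.
Detected intensity is ``unit_intensity`` per active fluorophore plus Gaussian
background.  Intensity is measured at the start of a frame, before that
frame's bleaching is applied, so a pulse with per-frame bleach probability p
leaves a fraction ``(1-p)^m`` of fluorophores after m pulse frames.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import IntensityTrace, OccupancyTrace
from ..params import PhotoParams, param_hash

__all__ = ["apply_photophysics"]


def apply_photophysics(occ: OccupancyTrace, photo: PhotoParams, seed,
                       channels: str = "by_color") -> IntensityTrace:
    """Convert ground-truth occupancy into a noisy intensity trace.

    Parameters
    ----------
    occ : OccupancyTrace
    photo : PhotoParams
    seed : int or numpy.random.Generator
    channels : {'by_color', 'total'}
        'by_color' returns one channel per fluorophore color present in the
        simulation; 'total' sums them.

    Returns
    -------
    IntensityTrace
        With truth linkage (per-frame occupancy and active-fluorophore
        counts) and metadata recording seed, pulse frames and parameters.
    """
    if photo.bg_sd < 0:
        raise ValueError("bg_sd must be >= 0")
    if abs(photo.frame_interval_s - occ.frame_interval_s) > 1e-12:
        raise ValueError("photo.frame_interval_s must match the occupancy frame grid")

    rng = np.random.default_rng(seed)
    times = occ.times
    n = len(times)
    pulse = photo.pulse_mask(times)
    p_normal = photo.bleach_probability(photo.power_normal)
    p_pulse = photo.bleach_probability(photo.power_pulse)

    colors = ("red", "green") if channels == "by_color" else ("total",)
    signal = {c: np.zeros(n) for c in colors}
    active_counts = np.zeros(n, dtype=int)
    occupancy = np.zeros(n, dtype=int)

    active: dict[int, int] = {}
    for i in range(n):
        p = p_pulse if pulse[i] else p_normal
        frame_active = 0
        for cid in occ.frames[i]:
            if cid not in active:
                active[cid] = occ.complexes[cid].n_labels
            a = active[cid]
            frame_active += a
            key = occ.complexes[cid].color if channels == "by_color" else "total"
            signal[key][i] += photo.unit_intensity * a
            if a and p > 0.0:
                active[cid] = a - int(rng.binomial(a, p))
        active_counts[i] = frame_active
        occupancy[i] = len(occ.frames[i])

    out = {}
    for c in colors:
        noise = rng.normal(photo.bg_mean, photo.bg_sd, size=n) if photo.bg_sd > 0 \
            else np.full(n, float(photo.bg_mean))
        out[c] = signal[c] + noise

    pulse_starts = np.flatnonzero(pulse & ~np.roll(pulse, 1)) if pulse.any() else np.array([], int)
    meta = {
        "frame_interval_s": occ.frame_interval_s,
        "bg_mean": photo.bg_mean,
        "pulse_frames": pulse_starts.tolist(),
        "pulse_mask": pulse,
        "conc_nm": occ.params.conc if occ.params is not None else None,
        "param_hash": param_hash(photo),
    }
    truth = {"occupancy": occupancy, "active_fluorophores": active_counts,
             "occupancy_trace": occ}
    return IntensityTrace(times=times.copy(), channels=out, truth=truth,
                          metadata=meta)
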