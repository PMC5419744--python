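"""Simulated two-color replisome-focus traces under candidate exchange mechanisms.

Each focus carries two labeled species (channel 1, epsilon-like; channel 2,
tau-like).  Binding at the focus is a discrete-time two-state Markov process
with per-frame probabilities ``k_on`` (empty -> bound) and ``k_off``
(bound -> empty); every arrival brings a fresh (unbleached) fluorophore and
bound fluorophores bleach irreversibly.  The four mechanisms differ only in
how the two channels' occupancy processes are coupled:

- ``complex_exchange``: one occupancy process drives both channels (the whole
  complex arrives and departs as a unit).
- ``no_exchange``: stable binding for both (k_on = 1, k_off << 1).
- ``core_only_exchange``: channel 1 exchanges at the set rates, channel 2 is
  stably bound.
- ``uncoupled``: both channels exchange independently at the set rates.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import IntensityTrace
from ..params import PhotoParams

__all__ = ["simulate_invivo_pair", "MECHANISMS", "STABLE_K_OFF"]

MECHANISMS = ("complex_exchange", "no_exchange", "core_only_exchange", "uncoupled")

#: "k_off << 1" for stably bound species, as a documented constant.
STABLE_K_OFF = 1e-6

#: Default in vivo photophysics: 0.1 s frames, single fluorescent proteins
#: with unit intensities near the measured single-molecule step sizes.
DEFAULT_INVIVO_PHOTO = PhotoParams(bleach_lifetime_s=20.0, frame_interval_s=0.1,
                                   unit_intensity=158.0, bg_mean=0.0, bg_sd=25.0)


def _occupancy_chain(n_frames: int, k_on: float, k_off: float,
                     rng: np.random.Generator) -> np.ndarray:
    """0/1 occupancy; starts bound (a pre-formed focus)."""
    occ = np.empty(n_frames, dtype=bool)
    state = True
    u = rng.random(n_frames)
    for i in range(n_frames):
        occ[i] = state
        if state:
            state = u[i] >= k_off
        else:
            state = u[i] < k_on
    return occ


def _channel_intensity(occ: np.ndarray, photo: PhotoParams, unit: float,
                       rng: np.random.Generator):
    """Intensity of one channel given its occupancy, with bleaching.

    Returns (intensity, event_log) where event_log lists (frame, 'arrive' or
    'depart').
    """
    n = len(occ)
    p_bleach = photo.bleach_probability(photo.power_normal)
    bleached = False
    signal = np.zeros(n)
    events = []
    prev = False
    for i in range(n):
        if occ[i] and not prev:
            events.append((i, "arrive"))
            bleached = False            # fresh fluorophore from solution
        elif prev and not occ[i]:
            events.append((i, "depart"))
        if occ[i] and not bleached:
            signal[i] = unit
            if rng.random() < p_bleach:
                bleached = True
        prev = occ[i]
    noise = rng.normal(photo.bg_mean, photo.bg_sd, size=n) if photo.bg_sd > 0 else photo.bg_mean
    return signal + noise, events


def simulate_invivo_pair(mechanism: str,
                         k_on: float = 0.01,
                         k_off: float = 0.01,
                         n_frames: int = 400,
                         n_foci: int = 300,
                         photo: PhotoParams = DEFAULT_INVIVO_PHOTO,
                         seed=None,
                         unit_intensities: tuple[float, float] = (158.0, 130.0)
                         ) -> list[IntensityTrace]:
    """Simulate paired two-channel focus traces for one exchange mechanism.

    Rates are per frame and must lie in [0, 1].  Returns one IntensityTrace
    per focus with channels 'ch1' and 'ch2' and per-channel event logs in
    ``metadata['events']``.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}")
    if not (0.0 <= k_on <= 1.0 and 0.0 <= k_off <= 1.0):
        raise ValueError("per-frame rates must lie in [0, 1]")
    if n_foci < 1:
        raise ValueError("n_foci must be >= 1")

    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * photo.frame_interval_s
    traces = []
    for f in range(n_foci):
        if mechanism == "complex_exchange":
            occ = _occupancy_chain(n_frames, k_on, k_off, rng)
            occ1, occ2 = occ, occ
        elif mechanism == "no_exchange":
            occ1 = _occupancy_chain(n_frames, 1.0, STABLE_K_OFF, rng)
            occ2 = _occupancy_chain(n_frames, 1.0, STABLE_K_OFF, rng)
        elif mechanism == "core_only_exchange":
            occ1 = _occupancy_chain(n_frames, k_on, k_off, rng)
            occ2 = _occupancy_chain(n_frames, 1.0, STABLE_K_OFF, rng)
        else:  # uncoupled
            occ1 = _occupancy_chain(n_frames, k_on, k_off, rng)
            occ2 = _occupancy_chain(n_frames, k_on, k_off, rng)
        ch1, ev1 = _channel_intensity(occ1, photo, unit_intensities[0], rng)
        ch2, ev2 = _channel_intensity(occ2, photo, unit_intensities[1], rng)
        traces.append(IntensityTrace(
            times=times.copy(), channels={"ch1": ch1, "ch2": ch2},
            truth={"occupancy_ch1": occ1.astype(int), "occupancy_ch2": occ2.astype(int)},
            metadata={"frame_interval_s": photo.frame_interval_s,
                      "bg_mean": photo.bg_mean, "focus_id": f,
                      "mechanism": mechanism,
                      "events": {"ch1": ev1, "ch2": ev2}}))
    return traces
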