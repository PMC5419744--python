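"""Simulated single-molecule FRAP experiments.

Replisomes evolve under the exchange CTMC while periodic high-power pulses
photobleach every fork-bound fluorophore.  Recovery occurs only through
exchange: complexes entering from solution carry fresh fluorophores.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import IntensityTrace
from ..params import ExchangeParams, PhotoParams
from .exchange import simulate_exchange
from .photophysics import apply_photophysics

__all__ = ["simulate_frap_experiment"]


def simulate_frap_experiment(x: ExchangeParams, photo: PhotoParams,
                             n_replisomes: int = 23,
                             duration_s: float = 90.0,
                             seed=None) -> list[IntensityTrace]:
    """Simulate pulsed-illumination intensity traces for ``n_replisomes``.

    ``photo`` must define a pulse schedule (period at least 2 frames).
    Returns single-channel ('total') traces with truth linkage.
    """
    if not photo.pulses_enabled:
        raise ValueError("photo must define a FRAP pulse schedule "
                         "(pulse_period_s and pulse_duration_s)")
    if photo.pulse_period_s < 2 * photo.frame_interval_s:
        raise ValueError("pulse_period_s must span at least 2 frames")
    if n_replisomes < 1:
        raise ValueError("n_replisomes must be >= 1")

    root = np.random.default_rng(seed)
    traces = []
    for _ in range(n_replisomes):
        occ = simulate_exchange(x, duration_s, root,
                                frame_interval_s=photo.frame_interval_s)
        traces.append(apply_photophysics(occ, photo, root, channels="total"))
    return traces
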