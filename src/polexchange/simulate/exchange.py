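"""Event-driven simulation of multisite competitive Pol III* exchange.

The replisome is modeled as one resident binding site plus ``n_sites - 1``
auxiliary sites.  Empty auxiliary sites fill from solution at rate
``k_on * C`` each and empty at ``k_off``.  While at least one auxiliary
occupant is present, the resident is replaced at rate ``k_handoff``: the
resident departs and one (uniformly chosen) auxiliary occupant takes its
place, vacating its auxiliary site.  At C = 0 no competitor ever arrives and
the resident persists indefinitely — the dilution-stability limit.  In the
``n_sites = 2, k_off = 0`` limit the mean resident residence time is
``1/(k_on*C) + 1/k_handoff``.

The jump process is simulated exactly (Gillespie), then sampled onto a
regular frame grid.
"""

from __future__ import annotations

import math

import numpy as np

from ..datatypes import ComplexInfo, Event, OccupancyTrace
from ..params import ExchangeParams

__all__ = ["simulate_exchange", "ExchangeSimulationError"]


class ExchangeSimulationError(RuntimeError):
    """Raised when the event count guard is exceeded."""


def _new_complex(cid: int, t: float, params: ExchangeParams,
                 rng: np.random.Generator) -> ComplexInfo:
    color = "red" if rng.random() < params.color_fractions[0] else "green"
    n_labels = int(rng.binomial(params.cores_per_complex, params.label_efficiency))
    return ComplexInfo(cid=cid, color=color, n_labels=n_labels, t_arrival=t)


def simulate_exchange(params: ExchangeParams, duration_s: float, seed,
                      frame_interval_s: float = 0.5,
                      max_events: int = 2_000_000) -> OccupancyTrace:
    """Simulate the exchange CTMC for one pre-assembled replisome.

    Parameters
    ----------
    params : ExchangeParams
    duration_s : float
        Simulated time span; the trace starts with one resident bound.
    seed : int or numpy.random.Generator
    frame_interval_s : float
        Sampling interval of the returned frame grid.
    max_events : int
        Guard on the total number of jump events.

    Returns
    -------
    OccupancyTrace
        Frame-sampled occupancy plus the full event log.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n_aux_total = params.n_sites - 1
    expected_events = duration_s * (
        (params.arrival_rate + params.k_off) * n_aux_total + params.k_handoff)
    if expected_events > max_events:
        raise ExchangeSimulationError(
            "expected event count exceeds max_events guard; "
            "reduce duration or rates, or raise max_events")

    rng = np.random.default_rng(seed)
    next_cid = 0
    resident = _new_complex(next_cid, 0.0, params, rng)
    next_cid += 1
    n_aux = params.n_sites - 1
    aux: list[ComplexInfo | None] = [None] * n_aux

    complexes = {resident.cid: resident}
    events = [Event(0.0, "initial_resident", resident.cid)]

    # state-change timeline for frame sampling: (time, bound ids, resident id)
    timeline_t = [0.0]
    timeline_state = [((resident.cid,), resident.cid)]

    k_arr = params.arrival_rate
    t = 0.0
    n_events = 0
    while True:
        occ_idx = [i for i in range(n_aux) if aux[i] is not None]
        emp_idx = [i for i in range(n_aux) if aux[i] is None]
        r_arrive = k_arr * len(emp_idx)
        r_depart = params.k_off * len(occ_idx)
        r_hand = params.k_handoff if occ_idx else 0.0
        total = r_arrive + r_depart + r_hand
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration_s:
            break
        n_events += 1
        if n_events > max_events:
            raise ExchangeSimulationError("event count guard exceeded")
        u = rng.random() * total
        if u < r_arrive:
            site = emp_idx[int(rng.integers(len(emp_idx)))]
            comp = _new_complex(next_cid, t, params, rng)
            next_cid += 1
            aux[site] = comp
            complexes[comp.cid] = comp
            events.append(Event(t, "arrive_aux", comp.cid))
        elif u < r_arrive + r_depart:
            site = occ_idx[int(rng.integers(len(occ_idx)))]
            comp = aux[site]
            aux[site] = None
            events.append(Event(t, "depart_aux", comp.cid))
        else:
            site = occ_idx[int(rng.integers(len(occ_idx)))]
            promoted = aux[site]
            aux[site] = None
            events.append(Event(t, "handoff", promoted.cid, other=resident.cid))
            resident = promoted
        bound = tuple([resident.cid] + [c.cid for c in aux if c is not None])
        timeline_t.append(t)
        timeline_state.append((bound, resident.cid))

    times = np.arange(0.0, duration_s, frame_interval_s)
    idx = np.searchsorted(np.asarray(timeline_t), times, side="right") - 1
    frames = [timeline_state[i][0] for i in idx]
    resident_ids = np.array([timeline_state[i][1] for i in idx], dtype=int)

    return OccupancyTrace(times=times, frames=frames, resident=resident_ids,
                          complexes=complexes, events=events,
                          frame_interval_s=frame_interval_s, params=params)
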