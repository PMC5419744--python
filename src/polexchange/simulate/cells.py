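"""Synthetic whole-cell photobleaching data for copy-number counting.

Emulates a field of immobilized cells expressing a fluorescently tagged
replisome subunit:

- per-cell total fluorescence = copies x unit intensity (each molecule
  bleaching at an exponential lifetime) + constant cellular autofluorescence
  + coverslip background shared across the field, which itself bleaches
  single-exponentially;
- per-focus traces containing a few molecules that bleach step-wise, used to
  calibrate the single-molecule intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datatypes import IntensityTrace
from ..params import PhotoParams

__all__ = ["simulate_cell_field", "CellField"]


@dataclass
class CellField:
    times: np.ndarray
    field_background: np.ndarray        # coverslip background, counts/frame
    autofluorescence: np.ndarray        # wild-type-like cell trace (constant)
    cell_traces: list                   # total cell fluorescence, counts
    focus_traces: list                  # IntensityTrace, stepwise bleaching
    truth: dict = field(default_factory=dict)


def simulate_cell_field(n_cells: int = 273,
                        copies_per_cell: int = 104,
                        unit_intensity: float = 158.0,
                        autofluorescence: float = 2000.0,
                        coverslip_decay_s: float = 30.0,
                        coverslip_amplitude: float = 5000.0,
                        photo: PhotoParams | None = None,
                        n_focus_traces: int = 300,
                        focus_copies: tuple[int, int] = (2, 5),
                        seed=None,
                        noise_sd: float = 60.0) -> CellField:
    """Simulate one field of cells plus single-focus bleaching traces.

    Defaults reflect the epsilon-like channel: 104 copies per cell and a
    single-molecule intensity of 158 counts.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if copies_per_cell < 0:
        raise ValueError("copies_per_cell must be >= 0")
    if photo is None:
        photo = PhotoParams(bleach_lifetime_s=10.0, frame_interval_s=0.1,
                            unit_intensity=unit_intensity, bg_mean=0.0,
                            bg_sd=noise_sd)

    rng = np.random.default_rng(seed)
    n_frames = int(round(4 * photo.bleach_lifetime_s / photo.frame_interval_s))
    times = np.arange(n_frames) * photo.frame_interval_s

    field_bg = coverslip_amplitude * np.exp(-times / coverslip_decay_s)
    field_bg_noisy = field_bg + rng.normal(0, noise_sd / 4, size=n_frames)
    auto = np.full(n_frames, autofluorescence) + rng.normal(0, noise_sd / 4, size=n_frames)

    cell_traces = []
    for _ in range(n_cells):
        if copies_per_cell > 0:
            bleach_times = rng.exponential(photo.bleach_lifetime_s, size=copies_per_cell)
            n_active = (bleach_times[None, :] > times[:, None]).sum(axis=1)
        else:
            n_active = np.zeros(n_frames)
        trace = (unit_intensity * n_active + autofluorescence + field_bg
                 + rng.normal(0, noise_sd, size=n_frames))
        cell_traces.append(trace)

    focus_traces = []
    p_bleach = photo.bleach_probability(photo.power_normal)
    for f in range(n_focus_traces):
        m = int(rng.integers(focus_copies[0], focus_copies[1] + 1))
        bleach_frames = rng.geometric(p_bleach, size=m)  # frames survived
        n_active = (bleach_frames[None, :] > np.arange(n_frames)[:, None]).sum(axis=1)
        y = unit_intensity * n_active + rng.normal(0, noise_sd / 2, size=n_frames)
        focus_traces.append(IntensityTrace(
            times=times.copy(), channels={"total": y},
            truth={"n_active": n_active, "n_molecules": m},
            metadata={"frame_interval_s": photo.frame_interval_s,
                      "bg_mean": 0.0, "focus_id": f}))

    truth = {"copies_per_cell": copies_per_cell, "unit_intensity": unit_intensity,
             "autofluorescence": autofluorescence,
             "coverslip_decay_s": coverslip_decay_s,
             "coverslip_amplitude": coverslip_amplitude,
             "bleach_lifetime_s": photo.bleach_lifetime_s}
    return CellField(times=times, field_background=field_bg_noisy,
                     autofluorescence=auto, cell_traces=cell_traces,
                     focus_traces=focus_traces, truth=truth)
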