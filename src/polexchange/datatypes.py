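"""Core data containers shared across simulation and analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ComplexInfo", "Event", "OccupancyTrace", "IntensityTrace",
    "ReplicationTrajectory", "Kymograph", "SegmentFit", "RateFit",
    "ProcessivityFit", "Calibration", "StoichiometryResult", "RecoveryCurve",
    "ExchangeTimeFit", "CcfCurve", "MechanismCall", "StepFit", "CellRecord",
]

#: Default DNA-length to image-length conversion: a 7.2 kb template spans
#: 2.1 um when flow-stretched, so gamma = 2.1/7.2 um per kb.
DEFAULT_GAMMA_UM_PER_KB = 2.1 / 7.2


@dataclass(frozen=True)
class ComplexInfo:
    """One Pol III* complex that visited the replisome."""

    cid: int
    color: str                 # 'red' or 'green'
    n_labels: int              # active fluorophores carried on arrival
    t_arrival: float


@dataclass(frozen=True)
class Event:
    """Entry in the exchange event log.

    kind is one of 'initial_resident', 'arrive_aux', 'depart_aux',
    'handoff' (cid = promoted auxiliary occupant, other = departing
    resident).
    """

    time: float
    kind: str
    cid: int
    other: Optional[int] = None


@dataclass
class OccupancyTrace:
    """Frame-sampled ground-truth occupancy of the replisome.

    ``frames[i]`` is the tuple of complex ids bound at ``times[i]``;
    ``resident[i]`` is the id of the resident complex.
    """

    times: np.ndarray
    frames: list
    resident: np.ndarray
    complexes: dict
    events: list
    frame_interval_s: float
    params: object = None

    def occupancy_counts(self) -> np.ndarray:
        return np.array([len(f) for f in self.frames], dtype=int)

    def aux_occupancy_fraction(self) -> float:
        """Time-average fraction of auxiliary sites occupied (frame-sampled)."""
        n_aux = self.params.n_sites - 1
        if n_aux == 0:
            return 0.0
        occ = self.occupancy_counts() - 1
        return float(occ.mean() / n_aux)

    def resident_residence_times(self) -> np.ndarray:
        """Durations of completed resident tenures (handoff to handoff)."""
        starts: dict[int, float] = {}
        for ev in self.events:
            if ev.kind == "initial_resident":
                starts[ev.cid] = ev.time
        durations = []
        for ev in self.events:
            if ev.kind == "handoff":
                if ev.other in starts:
                    durations.append(ev.time - starts.pop(ev.other))
                starts[ev.cid] = ev.time
        return np.asarray(durations, dtype=float)

    def replacement_count(self) -> int:
        return sum(1 for ev in self.events if ev.kind == "handoff")


@dataclass
class IntensityTrace:
    """Per-frame fluorescence of one spot/focus, one or two channels."""

    times: np.ndarray
    channels: dict
    truth: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name, arr in self.channels.items():
            if len(arr) != n:
                raise ValueError(f"channel {name!r} length != times length")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")

    @property
    def frame_interval_s(self) -> float:
        if "frame_interval_s" in self.metadata:
            return float(self.metadata["frame_interval_s"])
        return float(np.median(np.diff(self.times)))

    @property
    def total(self) -> np.ndarray:
        return np.sum([np.asarray(v, float) for v in self.channels.values()], axis=0)

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class ReplicationTrajectory:
    """Synthesized DNA length versus time for one replisome."""

    times: np.ndarray
    length_bp: np.ndarray
    segments: Optional[list] = None      # truth (t_start, t_end, slope_bp_s)
    processivity_bp: Optional[float] = None
    gaps: Optional[np.ndarray] = None    # frames where tracking found no spot

    @property
    def final_length_bp(self) -> float:
        return float(self.length_bp[-1])


@dataclass
class Kymograph:
    """Position-versus-time image of one DNA molecule."""

    image: np.ndarray                    # [position, time], counts
    pixel_size_um: float
    frame_interval_s: float
    gamma_um_per_kb: float = DEFAULT_GAMMA_UM_PER_KB
    origin_px: float = 0.0               # pixel row of the surface anchor (length 0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gamma_um_per_kb <= 0:
            raise ValueError("gamma_um_per_kb must be > 0")
        if self.image.ndim != 2:
            raise ValueError("kymograph image must be 2-D [position, time]")

    def row_to_bp(self, row) -> np.ndarray:
        """Convert a (possibly fractional) pixel row to DNA length in bp."""
        return ((np.asarray(row, float) - self.origin_px) * self.pixel_size_um
                / self.gamma_um_per_kb * 1000.0)

    def bp_to_row(self, bp) -> np.ndarray:
        return (np.asarray(bp, float) / 1000.0 * self.gamma_um_per_kb
                / self.pixel_size_um + self.origin_px)


# ---------------------------------------------------------------------------
# Fit-result records


@dataclass(frozen=True)
class SegmentFit:
    t_start: float
    t_end: float
    slope_bp_s: float
    intercept_bp: float
    residual_sd_bp: float


@dataclass(frozen=True)
class RateFit:
    mean_bp_s: float
    sem_bp_s: float
    n: int
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class ProcessivityFit:
    mean_bp: float
    error_bp: float
    n: int
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class Calibration:
    unit_mean: float
    unit_sd: float
    n: int
    channel: str = ""
    flagged: bool = False
    note: str = ""

    @property
    def relative_sd(self) -> float:
        return self.unit_sd / self.unit_mean


@dataclass
class StoichiometryResult:
    counts: np.ndarray                   # per-frame (or per-molecule) counts
    n_components: int = 0
    weights: Optional[np.ndarray] = None
    mode: Optional[int] = None
    metadata: dict = field(default_factory=dict)


@dataclass
class RecoveryCurve:
    """Averaged, normalized post-pulse fluorescence recovery."""

    time_s: np.ndarray                   # time since end of pulse
    intensity: np.ndarray                # normalized to pre-pulse steady state
    n_traces: int
    conc_nm: Optional[float] = None


@dataclass(frozen=True)
class ExchangeTimeFit:
    tau_s: float
    tau_err_s: float
    amplitude: float
    offset: float
    flagged: bool = False
    note: str = ""


@dataclass
class CcfCurve:
    """Normalized cross-correlation versus lag (symmetric about zero)."""

    lags: np.ndarray                     # frames (or seconds, see metadata)
    values: np.ndarray
    n_pairs: int
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MechanismCall:
    label: str                           # 'positive_peak' or 'flat'
    peak_value: float
    null_threshold: float


@dataclass
class StepFit:
    change_points: np.ndarray            # frame indices, strictly increasing
    levels: np.ndarray                   # per-segment means
    residual_var: float

    @property
    def step_sizes(self) -> np.ndarray:
        return -np.diff(self.levels)     # positive for bleaching (downward) steps


@dataclass
class CellRecord:
    cell_id: int
    area_px: float = np.nan
    mean_intensity: float = np.nan
    amplitude: float = np.nan            # bleach-fit intensity at t = 0
    copies: float = np.nan
    concentration_nm: float = np.nan
    flagged: bool = False
    note: str = ""
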