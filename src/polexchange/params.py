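"""Parameter containers for the exchange-kinetics and photophysics models.

The exchange model pictures a replisome as one *resident* Pol III* binding
site plus a small number of auxiliary, replisome-proximal sites (e.g. on the
beta-clamp or helicase) that competitors from solution can transiently
occupy.  The resident is stable in isolation but is competed out, at a
concentration-dependent rate, whenever an auxiliary site is occupied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

__all__ = ["ExchangeParams", "PhotoParams", "CellGeometry", "param_hash"]

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ExchangeParams:
    """Kinetic constants of the multisite competitive exchange model.

    Parameters
    ----------
    n_sites : int
        Total number of replisome-proximal binding sites (one resident plus
        ``n_sites - 1`` auxiliary sites).
    k_on : float
        Per-site association rate constant, 1/(nM s).  Together with
        ``k_handoff`` the default reproduces the measured exchange-time
        anchors (1.85 s at 13 nM, 42 s at 30 pM) through
        ``tau(C) = 1/(k_on*C) + 1/k_handoff``.
    k_off : float
        Dissociation rate of an auxiliary-site occupant, 1/s.  Large values
        make auxiliary binding transient, keeping the modal occupancy at one
        complex at nanomolar concentrations.
    k_handoff : float
        Rate at which a resident is replaced by an auxiliary occupant while
        at least one auxiliary site is occupied, 1/s.
    conc : float
        Free Pol III* concentration in solution, nM.
    cores_per_complex : int
        Labeled polymerase cores per Pol III* complex.
    label_efficiency : float
        Probability that a core carries an active fluorophore.
    color_fractions : tuple of float
        Fractions of complexes in solution labeled (red, green).
    """

    n_sites: int = 3
    k_on: float = 0.83
    k_off: float = 15.0
    k_handoff: float = 0.57
    conc: float = 6.7
    cores_per_complex: int = 3
    label_efficiency: float = 0.85
    color_fractions: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        _require(self.n_sites >= 1, "n_sites must be >= 1")
        for name in ("k_on", "k_off", "k_handoff", "conc"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be finite and >= 0")
        _require(self.cores_per_complex >= 1, "cores_per_complex must be >= 1")
        _require(0.0 <= self.label_efficiency <= 1.0,
                 "label_efficiency must be in [0, 1]")
        _require(len(self.color_fractions) == 2
                 and all(f >= 0 for f in self.color_fractions)
                 and abs(sum(self.color_fractions) - 1.0) < 1e-9,
                 "color_fractions must be two non-negative values summing to 1")

    @property
    def arrival_rate(self) -> float:
        """Per-empty-auxiliary-site arrival rate k_on * C, 1/s."""
        return self.k_on * self.conc

    @property
    def aux_occupancy(self) -> float:
        """Two-state equilibrium occupancy of one auxiliary site.

        Exact when ``k_handoff == 0``; a close approximation when
        ``k_handoff << k_off``.
        """
        r = self.arrival_rate
        if r == 0:
            return 0.0
        return r / (r + self.k_off)

    @property
    def mean_occupancy(self) -> float:
        """Equilibrium mean number of bound complexes (resident + auxiliary)."""
        return 1.0 + (self.n_sites - 1) * self.aux_occupancy


@dataclass(frozen=True)
class PhotoParams:
    """Photophysics and detection parameters.

    ``bleach_lifetime_s`` is the mean time to irreversible photobleaching of
    one fluorophore at the reference (normal) excitation power; the bleach
    rate scales linearly with power.  When ``pulse_period_s`` is set, frames
    falling inside the periodic high-power windows are illuminated at
    ``power_pulse`` (the smFRAP scheme).
    """

    bleach_lifetime_s: float = 14.1
    power_normal: float = 1.0
    power_pulse: float = 150.0
    pulse_duration_s: float | None = None
    pulse_period_s: float | None = None
    unit_intensity: float = 5100.0
    bg_mean: float = 100.0
    bg_sd: float = 30.0
    frame_interval_s: float = 0.5

    def __post_init__(self) -> None:
        _require(self.bleach_lifetime_s > 0, "bleach_lifetime_s must be > 0")
        _require(self.frame_interval_s > 0, "frame_interval_s must be > 0")
        _require(self.unit_intensity > 0, "unit_intensity must be > 0")
        _require(self.bg_sd >= 0, "bg_sd must be >= 0")
        _require(self.power_normal > 0 and self.power_pulse > 0,
                 "powers must be > 0")
        if self.pulses_enabled:
            _require(self.pulse_duration_s is not None and self.pulse_duration_s > 0,
                     "pulse_duration_s must be set and > 0 when pulses are enabled")
            _require(self.pulse_duration_s < self.pulse_period_s,
                     "pulse_duration_s must be shorter than pulse_period_s")
            _require(self.pulse_period_s >= 2 * self.frame_interval_s,
                     "pulse_period_s must cover at least 2 frames")

    @property
    def pulses_enabled(self) -> bool:
        return self.pulse_period_s is not None

    def bleach_probability(self, power: float) -> float:
        """Per-frame bleach probability at the given relative power."""
        rate = power / (self.bleach_lifetime_s * self.power_normal)
        return 1.0 - math.exp(-self.frame_interval_s * rate)

    def pulse_mask(self, times) -> "np.ndarray":
        """Boolean mask of frames lying inside FRAP pulses.

        Pulses start at t = k * pulse_period_s for k >= 1, so a steady-state
        window precedes the first pulse.
        """
        import numpy as np

        times = np.asarray(times, dtype=float)
        if not self.pulses_enabled:
            return np.zeros(times.shape, dtype=bool)
        phase = np.mod(times, self.pulse_period_s)
        return (phase < self.pulse_duration_s) & (times >= self.pulse_period_s)


@dataclass(frozen=True)
class CellGeometry:
    """Cell volume used to convert copy numbers to concentrations.

    The default 2.4 fL is consistent with both measured copy/concentration
    pairs (104 copies <-> 72 nM and 96 copies <-> 66-67 nM); it is a model
    parameter, not a measured quantity.
    """

    volume_fl: float = 2.4
    avogadro: float = field(default=AVOGADRO)

    def __post_init__(self) -> None:
        _require(self.volume_fl > 0, "volume_fl must be > 0")


def param_hash(*objs) -> str:
    """Stable short hash of one or more parameter dataclasses / dicts."""

    def norm(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: norm(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, dict):
            return {k: norm(o[k]) for k in sorted(o)}
        if isinstance(o, (list, tuple)):
            return [norm(v) for v in o]
        return o

    payload = json.dumps([norm(o) for o in objs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
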