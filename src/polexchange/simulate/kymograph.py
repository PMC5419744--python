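"""Render synthetic kymographs of a replicating DNA molecule.

The fork spot sits at image position ``gamma_um_per_kb * length(t) / 1000``
(converted to pixels) and is rendered as a 1-D Gaussian point-spread profile
whose *total* intensity is the spot amplitude, independent of position.
Complexes that depart the replisome can deposit stationary spots at the
departure position (polymerases left on Okazaki-fragment termini); when Pol I
is present these deposits are removed, so none are rendered.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import DEFAULT_GAMMA_UM_PER_KB, Kymograph, OccupancyTrace, ReplicationTrajectory
from ..params import PhotoParams

__all__ = ["render_kymograph", "deposits_from_occupancy", "KymographGeometryError"]


class KymographGeometryError(ValueError):
    """Fork excursion exceeds the image extent."""


def deposits_from_occupancy(occ: OccupancyTrace, traj: ReplicationTrajectory,
                            photo: PhotoParams) -> list:
    """Stationary deposit spots implied by departure events.

    Each auxiliary departure or handed-off resident deposits a spot at the
    fork position at its departure time, with amplitude set by its label
    count; the deposit amplitude then decays with the bleach lifetime.
    Returns a list of dicts with keys t_start, position_bp, amplitude.
    """
    deposits = []
    for ev in occ.events:
        if ev.kind == "depart_aux":
            cid = ev.cid
        elif ev.kind == "handoff":
            cid = ev.other
        else:
            continue
        pos_bp = float(np.interp(ev.time, traj.times, traj.length_bp))
        amp = photo.unit_intensity * occ.complexes[cid].n_labels
        deposits.append({"t_start": ev.time, "position_bp": pos_bp, "amplitude": amp})
    return deposits


def _add_spot_column(col: np.ndarray, center_px: float, amplitude: float,
                     sigma_px: float) -> None:
    rows = np.arange(len(col))
    profile = np.exp(-0.5 * ((rows - center_px) / sigma_px) ** 2)
    profile /= sigma_px * np.sqrt(2.0 * np.pi)
    col += amplitude * profile


def render_kymograph(traj: ReplicationTrajectory,
                     spots: list | None,
                     photo: PhotoParams,
                     pol1_present: bool = False,
                     seed=None,
                     pixel_size_um: float = 0.16,
                     gamma_um_per_kb: float = DEFAULT_GAMMA_UM_PER_KB,
                     psf_sigma_px: float = 1.0,
                     fork_amplitude: float | None = None,
                     n_rows: int | None = None) -> Kymograph:
    """Render a [position, time] kymograph for one trajectory.

    Parameters
    ----------
    traj : ReplicationTrajectory
    spots : list of dict, optional
        Stationary deposits (from :func:`deposits_from_occupancy`); ignored
        when ``pol1_present`` is True.
    fork_amplitude : float, optional
        Total counts of the fork spot per frame; defaults to the intensity of
        one fully labeled complex.
    n_rows : int, optional
        Image height in pixels; auto-sized to the fork excursion if omitted.
        If given and too small, a geometry error is raised.
    """
    rng = np.random.default_rng(seed)
    if fork_amplitude is None:
        fork_amplitude = photo.unit_intensity * 3
    origin_px = float(np.ceil(4 * psf_sigma_px))  # keep the anchor off the edge
    fork_px = traj.length_bp / 1000.0 * gamma_um_per_kb / pixel_size_um + origin_px
    need_rows = int(np.ceil(fork_px.max())) + int(np.ceil(4 * psf_sigma_px)) + 1
    if n_rows is None:
        n_rows = need_rows
    elif fork_px.max() > n_rows - 1:
        raise KymographGeometryError(
            f"fork excursion {fork_px.max():.1f} px exceeds image height {n_rows}")

    n_frames = len(traj.times)
    image = np.zeros((n_rows, n_frames))
    for j in range(n_frames):
        _add_spot_column(image[:, j], fork_px[j], fork_amplitude, psf_sigma_px)

    if spots and not pol1_present:
        for dep in spots:
            row = dep["position_bp"] / 1000.0 * gamma_um_per_kb / pixel_size_um + origin_px
            j0 = int(np.searchsorted(traj.times, dep["t_start"]))
            for j in range(j0, n_frames):
                decay = np.exp(-(traj.times[j] - dep["t_start"]) / photo.bleach_lifetime_s)
                _add_spot_column(image[:, j], row, dep["amplitude"] * decay, psf_sigma_px)

    if photo.bg_sd > 0 or photo.bg_mean != 0:
        image += rng.normal(photo.bg_mean, photo.bg_sd, size=image.shape)
    np.clip(image, 0.0, None, out=image)  # rendered images only; traces keep sign

    return Kymograph(image=image, pixel_size_um=pixel_size_um,
                     frame_interval_s=float(np.median(np.diff(traj.times)))
                     if n_frames > 1 else 1.0,
                     gamma_um_per_kb=gamma_um_per_kb, origin_px=origin_px,
                     metadata={"fork_amplitude": fork_amplitude,
                               "psf_sigma_px": psf_sigma_px})
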