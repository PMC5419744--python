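"""Readers and writers for the package's standard file formats.

- Images (kymographs, field stacks): multi-page 16-bit TIFF via tifffile,
  with a JSON metadata sidecar carrying pixel size, frame interval, the
  bp<->um conversion, seed and parameter hash.
- Traces: long-format CSV with columns
  (focus_id, frame, time_s, channel, intensity, truth_count).
- Fits, event logs, manifests: JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import IntensityTrace, Kymograph

__all__ = ["write_kymograph", "read_kymograph", "write_traces", "read_traces",
           "write_json", "read_json", "file_sha256"]


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default)
                    + "\n")
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def write_kymograph(path, kymo: Kymograph, seed=None, params_hash: str = "") -> Path:
    """Write a kymograph as 16-bit TIFF plus a JSON sidecar."""
    path = Path(path)
    img = np.clip(np.round(kymo.image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, img)
    sidecar = {
        "pixel_size_um": kymo.pixel_size_um,
        "frame_interval_s": kymo.frame_interval_s,
        "gamma_um_per_kb": kymo.gamma_um_per_kb,
        "origin_px": kymo.origin_px,
        "seed": seed,
        "param_hash": params_hash,
        "metadata": {k: v for k, v in kymo.metadata.items()
                     if isinstance(v, (int, float, str, bool))},
    }
    write_json(path.with_suffix(".json"), sidecar)
    return path


def read_kymograph(path) -> Kymograph:
    path = Path(path)
    img = tifffile.imread(path).astype(float)
    side = read_json(path.with_suffix(".json"))
    return Kymograph(image=img, pixel_size_um=side["pixel_size_um"],
                     frame_interval_s=side["frame_interval_s"],
                     gamma_um_per_kb=side["gamma_um_per_kb"],
                     origin_px=side.get("origin_px", 0.0),
                     metadata=side.get("metadata", {}))


def write_traces(path, traces: list[IntensityTrace]) -> Path:
    """Write traces as long-format CSV."""
    rows = []
    for k, tr in enumerate(traces):
        fid = tr.metadata.get("focus_id", k)
        truth = tr.truth.get("occupancy") if tr.truth else None
        for name, y in tr.channels.items():
            for i, (t, v) in enumerate(zip(tr.times, y)):
                rows.append({"focus_id": fid, "frame": i, "time_s": t,
                             "channel": name, "intensity": v,
                             "truth_count": (int(truth[i]) if truth is not None
                                             else np.nan)})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6f")
    return Path(path)


def read_traces(path) -> list[IntensityTrace]:
    """Read a long-format trace CSV back into IntensityTrace objects."""
    df = pd.read_csv(path)
    traces = []
    for fid, g in df.groupby("focus_id", sort=True):
        channels = {}
        times = None
        truth_count = None
        for name, gc in g.groupby("channel", sort=True):
            gc = gc.sort_values("frame")
            channels[name] = gc["intensity"].to_numpy(dtype=float)
            times = gc["time_s"].to_numpy(dtype=float)
            if gc["truth_count"].notna().all():
                truth_count = gc["truth_count"].to_numpy(dtype=int)
        truth = {"occupancy": truth_count} if truth_count is not None else None
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        traces.append(IntensityTrace(times=times, channels=channels, truth=truth,
                                     metadata={"focus_id": fid,
                                               "frame_interval_s": dt}))
    return traces


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
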