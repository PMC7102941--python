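"""File I/O: multi-page TIFF channel stacks, track tables, ground truth.

Localization-table I/O lives in :mod:`trnafret.smlm` (it is part of that
analysis surface); this module covers the image and table formats shared
by the simulators and the widefield/tracking analyses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthdata import ChannelStack, Track, TrackSet

__all__ = [
    "write_channel_stack",
    "read_channel_stack",
    "write_tracks",
    "read_tracks",
    "write_ground_truth_json",
]

#: page order used for channel-stack TIFFs
CHANNEL_ORDER = ("donor", "acceptor", "fret", "marker")


def write_channel_stack(stack: ChannelStack, path) -> None:
    """Write a channel stack as a multi-page TIFF (page order donor,
    acceptor, raw-FRET, marker; marker page omitted when absent).  The
    pixel size is stored in the TIFF resolution tags (pixels per cm)."""
    pages = [stack.donor, stack.acceptor, stack.fret]
    if stack.marker is not None:
        pages.append(stack.marker)
    data = np.stack([np.asarray(p, dtype=np.float32) for p in pages])
    px_per_cm = 1e7 / stack.pixel_size_nm
    tifffile.imwrite(path, data, resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")


def read_channel_stack(path, pixel_size_nm: float | None = None) -> ChannelStack:
    """Read a channel stack written by :func:`write_channel_stack`.

    The pixel size is recovered from the resolution tags unless given
    explicitly.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if pixel_size_nm is None:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None and unit is not None and unit.value == 3:
                num, den = res.value
                pixel_size_nm = 1e7 * den / num
            else:
                pixel_size_nm = 108.0
    if data.ndim != 3 or data.shape[0] < 3:
        raise ValueError("expected a multi-page TIFF with >= 3 channel pages")
    marker = data[3] if data.shape[0] > 3 else None
    return ChannelStack(donor=data[0].astype(float), acceptor=data[1].astype(float),
                        fret=data[2].astype(float), marker=marker,
                        pixel_size_nm=float(pixel_size_nm))


def write_tracks(trackset: TrackSet, path) -> None:
    """Write tracks as delimited text (track_id, frame, x_nm, y_nm,
    compartment)."""
    trackset.to_frame().to_csv(path, index=False)


def read_tracks(path, frame_interval_s: float = 60.0) -> TrackSet:
    df = pd.read_csv(path)
    tracks = []
    for tid, sub in df.groupby("track_id"):
        sub = sub.sort_values("frame")
        comp = sub["compartment"].iloc[0] if "compartment" in sub.columns else None
        if isinstance(comp, float) and np.isnan(comp):
            comp = None
        tracks.append(Track(frames=sub["frame"].to_numpy(),
                            xy_nm=sub[["x_nm", "y_nm"]].to_numpy(),
                            compartment=comp, track_id=int(tid)))
    return TrackSet(tracks=tracks, frame_interval_s=frame_interval_s)


def write_ground_truth_json(truth, path) -> None:
    """Serialize a ground-truth dataclass to JSON (arrays become lists)."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, dict):
            return o
        raise TypeError(f"not JSON serializable: {type(o)}")

    payload = truth.__dict__ if hasattr(truth, "__dict__") else truth
    # JSON object keys must be strings (e.g. channel-pair tuples)
    def stringify(obj):
        if isinstance(obj, dict):
            return {str(k): stringify(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [stringify(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(stringify(payload), fh, indent=2, sort_keys=True, default=default)
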