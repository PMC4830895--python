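"""TIFF / JSON / TSV round-trips for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .datatypes import TimeLapseStack

__all__ = ["save_stack", "load_stack"]


def save_stack(stack: TimeLapseStack, path: str | Path) -> None:
    """Write a frame-major, channel-interleaved multi-page 16-bit TIFF."""
    t, c, h, w = stack.frames.shape
    meta = {
        "channels": stack.channels,
        "frame_interval_min": stack.frame_interval_min,
        "t0_min": stack.t0_min,
        "shape": [t, c, h, w],
    }
    pages = np.asarray(stack.frames, dtype=np.uint16).reshape(t * c, h, w)
    tifffile.imwrite(str(path), pages, description=json.dumps(meta))


def load_stack(path: str | Path) -> TimeLapseStack:
    try:
        with tifffile.TiffFile(str(path)) as tif:
            desc = tif.pages[0].description
            pages = tif.asarray()
    except Exception as exc:
        raise ValueError(f"not a readable TIFF stack: {path}") from exc
    try:
        meta = json.loads(desc)
        t, c, h, w = meta["shape"]
    except Exception as exc:
        raise ValueError(f"missing or malformed stack metadata in {path}") from exc
    frames = pages.reshape(t, c, h, w)
    return TimeLapseStack(
        frames=frames,
        channels={k: int(v) for k, v in meta["channels"].items()},
        frame_interval_min=float(meta["frame_interval_min"]),
        t0_min=float(meta.get("t0_min", 0.0)),
    )
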