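"""Greedy nearest-centroid nucleus tracking and ratio measurement.

HepG2 nuclei move little between 6-min frames, so frame-to-frame linking
uses greedy nearest-neighbour assignment with a hard displacement gate and
no gap closing: a link farther than the gate ends the track and starts a
new one.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
from skimage.measure import regionprops

from .datatypes import CellTrack, RatioTrace, TimeLapseStack
from .segmentation import estimate_background

__all__ = ["track_nuclei", "measure_ratio", "frame_centroids"]


def frame_centroids(label_image: np.ndarray) -> Dict[int, np.ndarray]:
    """label -> (row, col) centroid."""
    return {p.label: np.asarray(p.centroid) for p in regionprops(np.asarray(label_image))}


def track_nuclei(
    labels_per_frame: Sequence[np.ndarray],
    max_disp_px: float = 10.0,
    min_coverage: float = 0.8,
) -> List[CellTrack]:
    """Link nuclei across frames by greedy nearest-centroid assignment.

    Pairs are assigned in order of increasing distance; distances above
    ``max_disp_px`` are never linked.  Tracks covering fewer than
    ``min_coverage`` of all frames are discarded.
    """
    n_frames = len(labels_per_frame)
    if n_frames < 1:
        raise ValueError("need at least one frame")

    open_tracks: List[dict] = []
    finished: List[dict] = []

    for f in range(n_frames):
        cents = frame_centroids(labels_per_frame[f])
        det_labels = list(cents)
        active = [tr for tr in open_tracks if tr["frames"][-1] == f - 1]
        # greedy ascending-distance one-to-one matching
        pairs = []
        for ti, tr in enumerate(active):
            for di, lab in enumerate(det_labels):
                d = float(np.linalg.norm(tr["centroids"][-1] - cents[lab]))
                if d <= max_disp_px:
                    pairs.append((d, ti, di))
        pairs.sort()
        used_t, used_d = set(), set()
        for d, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = active[ti]
            lab = det_labels[di]
            tr["frames"].append(f)
            tr["labels"].append(lab)
            tr["centroids"].append(cents[lab])
        # unmatched open tracks that were active are now closed
        for ti, tr in enumerate(active):
            if ti not in used_t:
                open_tracks.remove(tr)
                finished.append(tr)
        # unmatched detections start new tracks
        for di, lab in enumerate(det_labels):
            if di not in used_d:
                open_tracks.append(
                    {"frames": [f], "labels": [lab], "centroids": [cents[lab]]}
                )
    finished.extend(open_tracks)

    min_len = min_coverage * n_frames
    tracks = []
    tid = 0
    for tr in sorted(finished, key=lambda t: (t["frames"][0], t["centroids"][0].tolist())):
        if len(tr["frames"]) >= min_len:
            tracks.append(
                CellTrack(
                    track_id=tid,
                    frames=tr["frames"],
                    labels=tr["labels"],
                    centroids=np.asarray(tr["centroids"]),
                )
            )
            tid += 1
    return tracks


def measure_ratio(
    track: CellTrack,
    stack: TimeLapseStack,
    nucleus_labels: Sequence[np.ndarray],
    cytoplasm_labels: Sequence[np.ndarray],
    bg_exclude_px: int = 15,
    backgrounds: Optional[Sequence[float]] = None,
) -> RatioTrace:
    """Background-corrected nuclear/cytoplasmic mean-intensity ratio along
    one track.  Frames with non-positive cytoplasmic signal after
    background subtraction are marked missing (NaN)."""
    reporter = stack.channel("reporter")
    times, values = [], []
    for frame, label in zip(track.frames, track.labels):
        img = np.asarray(reporter[frame], dtype=float)
        if backgrounds is not None:
            bg = backgrounds[frame]
        else:
            bg = estimate_background(img, nucleus_labels[frame], bg_exclude_px)
        nmask = nucleus_labels[frame] == label
        cmask = cytoplasm_labels[frame] == label
        times.append(stack.times_min[frame])
        if not nmask.any() or not cmask.any():
            values.append(np.nan)
            continue
        nuc = img[nmask].mean() - bg
        cyt = img[cmask].mean() - bg
        values.append(nuc / cyt if cyt > 0 else np.nan)
    return RatioTrace(cell_id=track.track_id, times=np.asarray(times), values=np.asarray(values))
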