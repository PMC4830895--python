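"""Nuclei segmentation, cytoplasm-ring assignment and background estimation.

Nuclei are found by a global Otsu threshold (fixed override available)
followed by a distance-transform watershed to split touching nuclei.
Cytoplasm is the nearest-nucleus dilation ring, which partitions ring
pixels between neighbouring cells.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import expand_labels, relabel_sequential, watershed

__all__ = [
    "segment_nuclei",
    "segment_cytoplasm",
    "estimate_background",
]


def segment_nuclei(
    nuclei_image: np.ndarray,
    min_area_px: int = 50,
    threshold: Optional[float] = None,
    split_min_distance_px: int = 8,
) -> np.ndarray:
    """Label image of nuclei; 0 is background.

    A blank or constant image yields zero labels rather than an error.
    Touching nuclei are split by seeding a watershed with local maxima of
    the Euclidean distance transform (at least ``split_min_distance_px``
    apart); components below ``min_area_px`` are removed.
    """
    img = np.asarray(nuclei_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    labels = np.zeros(img.shape, dtype=np.int32)
    if np.ptp(img) == 0:
        return labels
    thr = threshold_otsu(img) if threshold is None else threshold
    fg = img > thr
    if not fg.any():
        return labels

    dist = ndi.distance_transform_edt(fg)
    comp, _ = ndi.label(fg)
    coords = peak_local_max(
        dist, min_distance=split_min_distance_px, labels=comp, exclude_border=False
    )
    if len(coords) == 0:
        labels = comp.astype(np.int32)
    else:
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = watershed(-dist, markers, mask=fg).astype(np.int32)

    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area_px)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cytoplasm(nucleus_labels: np.ndarray, ring_width_px: int) -> np.ndarray:
    """Per-nucleus cytoplasm ring: dilation by ``ring_width_px`` minus all
    nuclei, with contested pixels going to the nearest nucleus.  Width 0
    returns an empty label image."""
    labels = np.asarray(nucleus_labels)
    if ring_width_px <= 0:
        return np.zeros_like(labels)
    expanded = expand_labels(labels, distance=ring_width_px)
    return np.where(labels > 0, 0, expanded).astype(labels.dtype)


def estimate_background(
    image: np.ndarray, nucleus_labels: np.ndarray, exclude_px: int = 15
) -> float:
    """Median intensity outside all nuclei dilated by ``exclude_px``
    (keeps cytoplasm rings out of the estimate)."""
    outside = expand_labels(np.asarray(nucleus_labels), distance=exclude_px) == 0
    img = np.asarray(image, dtype=float)
    if not outside.any():
        return float(np.median(img))
    return float(np.median(img[outside]))
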