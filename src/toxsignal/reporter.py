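"""Well-level reporter quantification: Srxn1-GFP induction score,
Annexin-V death fraction / AUC, and the drug–TNFα synergy statistic.

The Srxn1 score follows the adjacent-pixel rule: connected components of
pixels strictly above background, with components smaller than 45 px
(about one-fourth of an average cell footprint) discarded; the qualifying
pixel count times their mean above-background density is normalised by the
nucleus count.  The Annexin-V-positive pixel total is normalised to the
total cell area estimated from the transmission image.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .datatypes import DeathCurve, ReporterScore

__all__ = [
    "srxn1_score",
    "fold_induction",
    "annexin_fraction",
    "cell_area_from_transmission",
    "death_auc",
    "tnf_synergy",
]

# 8-connectivity for "adjacent" fluorescent pixels
_STRUCT8 = np.ones((3, 3), dtype=bool)

MIN_BLOB_PX = 45


def srxn1_score(
    reporter_image: np.ndarray,
    background: float,
    n_nuclei: int,
    min_blob_px: int = MIN_BLOB_PX,
    per_blob_density: bool = False,
    threshold: Optional[float] = None,
) -> float:
    """Srxn1-GFP induction score for one frame.

    score = (qualifying pixel count × mean above-background density of
    those pixels) / n_nuclei, where qualifying pixels belong to
    8-connected components of at least ``min_blob_px`` pixels strictly
    above ``threshold`` (default: ``background``; pass a noise-aware value
    for shot-noisy images — density stays relative to ``background`` so the
    score remains linear in true signal).  ``per_blob_density=True``
    averages per-blob mean densities instead of pooling all qualifying
    pixels.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    if threshold is None:
        threshold = background
    img = np.asarray(reporter_image, dtype=float)
    mask = img > threshold
    if not mask.any():
        return 0.0
    labels, n = ndi.label(mask, structure=_STRUCT8)
    if n == 0:
        return 0.0
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_blob_px) + 1
    if keep.size == 0:
        return 0.0
    qual = np.isin(labels, keep)
    excess = img[qual] - background
    if per_blob_density:
        density = float(
            np.mean([np.mean(img[labels == k] - background) for k in keep])
        )
    else:
        density = float(excess.mean())
    return float(qual.sum()) * density / n_nuclei


def fold_induction(
    treated: ReporterScore, control: ReporterScore, at_min: float = 1440.0
) -> float:
    """Treated / control score at ``at_min`` (linear interpolation in time).

    Raises ``ValueError`` if either series does not cover ``at_min`` or the
    control score there is zero.
    """
    for name, s in (("treated", treated), ("control", control)):
        if at_min < s.times[0] or at_min > s.times[-1]:
            raise ValueError(f"{name} series does not cover t={at_min} min")
    num = float(np.interp(at_min, treated.times, treated.score))
    den = float(np.interp(at_min, control.times, control.score))
    if den == 0:
        raise ValueError("control score is zero; fold induction undefined")
    return num / den


def annexin_fraction(
    death_image: np.ndarray, cell_area_px: float, background: float
) -> float:
    """Percent of the cell area that is Annexin-V positive (capped at 100)."""
    if cell_area_px <= 0:
        raise ValueError("cell_area_px must be > 0")
    positive = int(np.count_nonzero(np.asarray(death_image, dtype=float) > background))
    return float(min(100.0, 100.0 * positive / cell_area_px))


def cell_area_from_transmission(
    transmission_image: np.ndarray,
    window_px: int = 5,
    var_threshold: Optional[float] = None,
) -> int:
    """Pixel area occupied by cells, from local-variance texture.

    The local standard deviation over a ``window_px`` box marks textured
    (cell-occupied) regions; the mask is eroded by half the window to undo
    the filter's spatial smearing at cell borders.  A flat image gives 0.
    """
    img = np.asarray(transmission_image, dtype=float)
    mean = ndi.uniform_filter(img, size=window_px)
    sq = ndi.uniform_filter(img * img, size=window_px)
    std = np.sqrt(np.clip(sq - mean * mean, 0, None))
    if std.max() <= 1e-9:
        return 0
    thr = threshold_otsu(std) if var_threshold is None else var_threshold
    mask = std > thr
    pad = window_px // 2
    if pad > 0:
        mask = ndi.binary_erosion(mask, iterations=pad)
    return int(mask.sum())


def death_auc(curve: DeathCurve) -> float:
    """Trapezoidal area under the percent-positive curve, in %·hours."""
    hours = np.asarray(curve.times_min, dtype=float) / 60.0
    return float(np.trapezoid(curve.percent_positive, hours))


def tnf_synergy(pct_drug: float, pct_drug_tnf: float) -> float:
    """TNFα apoptosis enhancement in percentage points:
    percent dead with drug + TNFα minus percent dead with drug alone."""
    for v in (pct_drug, pct_drug_tnf):
        if not 0 <= v <= 100:
            raise ValueError("percentages must lie in [0, 100]")
    return pct_drug_tnf - pct_drug
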