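"""Rendering of synthetic time-lapse stacks.

Cells are placed on a jittered grid with guaranteed non-overlap so that
segmentation tests exercise splitting only when a fixture asks for it.
Intensities are camera counts over a flat background; optional Poisson
noise emulates shot noise.  All stacks are 16-bit, frame-major.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.draw import disk as draw_disk

from ..config import SimConfig
from ..datatypes import GroundTruth, RatioTrace, TimeLapseStack

__all__ = [
    "place_cells",
    "render_p65_stack",
    "simulate_srxn1_stack",
    "simulate_death_series",
    "draw_death_times",
]

NUCLEI_LEVEL = 1000.0  # Hoechst disk intensity above background
CYTO_LEVEL = 400.0  # cytoplasmic reporter intensity above background
DEATH_LEVEL = 500.0  # Annexin-V blob intensity above background
TEXTURE_AMPLITUDE = 80.0  # transmission texture half-range inside cells


def place_cells(
    n_cells: int,
    image_size: int,
    min_spacing: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jittered-grid cell centres, pairwise separated by >= min_spacing.

    Raises ``ValueError`` when ``n_cells`` cannot fit without touching the
    image border or each other.
    """
    if n_cells == 0:
        return np.empty((0, 2))
    m = int(np.ceil(np.sqrt(n_cells)))
    margin = min_spacing / 2.0 + 1.0
    pitch = (image_size - 2 * margin) / m
    if pitch < min_spacing:
        raise ValueError(
            f"{n_cells} cells with spacing {min_spacing} exceed a "
            f"{image_size}px image"
        )
    jitter_max = (pitch - min_spacing) / 2.0
    centers = []
    for i in range(m):
        for j in range(m):
            if len(centers) >= n_cells:
                break
            r = margin + pitch * (i + 0.5) + rng.uniform(-jitter_max, jitter_max)
            c = margin + pitch * (j + 0.5) + rng.uniform(-jitter_max, jitter_max)
            centers.append((r, c))
    return np.asarray(centers)


def _to_uint16(img: np.ndarray, rng: Optional[np.random.Generator]) -> np.ndarray:
    if rng is not None:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def render_p65_stack(
    traces: Sequence[RatioTrace],
    config: SimConfig,
    noise: bool = True,
    centers: Optional[np.ndarray] = None,
) -> TimeLapseStack:
    """Render ratio traces as a two-channel (nuclei, reporter) movie.

    The cytoplasmic ring is held at a fixed level and the nuclear reporter
    intensity is scaled, so the rendered (background-corrected) disk/ring
    intensity ratio equals the input trace value at every frame.
    """
    if traces:
        t0 = traces[0].times
        for tr in traces:
            if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
                raise ValueError("all traces must share one time base")
        times = t0
    else:
        times = config.times_min

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    r_nuc = config.nucleus_radius_px
    r_out = r_nuc + config.ring_width_px
    if centers is None:
        centers = place_cells(len(traces), config.image_size, 2 * r_out + 4.0, rng)
    else:
        centers = np.asarray(centers, dtype=float)
        if len(centers) != len(traces):
            raise ValueError("centers and traces length mismatch")
        lo, hi = centers.min(initial=np.inf), centers.max(initial=-np.inf)
        if len(centers) and (lo < r_out or hi > config.image_size - 1 - r_out):
            raise ValueError("cells exceed image bounds")

    shape = (config.image_size, config.image_size)
    noise_rng = rng if noise else None
    frames = np.empty((len(times), 2, *shape), dtype=np.uint16)
    for f in range(len(times)):
        nuclei = np.full(shape, config.background_level)
        reporter = np.full(shape, config.background_level)
        for tr, (cr, cc) in zip(traces, centers):
            rr_o, cc_o = draw_disk((cr, cc), r_out, shape=shape)
            reporter[rr_o, cc_o] = config.background_level + CYTO_LEVEL
            rr_n, cc_n = draw_disk((cr, cc), r_nuc, shape=shape)
            nuclei[rr_n, cc_n] = config.background_level + NUCLEI_LEVEL
            reporter[rr_n, cc_n] = config.background_level + CYTO_LEVEL * tr.values[f]
        frames[f, 0] = _to_uint16(nuclei, noise_rng)
        frames[f, 1] = _to_uint16(reporter, noise_rng)

    return TimeLapseStack(
        frames=frames,
        channels={"nuclei": 0, "reporter": 1},
        frame_interval_min=config.frame_interval_min,
        t0_min=float(times[0]),
    )


def srxn1_trajectories(config: SimConfig, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cell GFP trajectories (n_cells, T) and onset times."""
    p = config.srxn1
    t = config.times_min
    tau = p.plateau / (4.0 * p.rate)
    onsets = rng.normal(p.onset_min, p.onset_sd_min, size=config.n_cells)
    traj = p.plateau / (1.0 + np.exp(-(t[None, :] - onsets[:, None]) / tau))
    return traj, onsets


def simulate_srxn1_stack(
    config: SimConfig, noise: bool = True
) -> Tuple[TimeLapseStack, GroundTruth]:
    """Two-channel (nuclei, reporter) movie of sigmoidal Srxn1-GFP induction.

    Each cell is a disk of radius ``2 * nucleus_radius_px`` whose GFP level
    follows ``plateau * sigmoid((t - onset_i)/tau)``; nuclei are rendered for
    counting.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    traj, _ = srxn1_trajectories(config, rng)
    t = config.times_min
    r_cell = 2 * config.nucleus_radius_px
    centers = place_cells(config.n_cells, config.image_size, 2 * r_cell + 4.0, rng)

    shape = (config.image_size, config.image_size)
    noise_rng = rng if noise else None
    frames = np.empty((len(t), 2, *shape), dtype=np.uint16)
    for f in range(len(t)):
        nuclei = np.full(shape, config.background_level)
        reporter = np.full(shape, config.background_level)
        for i, (cr, cc) in enumerate(centers):
            rr, cc_ = draw_disk((cr, cc), r_cell, shape=shape)
            reporter[rr, cc_] = config.background_level + traj[i, f]
            rr_n, cc_n = draw_disk((cr, cc), config.nucleus_radius_px, shape=shape)
            nuclei[rr_n, cc_n] = config.background_level + NUCLEI_LEVEL
        frames[f, 0] = _to_uint16(nuclei, noise_rng)
        frames[f, 1] = _to_uint16(reporter, noise_rng)

    stack = TimeLapseStack(
        frames=frames,
        channels={"nuclei": 0, "reporter": 1},
        frame_interval_min=config.frame_interval_min,
    )
    truth = GroundTruth(per_cell_srxn1_trajectory=traj, cell_centers=centers)
    return stack, truth


def draw_death_times(
    config: SimConfig, with_tnf: bool, rng: np.random.Generator
) -> List[Optional[float]]:
    """Death times (minutes) from the piecewise-exponential hazard;
    ``None`` for cells surviving past the movie end.

    The cumulative hazard is ``h0 * t`` up to ``tnf_add_min`` and continues
    with slope ``h0 * tnf_multiplier`` afterwards when TNFα is added.
    """
    p = config.death
    h0 = p.baseline_hazard_per_h / 60.0  # per minute
    mult = p.tnf_multiplier if with_tnf else 1.0
    ta = p.tnf_add_min
    out: List[Optional[float]] = []
    for _ in range(config.n_cells):
        target = -np.log(rng.uniform())
        if h0 == 0:
            out.append(None)
            continue
        t_at_ta = h0 * ta
        if target <= t_at_ta:
            t = target / h0
        else:
            t = ta + (target - t_at_ta) / (h0 * mult)
        out.append(float(t) if t <= config.duration_min else None)
    return out


def simulate_death_series(
    config: SimConfig, with_tnf: bool, noise: bool = True
) -> Tuple[TimeLapseStack, GroundTruth]:
    """Two-channel (death, transmission) Annexin-V movie.

    Dead cells appear as Annexin-positive blobs from their death frame
    onward (death is irreversible, so labelling is cumulative); the static
    transmission channel carries intracellular texture for cell-area
    estimation.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, int(with_tnf)]))
    death_times = draw_death_times(config, with_tnf, rng)
    t = config.times_min
    r_cell = 2 * config.nucleus_radius_px
    centers = place_cells(config.n_cells, config.image_size, 2 * r_cell + 4.0, rng)

    shape = (config.image_size, config.image_size)
    texture = np.full(shape, config.background_level)
    for cr, cc in centers:
        rr, cc_ = draw_disk((cr, cc), r_cell, shape=shape)
        texture[rr, cc_] = config.background_level + rng.uniform(
            -TEXTURE_AMPLITUDE, TEXTURE_AMPLITUDE, size=len(rr)
        )

    noise_rng = rng if noise else None
    frames = np.empty((len(t), 2, *shape), dtype=np.uint16)
    for f, tf in enumerate(t):
        death = np.full(shape, config.background_level)
        for (cr, cc), td in zip(centers, death_times):
            if td is not None and tf >= td:
                rr, cc_ = draw_disk((cr, cc), r_cell, shape=shape)
                death[rr, cc_] = config.background_level + DEATH_LEVEL
        frames[f, 0] = _to_uint16(death, noise_rng)
        frames[f, 1] = _to_uint16(texture, noise_rng)

    stack = TimeLapseStack(
        frames=frames,
        channels={"death": 0, "transmission": 1},
        frame_interval_min=config.frame_interval_min,
    )
    truth = GroundTruth(per_cell_death_time_min=death_times, cell_centers=centers)
    return stack, truth
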