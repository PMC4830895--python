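"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TimeLapseStack",
    "RatioTrace",
    "NormalizedTrace",
    "CellTrack",
    "PeakSet",
    "OscillationFeatureSet",
    "PopulationSummary",
    "ReporterScore",
    "DeathCurve",
    "GroundTruth",
]

CHANNEL_ROLES = ("nuclei", "reporter", "death", "transmission")


@dataclass
class TimeLapseStack:
    """Ordered multi-channel time-lapse movie.

    ``frames`` has shape (T, C, H, W); ``channels`` maps a role name
    (nuclei / reporter / death / transmission) to its channel index.
    Frame 0 is acquired at ``t0_min`` minutes relative to stimulation.
    """

    frames: np.ndarray
    channels: dict
    frame_interval_min: float
    t0_min: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError("frames must have shape (T, C, H, W)")
        if self.frames.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        for role, idx in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role: {role}")
            if not 0 <= idx < self.frames.shape[1]:
                raise ValueError(f"channel index out of range for {role}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_min(self) -> np.ndarray:
        return self.t0_min + np.arange(self.n_frames) * self.frame_interval_min

    def channel(self, role: str) -> np.ndarray:
        """All frames of one channel, shape (T, H, W)."""
        return self.frames[:, self.channels[role]]


@dataclass
class RatioTrace:
    """Per-cell nuclear/cytoplasmic reporter intensity ratio over time.

    ``values`` may contain NaN where a frame measurement was invalid
    (e.g. non-positive cytoplasmic signal after background subtraction).
    """

    cell_id: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class NormalizedTrace:
    """Min–max normalised trace in [0, 1]; constant inputs are flagged
    degenerate and mapped to all zeros."""

    times: np.ndarray
    values: np.ndarray
    degenerate: bool = False


@dataclass
class CellTrack:
    """A tracked nucleus: per-frame label and centroid over a consecutive
    frame span."""

    track_id: int
    frames: list
    labels: list
    centroids: np.ndarray  # (n, 2) as (row, col)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if not (len(self.frames) == len(self.labels) == len(self.centroids)):
            raise ValueError("track fields must have equal length")
        if len(self.frames) > 1 and not all(
            b - a == 1 for a, b in zip(self.frames, self.frames[1:])
        ):
            raise ValueError("track frames must be consecutive")

    @property
    def span(self) -> tuple:
        return self.frames[0], self.frames[-1]


@dataclass
class PeakSet:
    """Detected peaks of one normalised trace."""

    indices: np.ndarray
    times_min: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class OscillationFeatureSet:
    """Single-cell NF-κB oscillation descriptors."""

    n_peaks: int
    peak_times_min: np.ndarray
    peak_heights: np.ndarray
    peak_periods_min: np.ndarray
    inter_peak_delays_min: np.ndarray
    delay_p1_p2_min: Optional[float]
    entry_rate: Optional[float]
    exit_rate: Optional[float]


@dataclass
class PopulationSummary:
    """Population-level oscillation readouts.

    ``histogram`` counts cells showing 0..5 peaks (≥5 capped at class 5)
    and always sums to ``n_cells``.
    """

    histogram: np.ndarray
    n_cells: int
    frac_three_plus: float
    mean_delay_p1_p2_min: Optional[float]
    mean_second_peak_min: Optional[float]
    mean_trace_times: Optional[np.ndarray] = None
    mean_trace_values: Optional[np.ndarray] = None


@dataclass
class ReporterScore:
    """Well-level Srxn1-GFP induction score time series (qualifying-pixel
    count × mean above-background density / nuclei count)."""

    times: np.ndarray
    score: np.ndarray
    n_nuclei: np.ndarray


@dataclass
class DeathCurve:
    """Annexin-V percent-positive curve; AUC integrates percent over hours."""

    times_min: np.ndarray
    percent_positive: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.percent_positive = np.asarray(self.percent_positive, dtype=float)
        if np.any(self.percent_positive < 0) or np.any(self.percent_positive > 100):
            raise ValueError("percent_positive must lie in [0, 100]")

    @property
    def auc(self) -> float:
        from .reporter import death_auc

        return death_auc(self)


@dataclass
class GroundTruth:
    """Known truth emitted alongside every synthetic dataset."""

    per_cell_peak_times_min: list = field(default_factory=list)
    per_cell_death_time_min: list = field(default_factory=list)
    per_cell_srxn1_trajectory: Optional[np.ndarray] = None
    planted_delay_min: float = 0.0
    planted_gene_blocks: dict = field(default_factory=dict)
    cell_centers: Optional[np.ndarray] = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "per_cell_peak_times_min": [list(map(float, p)) for p in self.per_cell_peak_times_min],
            "per_cell_death_time_min": [
                None if t is None else float(t) for t in self.per_cell_death_time_min
            ],
            "per_cell_srxn1_trajectory": (
                None
                if self.per_cell_srxn1_trajectory is None
                else np.asarray(self.per_cell_srxn1_trajectory).tolist()
            ),
            "planted_delay_min": float(self.planted_delay_min),
            "planted_gene_blocks": self.planted_gene_blocks,
            "cell_centers": None if self.cell_centers is None else np.asarray(self.cell_centers).tolist(),
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        traj = d.get("per_cell_srxn1_trajectory")
        centers = d.get("cell_centers")
        return cls(
            per_cell_peak_times_min=d.get("per_cell_peak_times_min", []),
            per_cell_death_time_min=d.get("per_cell_death_time_min", []),
            per_cell_srxn1_trajectory=None if traj is None else np.asarray(traj),
            planted_delay_min=d.get("planted_delay_min", 0.0),
            planted_gene_blocks=d.get("planted_gene_blocks", {}),
            cell_centers=None if centers is None else np.asarray(centers),
        )
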