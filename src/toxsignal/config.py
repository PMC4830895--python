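"""Simulation and analysis configuration.

All times are minutes after cytokine (TNFα) addition unless stated
otherwise; intensities are camera counts; lengths are pixels.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "OscillationParams",
    "Srxn1Params",
    "DeathParams",
    "DegParams",
    "SimConfig",
    "load_config",
    "save_config",
]


@dataclass
class OscillationParams:
    """Shape of the damped, progressively desynchronising NF-κB
    nuclear-translocation oscillation.

    The per-cell nuclear/cytoplasmic ratio is modelled as a baseline of 1
    plus a train of Gaussian bumps.  ``peak_width_min`` is the full width at
    half maximum of one bump; ``damping`` scales each successive bump;
    ``desync_sd_min`` is the standard deviation of the timing jitter *per
    peak index* (the first peak is synchronous, later peaks drift apart).
    ``treatment_delay_min`` shifts every peak after the first — the readout
    a perturbing drug produces.
    """

    first_peak_min: float = 30.0
    inter_peak_min: float = 120.0
    peak_width_min: float = 40.0
    amplitude: float = 1.0
    damping: float = 0.7
    desync_sd_min: float = 6.0
    treatment_delay_min: float = 0.0


@dataclass
class Srxn1Params:
    """Sigmoidal accumulation of the Srxn1-GFP oxidative-stress reporter.

    Per-cell GFP follows ``plateau * sigmoid((t - onset_i) / tau)`` with
    ``onset_i ~ Normal(onset_min, onset_sd_min)`` and the rise timescale
    ``tau = plateau / (4 * rate)`` so that ``rate`` is the slope (counts per
    minute) at the half-rise point.
    """

    onset_min: float = 480.0
    rate: float = 2.0
    plateau: float = 1000.0
    onset_sd_min: float = 60.0


@dataclass
class DeathParams:
    """Piecewise-exponential apoptosis hazard.

    Baseline hazard applies from t=0; when TNFα is co-added at
    ``tnf_add_min`` the hazard is multiplied by ``tnf_multiplier`` from that
    point on.  Defaults approximate a sensitising drug condition: ~4.5 %
    death at 24 h alone, ~14 % with TNFα added after an 8-h pre-exposure.
    """

    baseline_hazard_per_h: float = 0.002
    tnf_multiplier: float = 5.0
    tnf_add_min: float = 480.0


@dataclass
class DegParams:
    """Planted block structure for the synthetic differential-expression
    table: an Nrf2-target block (up under oxidative-stress model compounds
    and severe hepatotoxicants), an NF-κB/inflammatory block (up under
    cytokine models, down under the same hepatotoxicants) and a null
    background."""

    n_nrf2: int = 30
    n_nfkb: int = 40
    n_background: int = 200
    effect_nrf2: float = 2.5
    effect_nfkb: float = 2.5
    model_effect: float = 3.5
    mild_scale: float = 0.35
    lfc_noise_sd: float = 0.3
    block_expr_mean: float = 8.0
    block_expr_sd: float = 0.5
    background_expr_mean: float = 6.0
    background_expr_sd: float = 1.5


@dataclass
class SimConfig:
    """Full synthetic-experiment configuration.

    Defaults correspond to the p65 translocation assay: 512×512 frames every
    6 min for 6 h.  Use :meth:`srxn1_defaults` / :meth:`death_defaults` for
    the 30-min / 24-h reporter and death assays.
    """

    seed: int = 0
    n_cells: int = 100
    frame_interval_min: float = 6.0
    duration_min: float = 360.0
    image_size: int = 512
    nucleus_radius_px: int = 12
    ring_width_px: int = 5
    background_level: float = 100.0
    noise_sd: float = 0.05
    oscillation: OscillationParams = field(default_factory=OscillationParams)
    srxn1: Srxn1Params = field(default_factory=Srxn1Params)
    death: DeathParams = field(default_factory=DeathParams)
    deg: DegParams = field(default_factory=DegParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.duration_min < self.frame_interval_min:
            raise ValueError("duration_min must be >= frame_interval_min")
        osc = self.oscillation
        if not 0 < osc.damping <= 1:
            raise ValueError("damping must lie in (0, 1]")
        if not osc.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        for name, v in [
            ("noise_sd", self.noise_sd),
            ("desync_sd_min", osc.desync_sd_min),
            ("peak_width_min", osc.peak_width_min),
            ("onset_sd_min", self.srxn1.onset_sd_min),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        for obj in (self, osc, self.srxn1, self.death):
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, (int, float)) and not math.isfinite(v):
                    raise ValueError(f"non-finite parameter: {f.name}")

    @property
    def times_min(self):
        import numpy as np

        n = int(round(self.duration_min / self.frame_interval_min)) + 1
        return np.arange(n) * self.frame_interval_min

    @classmethod
    def srxn1_defaults(cls, **overrides: Any) -> "SimConfig":
        """24-h Srxn1-GFP assay imaged every 30 min."""
        base = dict(frame_interval_min=30.0, duration_min=1440.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def death_defaults(cls, **overrides: Any) -> "SimConfig":
        """24-h Annexin-V death assay imaged every 30 min."""
        return cls.srxn1_defaults(**overrides)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, typ in (
            ("oscillation", OscillationParams),
            ("srxn1", Srxn1Params),
            ("death", DeathParams),
            ("deg", DegParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
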