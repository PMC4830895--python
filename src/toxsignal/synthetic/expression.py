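"""Synthetic differential-expression tables with planted block structure.

Emulates the contrast a hepatotoxicant screen shows: an Nrf2-target gene
block upregulated by oxidative-stress model compounds and by severe
hepatotoxicants, an inflammatory (NF-κB target) block upregulated by
cytokine model treatments but *down*regulated by the same hepatotoxicants,
and a null background.  Adjusted p-values are generated as a deterministic
monotone function of |log2FC|/noise with multiplicative jitter — this
module consumes, rather than reproduces, replicate-level expression fits.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from ..config import SimConfig
from ..datatypes import GroundTruth

__all__ = ["simulate_deg_table", "write_deg_table", "TREATMENTS"]

#: treatment label -> (class, severity tag)
TREATMENTS = {
    "control": ("control", "none"),
    "model_oxidative": ("model_oxidative", "model"),
    "model_inflammatory": ("model_inflammatory", "model"),
    "dili_severe": ("dili", "severe"),
    "dili_mild": ("dili", "mild"),
}


def _mean_lfc(block: str, treatment: str, p) -> float:
    if block == "nrf2_block":
        if treatment == "model_oxidative":
            return p.model_effect
        if treatment == "dili_severe":
            return p.effect_nrf2
        if treatment == "dili_mild":
            return p.effect_nrf2 * p.mild_scale
    elif block == "nfkb_block":
        if treatment == "model_inflammatory":
            return p.model_effect
        if treatment == "dili_severe":
            return -p.effect_nfkb
        if treatment == "dili_mild":
            return -p.effect_nfkb * p.mild_scale
    return 0.0


def simulate_deg_table(config: SimConfig) -> Tuple[pd.DataFrame, GroundTruth]:
    """Long-format table keyed (gene, treatment) with columns log2fc,
    adj_p, avg_expr, treatment_class, severity.  Deterministic per seed."""
    p = config.deg
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))

    genes, blocks = [], []
    for i in range(p.n_nrf2):
        genes.append(f"NRF2T{i:03d}")
        blocks.append("nrf2_block")
    for i in range(p.n_nfkb):
        genes.append(f"NFKBT{i:03d}")
        blocks.append("nfkb_block")
    for i in range(p.n_background):
        genes.append(f"BG{i:04d}")
        blocks.append("background")

    expr = np.where(
        np.asarray(blocks) == "background",
        rng.normal(p.background_expr_mean, p.background_expr_sd, len(genes)),
        rng.normal(p.block_expr_mean, p.block_expr_sd, len(genes)),
    )

    rows = []
    for treatment, (tclass, severity) in TREATMENTS.items():
        for g, b, e in zip(genes, blocks, expr):
            mu = _mean_lfc(b, treatment, p)
            lfc = mu + (rng.normal(0.0, p.lfc_noise_sd) if p.lfc_noise_sd > 0 else 0.0)
            if p.lfc_noise_sd > 0:
                z = abs(lfc) / p.lfc_noise_sd
                adj_p = 2.0 * norm.sf(z) * np.exp(rng.normal(0.0, 0.25))
            else:
                adj_p = 0.0 if abs(lfc) > 0 else 1.0
            adj_p = float(np.clip(adj_p, 1e-300, 1.0))
            rows.append((g, treatment, lfc, adj_p, e, tclass, severity))

    table = pd.DataFrame(
        rows,
        columns=["gene", "treatment", "log2fc", "adj_p", "avg_expr", "treatment_class", "severity"],
    )
    truth = GroundTruth(planted_gene_blocks=dict(zip(genes, blocks)))
    return table, truth


def write_deg_table(table: pd.DataFrame, path) -> None:
    """TSV with fixed float formatting, byte-identical across runs."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
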