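"""End-to-end orchestration: simulate, analyze and report runs.

Every run writes a ``manifest.json`` recording the configuration, seed,
package version and SHA-256 of each artifact, so that identical configs
are verifiably byte-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import SimConfig, save_config
from .datatypes import DeathCurve, RatioTrace, ReporterScore, TimeLapseStack
from .io import load_stack, save_stack
from .oscillation import (
    detect_peaks,
    extract_features,
    normalize_trace,
    peak_count_histogram,
    population_mean_trace,
)
from .reporter import (
    annexin_fraction,
    cell_area_from_transmission,
    death_auc,
    srxn1_score,
)
from .segmentation import estimate_background, segment_cytoplasm, segment_nuclei
from .synthetic import (
    render_p65_stack,
    simulate_death_series,
    simulate_deg_table,
    simulate_ratio_traces,
    simulate_srxn1_stack,
    write_deg_table,
)
from .tracking import measure_ratio, track_nuclei

logger = logging.getLogger(__name__)

ASSAYS = ("p65", "srxn1", "annexin", "genesets")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, config: Optional[SimConfig], seed: Optional[int]) -> Path:
    files = sorted(p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": None if config is None else config.to_dict(),
        "artifacts": {p.name: _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# simulate


def run_simulate(assay: str, config: SimConfig, out_dir: str | Path) -> Dict[str, Path]:
    """Generate one synthetic dataset plus ground truth and manifest."""
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; choose from {ASSAYS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}

    if assay == "p65":
        traces, truth = simulate_ratio_traces(config)
        stack = render_p65_stack(traces, config)
        save_stack(stack, out / "stack.tif")
        truth.to_json(out / "truth.json")
        pd.DataFrame(
            {
                "cell_id": np.repeat([t.cell_id for t in traces], len(traces[0].times)),
                "time_min": np.tile(traces[0].times, len(traces)),
                "ratio": np.concatenate([t.values for t in traces]),
            }
        ).to_csv(out / "traces.tsv", sep="\t", index=False, float_format="%.6g")
        artifacts = {"stack": out / "stack.tif", "truth": out / "truth.json"}
    elif assay == "srxn1":
        stack, truth = simulate_srxn1_stack(config)
        save_stack(stack, out / "stack.tif")
        truth.to_json(out / "truth.json")
        artifacts = {"stack": out / "stack.tif", "truth": out / "truth.json"}
    elif assay == "annexin":
        for label, with_tnf in (("drug", False), ("drug_tnf", True)):
            stack, truth = simulate_death_series(config, with_tnf=with_tnf)
            save_stack(stack, out / f"stack_{label}.tif")
            truth.to_json(out / f"truth_{label}.json")
            artifacts[label] = out / f"stack_{label}.tif"
    else:  # genesets
        table, truth = simulate_deg_table(config)
        write_deg_table(table, out / "deg_table.tsv")
        truth.to_json(out / "truth.json")
        blocks: Dict[str, List[str]] = {}
        for g, b in truth.planted_gene_blocks.items():
            blocks.setdefault(b, []).append(g)
        lines = [
            "\t".join([name, "synthetic", *genes])
            for name, genes in blocks.items()
            if name != "background"
        ]
        (out / "planted_sets.gmt").write_text("\n".join(lines) + "\n")
        artifacts = {"table": out / "deg_table.tsv", "truth": out / "truth.json"}

    save_config(config, out / "config.yaml")
    write_manifest(out, config, config.seed)
    return artifacts


# ---------------------------------------------------------------------------
# analyze


def analyze_p65_stack(
    stack: TimeLapseStack,
    min_area_px: int = 50,
    ring_width_px: int = 5,
    max_disp_px: float = 10.0,
    min_coverage: float = 0.8,
) -> List[RatioTrace]:
    """Segment, track and measure every cell in a p65 movie."""
    nuclei = stack.channel("nuclei")
    nucleus_labels = [segment_nuclei(frame, min_area_px=min_area_px) for frame in nuclei]
    cyto_labels = [segment_cytoplasm(lbl, ring_width_px) for lbl in nucleus_labels]
    tracks = track_nuclei(nucleus_labels, max_disp_px=max_disp_px, min_coverage=min_coverage)
    reporter = stack.channel("reporter")
    backgrounds = [
        estimate_background(reporter[f], nucleus_labels[f]) for f in range(stack.n_frames)
    ]
    traces = [
        measure_ratio(tr, stack, nucleus_labels, cyto_labels, backgrounds=backgrounds)
        for tr in tracks
    ]
    logger.info("analyze_p65_stack: %d tracks from %d frames", len(traces), stack.n_frames)
    return traces


def _frame_threshold(frame: np.ndarray, sigma: float = 5.0) -> float:
    """Photon-noise-aware 'above background' threshold: median + sigma·√median."""
    med = float(np.median(frame))
    return med + sigma * np.sqrt(max(med, 1.0))


def srxn1_series(stack: TimeLapseStack, min_blob_px: int = 45, sigma: float = 5.0) -> ReporterScore:
    """Per-frame Srxn1-GFP score, normalised to the segmented nucleus count."""
    reporter = stack.channel("reporter")
    nuclei = stack.channel("nuclei")
    scores, counts = [], []
    for f in range(stack.n_frames):
        labels = segment_nuclei(nuclei[f])
        n = max(int(labels.max()), 1)
        med = float(np.median(reporter[f]))
        scores.append(
            srxn1_score(
                reporter[f], med, n, min_blob_px=min_blob_px,
                threshold=_frame_threshold(reporter[f], sigma),
            )
        )
        counts.append(n)
    return ReporterScore(
        times=stack.times_min, score=np.asarray(scores), n_nuclei=np.asarray(counts)
    )


def death_series(stack: TimeLapseStack, sigma: float = 5.0) -> DeathCurve:
    """Annexin-V percent-positive curve, normalised to the transmission
    cell area of the first frame."""
    death = stack.channel("death")
    area = cell_area_from_transmission(stack.channel("transmission")[0])
    if area <= 0:
        raise ValueError("no cell area detected in transmission channel")
    pct = [
        annexin_fraction(death[f], area, _frame_threshold(death[f], sigma))
        for f in range(stack.n_frames)
    ]
    return DeathCurve(times_min=stack.times_min, percent_positive=np.asarray(pct))


def run_analyze(
    assay: str,
    inputs: Dict[str, Path],
    out_dir: str | Path,
    params: Optional[dict] = None,
) -> Dict[str, Path]:
    """Analyze one dataset; emits per-assay tables and figures."""
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; choose from {ASSAYS}")
    params = params or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    if assay == "p65":
        stack = load_stack(inputs["stack"])
        traces = analyze_p65_stack(stack, **{k: params[k] for k in params
                                             if k in ("min_area_px", "ring_width_px",
                                                      "max_disp_px", "min_coverage")})
        feats, normed = [], []
        for tr in traces:
            nt = normalize_trace(tr)
            normed.append(nt)
            feats.append(extract_features(nt, detect_peaks(nt)))
        summary = peak_count_histogram(feats)
        (out / "features.json").write_text(json.dumps([
            {
                "cell_id": tr.cell_id,
                "n_peaks": f.n_peaks,
                "peak_times_min": list(map(float, f.peak_times_min)),
                "delay_p1_p2_min": f.delay_p1_p2_min,
                "entry_rate": f.entry_rate,
                "exit_rate": f.exit_rate,
            }
            for tr, f in zip(traces, feats)
        ], indent=1))
        pd.DataFrame(
            {
                "n_peaks_class": list(range(6)),
                "n_cells": summary.histogram,
            }
        ).assign(
            frac_three_plus=summary.frac_three_plus,
            mean_delay_p1_p2_min=summary.mean_delay_p1_p2_min,
            mean_second_peak_min=summary.mean_second_peak_min,
        ).to_csv(out / "population.tsv", sep="\t", index=False)
        if normed:
            from .plots import plot_mean_trace

            t, v = population_mean_trace(normed)
            plot_mean_trace(t, v).savefig(out / "mean_trace.png", dpi=120)
        written = {"features": out / "features.json", "population": out / "population.tsv"}
    elif assay == "srxn1":
        stack = load_stack(inputs["stack"])
        score = srxn1_series(stack, **{k: params[k] for k in params if k in ("min_blob_px", "sigma")})
        pd.DataFrame(
            {"time_min": score.times, "score": score.score, "n_nuclei": score.n_nuclei}
        ).to_csv(out / "score.tsv", sep="\t", index=False, float_format="%.6g")
        written = {"score": out / "score.tsv"}
    elif assay == "annexin":
        rows = {}
        for label in ("drug", "drug_tnf"):
            key = "stack" if label == "drug" and "stack" in inputs else label
            if key not in inputs:
                continue
            curve = death_series(load_stack(inputs[key]))
            pd.DataFrame(
                {"time_min": curve.times_min, "percent_positive": curve.percent_positive}
            ).to_csv(out / f"death_curve_{label}.tsv", sep="\t", index=False, float_format="%.6g")
            rows[label] = curve
            written[label] = out / f"death_curve_{label}.tsv"
        summary = {
            label: {"end_percent": float(c.percent_positive[-1]), "auc": death_auc(c)}
            for label, c in rows.items()
        }
        if {"drug", "drug_tnf"} <= set(rows):
            from .reporter import tnf_synergy

            summary["synergy_percent_points"] = tnf_synergy(
                rows["drug"].percent_positive[-1], rows["drug_tnf"].percent_positive[-1]
            )
        (out / "death_summary.json").write_text(json.dumps(summary, indent=1))
        written["summary"] = out / "death_summary.json"
    else:  # genesets
        from .genesets import (
            FilterSpec,
            cluster_heatmap,
            enrich_catalog,
            filter_responsive,
            load_deg_table,
            read_gmt,
            union_catalog,
        )

        table = load_deg_table(inputs["table"])
        if table.empty:
            logger.warning("empty DEG table; writing empty outputs")
            (out / "enrichment.tsv").write_text("")
            written = {"enrichment": out / "enrichment.tsv"}
            write_manifest(out, None, None)
            return written
        catalog = read_gmt(inputs["gmt"]) if "gmt" in inputs else None
        treatments = sorted(table["treatment"].unique())
        model_subset = params.get(
            "model_subset",
            [t for t in treatments if t.startswith("model_")] or treatments,
        )
        universe = sorted(table["gene"].unique())
        if catalog is not None:
            genes, _ = union_catalog([catalog])
        else:
            genes = universe
        spec = FilterSpec(
            abs_lfc_min_log2=params.get("abs_lfc_min", 1.5), model_subset=model_subset
        )
        survivors = filter_responsive(table, genes, spec)
        (out / "filtered_genes.txt").write_text("\n".join(survivors) + "\n")
        if survivors:
            result = cluster_heatmap(table, survivors, treatments,
                                     k_genes=params.get("k_genes", 2))
            result.matrix.to_csv(out / "clustered_matrix.tsv", sep="\t", float_format="%.6g")
            (out / "orders.json").write_text(json.dumps(
                {
                    "gene_order": result.gene_order,
                    "treatment_order": result.treatment_order,
                    "gene_labels": result.gene_labels,
                }, indent=1))
            from .plots import plot_heatmap

            plot_heatmap(result).savefig(out / "heatmap.png", dpi=120)
        if catalog is not None:
            treatment = params.get("enrich_treatment", treatments[0])
            selected = select_genes = None
            from .genesets import select_deg

            selected = select_deg(table, treatment)
            df = enrich_catalog(selected, catalog, universe, table=table, treatment=treatment)
            df.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
            from .plots import plot_enrichment_bars

            plot_enrichment_bars(df).savefig(out / "enrichment.png", dpi=120)
            written["enrichment"] = out / "enrichment.tsv"
        written["filtered"] = out / "filtered_genes.txt"

    write_manifest(out, None, None)
    return written


# ---------------------------------------------------------------------------
# report


def run_report(result_dirs: Sequence[str | Path], out_path: str | Path) -> pd.DataFrame:
    """Combine per-condition analysis outputs into one summary table.

    One row per directory with Srxn1 fold metrics, oscillation delay and
    death percentages where available; metrics whose inputs are missing
    are reported as NA, never fabricated.
    """
    rows = []
    for d in result_dirs:
        d = Path(d)
        row: Dict[str, object] = {"condition": d.name}
        pop = d / "population.tsv"
        if pop.exists():
            df = pd.read_csv(pop, sep="\t")
            row["mean_delay_p1_p2_min"] = df["mean_delay_p1_p2_min"].iloc[0]
            row["mean_second_peak_min"] = df["mean_second_peak_min"].iloc[0]
        score = d / "score.tsv"
        if score.exists():
            df = pd.read_csv(score, sep="\t")
            row["srxn1_end_score"] = df["score"].iloc[-1]
        summ = d / "death_summary.json"
        if summ.exists():
            s = json.loads(summ.read_text())
            if "drug" in s:
                row["pct_dead"] = s["drug"]["end_percent"]
                row["death_auc"] = s["drug"]["auc"]
            if "drug_tnf" in s:
                row["pct_dead_tnf"] = s["drug_tnf"]["end_percent"]
            if "synergy_percent_points" in s:
                row["synergy_percent_points"] = s["synergy_percent_points"]
        rows.append(row)
    report = pd.DataFrame(rows)
    report.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return report
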