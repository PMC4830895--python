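"""Gene-set assembly, responsiveness filtering, Manhattan/Ward clustering
and Fisher-exact pathway enrichment.

The transcriptomics arm consumes precomputed per-(gene, treatment)
differential-expression statistics (log2 fold change, BH-adjusted p,
average log2 expression).  Candidate oxidative-stress and inflammatory
gene sets are unioned across annotation catalogs, filtered for
responsiveness under model stimuli (p ≤ 0.05, average expression ≥ 5
log2, |log2FC| ≥ 1.5 for oxidative / 2.0 for inflammatory), and the
resulting fold-change matrix is clustered with Ward linkage on Manhattan
distances.  Pathway over-representation uses the right-tailed Fisher
exact (hypergeometric upper-tail) test, reported as −log10 p together
with the mean |log2FC| of the contributing genes and its mean direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCatalog",
    "FilterSpec",
    "ClusterResult",
    "EnrichmentEntry",
    "CATEGORY_LFC_MIN",
    "read_gmt",
    "write_gmt",
    "union_catalog",
    "validate_deg_table",
    "load_deg_table",
    "filter_responsive",
    "select_deg",
    "fisher_enrichment",
    "enrich_catalog",
    "mean_fc_vector",
    "cluster_heatmap",
    "threshold_sweep",
]

#: published minimum |log2FC| per gene-set category
CATEGORY_LFC_MIN = {"oxidative": 1.5, "inflammatory": 2.0}


@dataclass
class GeneSetCatalog:
    """Named gene sets from one annotation source (sets may overlap)."""

    sets: Dict[str, List[str]]
    source: str = "unknown"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if any(not isinstance(g, str) or not g for g in genes):
                raise ValueError(f"set {name!r} contains empty gene names")


@dataclass
class FilterSpec:
    """Responsiveness filter thresholds (all comparisons inclusive)."""

    adj_p_max: float = 0.05
    avg_expr_min_log2: float = 5.0
    abs_lfc_min_log2: float = 1.5
    model_subset: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.adj_p_max, self.avg_expr_min_log2, self.abs_lfc_min_log2) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def for_category(cls, category: str, model_subset: Sequence[str]) -> "FilterSpec":
        return cls(
            abs_lfc_min_log2=CATEGORY_LFC_MIN[category],
            model_subset=list(model_subset),
        )


@dataclass
class ClusterResult:
    gene_order: List[str]
    treatment_order: List[str]
    gene_linkage: np.ndarray
    treatment_linkage: np.ndarray
    gene_labels: Dict[str, int]
    treatment_labels: Dict[str, int]
    matrix: pd.DataFrame  # genes × treatments log2FC, in clustered order


@dataclass
class EnrichmentEntry:
    pathway: str
    overlap: List[str]
    p_value: float
    neg_log10_p: float
    overlap_count: int
    pathway_size: int


# ---------------------------------------------------------------------------
# catalogs


def read_gmt(path: str | Path, source: Optional[str] = None) -> GeneSetCatalog:
    """Read a GMT file (set name, description, then member genes, tab
    separated, one set per line)."""
    sets: Dict[str, List[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCatalog(sets=sets, source=source or Path(path).stem)


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    lines = [
        "\t".join([name, catalog.source, *genes])
        for name, genes in catalog.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def union_catalog(
    catalogs: Sequence[GeneSetCatalog], category: str = ""
) -> Tuple[List[str], Dict[str, List[str]]]:
    """Deduplicated union of all member genes with per-gene source tags.

    Returns the sorted gene list and a gene → sorted source-list map; a
    gene contributed by several catalogs carries every source.
    """
    provenance: Dict[str, set] = {}
    for cat in catalogs:
        for genes in cat.sets.values():
            for g in genes:
                provenance.setdefault(g, set()).add(cat.source)
    genes = sorted(provenance)
    logger.info("union_catalog(%s): %d unique genes from %d catalogs",
                category or "-", len(genes), len(catalogs))
    return genes, {g: sorted(s) for g, s in provenance.items()}


# ---------------------------------------------------------------------------
# differential-expression tables


def validate_deg_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "treatment", "log2fc", "adj_p", "avg_expr"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["gene", "treatment"]).any():
        raise ValueError("duplicate (gene, treatment) keys")
    if ((table["adj_p"] < 0) | (table["adj_p"] > 1)).any():
        raise ValueError("adj_p outside [0, 1]")
    return table


def load_deg_table(path: str | Path) -> pd.DataFrame:
    return validate_deg_table(pd.read_csv(path, sep="\t"))


def filter_responsive(
    table: pd.DataFrame, genes: Sequence[str], spec: FilterSpec
) -> List[str]:
    """Genes responsive under at least one model treatment.

    A gene survives iff some treatment in ``spec.model_subset`` shows
    adj_p ≤ adj_p_max AND avg_expr ≥ avg_expr_min AND |log2fc| ≥
    abs_lfc_min (inclusive bounds).  Query genes absent from the table are
    dropped with a warning.
    """
    validate_deg_table(table)
    present = set(table["gene"])
    missing = [g for g in genes if g not in present]
    if missing:
        logger.warning("filter_responsive: %d query genes absent from table", len(missing))
    sub = table[
        table["gene"].isin(set(genes) & present)
        & table["treatment"].isin(spec.model_subset)
    ]
    if sub.empty and spec.model_subset:
        if not set(spec.model_subset) & set(table["treatment"]):
            raise ValueError("model_subset treatments not present in table")
    ok = sub[
        (sub["adj_p"] <= spec.adj_p_max)
        & (sub["avg_expr"] >= spec.avg_expr_min_log2)
        & (sub["log2fc"].abs() >= spec.abs_lfc_min_log2)
    ]
    survivors = sorted(set(ok["gene"]))
    logger.info("filter_responsive: %d/%d genes pass", len(survivors), len(set(genes) & present))
    return survivors


def select_deg(
    table: pd.DataFrame,
    treatment: str,
    abs_lfc_min: float = 1.3,
    adj_p_max: float = 0.05,
    avg_expr_min: float = 7.0,
) -> List[str]:
    """Differentially expressed genes for one treatment (inclusive
    thresholds on |log2FC|, adjusted p and average expression)."""
    validate_deg_table(table)
    sub = table[table["treatment"] == treatment]
    ok = sub[
        (sub["log2fc"].abs() >= abs_lfc_min)
        & (sub["adj_p"] <= adj_p_max)
        & (sub["avg_expr"] >= avg_expr_min)
    ]
    return sorted(set(ok["gene"]))


# ---------------------------------------------------------------------------
# enrichment


def fisher_enrichment(
    selected: Sequence[str], pathway: Sequence[str], universe: Sequence[str],
    name: str = "",
) -> EnrichmentEntry:
    """Right-tailed Fisher exact (hypergeometric upper tail) pathway test.

    p = P(X ≥ k) for k = |selected ∩ pathway| when drawing |selected|
    genes from the universe containing |pathway ∩ universe| successes.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected)
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    path_eff = set(pathway) & uni
    overlap = sorted(sel & path_eff)
    k = len(overlap)
    # P(X >= k) == sf(k - 1)
    p = float(hypergeom.sf(k - 1, len(uni), len(path_eff), len(sel)))
    p = min(max(p, 5e-324), 1.0)
    return EnrichmentEntry(
        pathway=name,
        overlap=overlap,
        p_value=p,
        neg_log10_p=float(-np.log10(p)),
        overlap_count=k,
        pathway_size=len(path_eff),
    )


def enrich_catalog(
    selected: Sequence[str],
    catalog: GeneSetCatalog,
    universe: Sequence[str],
    table: Optional[pd.DataFrame] = None,
    treatment: Optional[str] = None,
) -> pd.DataFrame:
    """Enrichment of every set in a catalog, with BH q-values and, when a
    DEG table is supplied, the mean fold-change arrow (magnitude and
    direction) of the contributing genes."""
    entries = [
        fisher_enrichment(selected, genes, universe, name=name)
        for name, genes in catalog.sets.items()
    ]
    df = pd.DataFrame(
        {
            "pathway": [e.pathway for e in entries],
            "p_value": [e.p_value for e in entries],
            "neg_log10_p": [e.neg_log10_p for e in entries],
            "overlap_count": [e.overlap_count for e in entries],
            "pathway_size": [e.pathway_size for e in entries],
            "overlap_genes": [",".join(e.overlap) for e in entries],
        }
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    if table is not None and treatment is not None:
        mags, dirs = [], []
        for e in entries:
            m, d = mean_fc_vector(e.overlap, table, treatment)
            mags.append(m)
            dirs.append(d)
        df["mean_abs_lfc"] = mags
        df["direction"] = dirs
    return df.sort_values("p_value", ignore_index=True)


def mean_fc_vector(
    overlap: Sequence[str], table: pd.DataFrame, treatment: str
) -> Tuple[float, int]:
    """Arrow vector for a pathway: (mean |log2FC| over the contributing
    genes, sign of the mean signed log2FC).  Direction 0 means balanced
    up/down regulation (drawn flat)."""
    sub = table[(table["treatment"] == treatment) & (table["gene"].isin(set(overlap)))]
    if sub.empty:
        return 0.0, 0
    lfc = sub["log2fc"].to_numpy()
    return float(np.abs(lfc).mean()), int(np.sign(lfc.mean()))


# ---------------------------------------------------------------------------
# clustering


def cluster_heatmap(
    table: pd.DataFrame,
    genes: Sequence[str],
    treatments: Sequence[str],
    k_genes: int = 2,
    k_treatments: int = 2,
    metric: str = "cityblock",
    method: str = "ward",
) -> ClusterResult:
    """Bi-directional hierarchical clustering of the log2FC matrix.

    Rows (genes) and columns (treatments) are clustered independently with
    Ward linkage on Manhattan (cityblock) distances; a Euclidean metric is
    available via ``metric``.  Missing (gene, treatment) entries are
    imputed as 0 with a warning — only for clustering, never for
    filtering.
    """
    validate_deg_table(table)
    mat = table.pivot(index="gene", columns="treatment", values="log2fc")
    mat = mat.reindex(index=list(genes), columns=list(treatments))
    if mat.isna().any().any():
        logger.warning(
            "cluster_heatmap: imputing %d missing fold changes as 0",
            int(mat.isna().to_numpy().sum()),
        )
        mat = mat.fillna(0.0)

    def _cluster(m: np.ndarray, k: int):
        if m.shape[0] < 2:
            return np.empty((0, 4)), np.arange(m.shape[0]), np.ones(m.shape[0], int)
        z = linkage(pdist(m, metric=metric), method=method)
        order = leaves_list(z)
        labels = fcluster(z, t=min(k, m.shape[0]), criterion="maxclust")
        return z, order, labels

    zg, og, lg = _cluster(mat.to_numpy(), k_genes)
    zt, ot, lt = _cluster(mat.to_numpy().T, k_treatments)

    gene_order = [mat.index[i] for i in og]
    treatment_order = [mat.columns[i] for i in ot]
    return ClusterResult(
        gene_order=gene_order,
        treatment_order=treatment_order,
        gene_linkage=zg,
        treatment_linkage=zt,
        gene_labels=dict(zip(mat.index, map(int, lg))),
        treatment_labels=dict(zip(mat.columns, map(int, lt))),
        matrix=mat.loc[gene_order, treatment_order],
    )


def threshold_sweep(
    table: pd.DataFrame,
    genes: Sequence[str],
    spec: FilterSpec,
    lfc_values: Sequence[float],
) -> pd.DataFrame:
    """Survivor counts across a range of |log2FC| thresholds — utility for
    matching gene-set sizes between categories."""
    rows = []
    for v in lfc_values:
        s = FilterSpec(
            adj_p_max=spec.adj_p_max,
            avg_expr_min_log2=spec.avg_expr_min_log2,
            abs_lfc_min_log2=v,
            model_subset=spec.model_subset,
        )
        rows.append((v, len(filter_responsive(table, genes, s))))
    return pd.DataFrame(rows, columns=["abs_lfc_min", "n_genes"])
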