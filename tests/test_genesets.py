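"""Gene-set union, responsiveness filtering, enrichment and clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hypergeom_tail
from toxsignal import SimConfig
from toxsignal.genesets import (
    FilterSpec,
    GeneSetCatalog,
    cluster_heatmap,
    fisher_enrichment,
    filter_responsive,
    mean_fc_vector,
    read_gmt,
    select_deg,
    threshold_sweep,
    union_catalog,
    write_gmt,
)
from toxsignal.synthetic import simulate_deg_table


def _table(rows):
    """rows: (gene, treatment, log2fc, adj_p, avg_expr)"""
    return pd.DataFrame(rows, columns=["gene", "treatment", "log2fc", "adj_p", "avg_expr"])


class TestUnionCatalog:
    def test_disjoint_sets_concatenate(self):
        a = GeneSetCatalog({"s1": ["A", "B", "C"]}, source="db1")
        b = GeneSetCatalog({"s2": ["D", "E", "F", "G"]}, source="db2")
        genes, _ = union_catalog([a, b])
        assert len(genes) == 7

    def test_identical_sets_collapse(self):
        a = GeneSetCatalog({"s": ["A", "B"]}, source="db1")
        genes, _ = union_catalog([a, a])
        assert genes == ["A", "B"]

    def test_overlap_carries_both_sources(self):
        a = GeneSetCatalog({"s": ["A", "B", "C"]}, source="db1")
        b = GeneSetCatalog({"s": ["B", "C", "D"]}, source="db2")
        genes, prov = union_catalog([a, b])
        assert genes == ["A", "B", "C", "D"]
        assert prov["B"] == ["db1", "db2"] and prov["C"] == ["db1", "db2"]
        assert prov["A"] == ["db1"] and prov["D"] == ["db2"]

    def test_gmt_round_trip(self, tmp_path):
        cat = GeneSetCatalog({"ox": ["NFE2L2", "SRXN1"], "infl": ["RELA", "CXCL1", "CCL2"]},
                             source="toy")
        write_gmt(cat, tmp_path / "toy.gmt")
        back = read_gmt(tmp_path / "toy.gmt", source="toy")
        assert back.sets == cat.sets


class TestFilterResponsive:
    TOY = _table([
        # passes all three oxidative thresholds in a model treatment
        ("g1", "model_ox", 1.6, 0.04, 6.0),
        # fails p only
        ("g2", "model_ox", 3.0, 0.06, 9.0),
        # fails expression only
        ("g3", "model_ox", 2.0, 0.01, 4.0),
        # fails |lfc| only
        ("g4", "model_ox", 1.4, 0.01, 8.0),
        # passes via the second model treatment, negative fold change
        ("g5", "model_ox", 0.1, 0.9, 8.0),
        ("g5", "model_bha", -1.5, 0.05, 5.0),
        # passes only outside the model subset -> dropped
        ("g6", "dili_a", 4.0, 0.001, 9.0),
        ("g6", "model_ox", 0.2, 0.8, 9.0),
    ])

    def test_hand_applied_thresholds(self):
        spec = FilterSpec(abs_lfc_min_log2=1.5, model_subset=["model_ox", "model_bha"])
        survivors = filter_responsive(self.TOY, [f"g{i}" for i in range(1, 7)], spec)
        assert survivors == ["g1", "g5"]

    def test_boundary_values_inclusive(self):
        t = _table([("g", "m", 1.5, 0.05, 5.0)])
        spec = FilterSpec(abs_lfc_min_log2=1.5, model_subset=["m"])
        assert filter_responsive(t, ["g"], spec) == ["g"]

    def test_absent_genes_dropped_with_warning(self, caplog):
        spec = FilterSpec(model_subset=["model_ox"])
        with caplog.at_level("WARNING"):
            out = filter_responsive(self.TOY, ["g1", "nope"], spec)
        assert "absent" in caplog.text
        assert out == ["g1"]

    @given(
        p=st.floats(0.001, 0.2), e=st.floats(1.0, 9.0), l=st.floats(0.5, 3.0),
        dp=st.floats(0.0, 0.1), de=st.floats(0.0, 3.0), dl=st.floats(0.0, 1.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_raising_any_threshold_never_adds_survivors(self, p, e, l, dp, de, dl):
        genes = [f"g{i}" for i in range(1, 7)]
        loose = FilterSpec(adj_p_max=p + dp, avg_expr_min_log2=e,
                           abs_lfc_min_log2=l, model_subset=["model_ox", "model_bha"])
        tight = FilterSpec(adj_p_max=p, avg_expr_min_log2=e + de,
                           abs_lfc_min_log2=l + dl, model_subset=["model_ox", "model_bha"])
        assert set(filter_responsive(self.TOY, genes, tight)) <= set(
            filter_responsive(self.TOY, genes, loose))

    def test_threshold_sweep_counts_monotone(self):
        spec = FilterSpec(model_subset=["model_ox", "model_bha"])
        sweep = threshold_sweep(self.TOY, [f"g{i}" for i in range(1, 7)], spec,
                                [0.5, 1.0, 1.5, 2.0, 3.0])
        counts = sweep["n_genes"].tolist()
        assert counts == sorted(counts, reverse=True)


class TestSelectDeg:
    def test_exact_boundary_kept(self):
        t = _table([("g", "trt", 1.3, 0.05, 7.0)])
        assert select_deg(t, "trt") == ["g"]

    def test_negative_fold_change_uses_absolute_value(self):
        t = _table([("g", "trt", -1.4, 0.01, 8.0)])
        assert select_deg(t, "trt") == ["g"]

    def test_empty_table_gives_empty_list(self):
        assert select_deg(_table([]), "trt") == []


class TestFisher:
    def test_zero_overlap_is_p_one(self):
        uni = [f"u{i}" for i in range(50)]
        e = fisher_enrichment(uni[:5], uni[40:], uni)
        assert e.p_value == 1.0
        assert e.neg_log10_p == 0.0

    def test_pathway_equals_universe_is_p_one(self):
        uni = [f"u{i}" for i in range(30)]
        assert fisher_enrichment(uni[:7], uni, uni).p_value == pytest.approx(1.0)

    def test_worked_hypergeometric_sum(self):
        uni = [f"u{i}" for i in range(100)]
        pathway = uni[:20]
        selected = uni[:5] + uni[50:55]  # overlap 5
        e = fisher_enrichment(selected, pathway, uni)
        assert e.overlap_count == 5
        assert e.p_value == pytest.approx(hypergeom_tail(5, 100, 20, 10), rel=1e-12)

    def test_matches_combinatorial_oracle_on_random_instances(self, rng):
        for _ in range(200):
            m = int(rng.integers(5, 201))
            uni = [f"u{i}" for i in range(m)]
            n_path = int(rng.integers(1, m + 1))
            n_sel = int(rng.integers(1, m + 1))
            pathway = list(rng.choice(uni, size=n_path, replace=False))
            selected = list(rng.choice(uni, size=n_sel, replace=False))
            e = fisher_enrichment(selected, pathway, uni)
            k = len(set(selected) & set(pathway))
            assert e.p_value == pytest.approx(
                hypergeom_tail(k, m, n_path, n_sel), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], [], [])

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["x"], ["a"], ["a", "b"])

    def test_planted_block_beats_random_sets(self):
        """The planted Nrf2-up block is more enriched among severe-DILI
        DEGs than ≥95 % of random same-size gene sets."""
        table, truth = simulate_deg_table(SimConfig(seed=13))
        universe = sorted(set(table["gene"]))
        selected = select_deg(table, "dili_severe")
        planted = sorted(g for g, b in truth.planted_gene_blocks.items()
                         if b == "nrf2_block")
        p_planted = fisher_enrichment(selected, planted, universe).p_value
        rng = np.random.default_rng(99)
        wins = sum(
            p_planted
            < fisher_enrichment(
                selected, list(rng.choice(universe, len(planted), replace=False)),
                universe).p_value
            for _ in range(100)
        )
        assert wins >= 95


class TestMeanFcVector:
    TRT = "t"

    def _tab(self, lfcs):
        return _table([(f"g{i}", self.TRT, v, 0.01, 8.0) for i, v in enumerate(lfcs)])

    def test_two_up_genes(self):
        mag, d = mean_fc_vector(["g0", "g1"], self._tab([2.0, 2.0]), self.TRT)
        assert (mag, d) == (2.0, 1)

    def test_balanced_up_down_is_flat(self):
        mag, d = mean_fc_vector(["g0", "g1"], self._tab([2.0, -2.0]), self.TRT)
        assert (mag, d) == (2.0, 0)

    def test_two_down_genes(self):
        mag, d = mean_fc_vector(["g0", "g1"], self._tab([-1.0, -3.0]), self.TRT)
        assert (mag, d) == (2.0, -1)


class TestClustering:
    def test_manhattan_merge_height_of_two_rows(self):
        rows = []
        for trt, a, b in (("t1", 1.0, 2.0), ("t2", 2.0, 2.0), ("t3", 3.0, 5.0)):
            rows += [("gA", trt, a, 0.01, 8.0), ("gB", trt, b, 0.01, 8.0)]
        res = cluster_heatmap(_table(rows), ["gA", "gB"], ["t1", "t2", "t3"])
        # |1-2| + |2-2| + |3-5| = 3
        assert res.gene_linkage[0, 2] == pytest.approx(3.0)

    def test_identical_rows_merge_first_at_zero(self):
        rows = []
        for trt in ("t1", "t2"):
            for g in ("gA", "gB"):
                rows.append((g, trt, 1.5, 0.01, 8.0))
            rows.append(("gC", trt, -4.0, 0.01, 8.0))
        res = cluster_heatmap(_table(rows), ["gA", "gB", "gC"], ["t1", "t2"], k_genes=2)
        assert res.gene_linkage[0, 2] == 0.0
        assert res.gene_labels["gA"] == res.gene_labels["gB"] != res.gene_labels["gC"]

    def test_planted_two_block_table_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = SimConfig(seed=14)
        cfg.deg.lfc_noise_sd = 0.0
        table, truth = simulate_deg_table(cfg)
        planted = [g for g, b in truth.planted_gene_blocks.items() if b != "background"]
        res = cluster_heatmap(table, planted, sorted(set(table["treatment"])), k_genes=2)
        pred = [res.gene_labels[g] for g in planted]
        true = [truth.planted_gene_blocks[g] for g in planted]
        assert adjusted_rand_score(true, pred) == 1.0

    def test_row_permutation_invariance(self):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        table, truth = simulate_deg_table(SimConfig(seed=15))
        genes = sorted(truth.planted_gene_blocks)[:40]
        trts = sorted(set(table["treatment"]))
        a = cluster_heatmap(table, genes, trts)
        shuffled = list(reversed(genes))
        b = cluster_heatmap(table, shuffled, trts)
        ca = pd.DataFrame(squareform(cophenet(a.gene_linkage)), index=genes, columns=genes)
        cb = pd.DataFrame(squareform(cophenet(b.gene_linkage)), index=shuffled,
                          columns=shuffled)
        np.testing.assert_allclose(ca.loc[genes, genes], cb.loc[genes, genes])

    def test_missing_entries_imputed_with_warning(self, caplog):
        rows = [("gA", "t1", 1.0, 0.01, 8.0), ("gB", "t1", 2.0, 0.01, 8.0),
                ("gA", "t2", 1.0, 0.01, 8.0)]
        with caplog.at_level("WARNING"):
            res = cluster_heatmap(_table(rows), ["gA", "gB"], ["t1", "t2"])
        assert "imputing" in caplog.text
        assert res.matrix.loc["gB", "t2"] == 0.0
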