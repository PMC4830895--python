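"""Synthetic-data generators: construction inverses, determinism, truth."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk

from conftest import flood_fill_count
from toxsignal import SimConfig
from toxsignal.datatypes import RatioTrace
from toxsignal.genesets import FilterSpec, filter_responsive
from toxsignal.synthetic import (
    draw_death_times,
    render_p65_stack,
    simulate_death_series,
    simulate_deg_table,
    simulate_ratio_traces,
    simulate_srxn1_stack,
    srxn1_trajectories,
    write_deg_table,
)


def _noiseless(n_cells=5, **osc):
    cfg = SimConfig(seed=0, n_cells=n_cells, noise_sd=0.0)
    cfg.oscillation.desync_sd_min = 0.0
    for k, v in osc.items():
        setattr(cfg.oscillation, k, v)
    return cfg


class TestRatioTraces:
    def test_noiseless_truth_peaks_at_nominal_times(self):
        traces, truth = simulate_ratio_traces(_noiseless())
        for peaks in truth.per_cell_peak_times_min:
            assert peaks == [30.0, 150.0, 270.0]
        # trace maxima coincide with the truth on the sampled grid
        tr = traces[0]
        assert tr.times[np.argmax(tr.values)] == 30.0

    def test_treatment_delay_shifts_all_peaks_after_first(self):
        traces, truth = simulate_ratio_traces(_noiseless(treatment_delay_min=26.0))
        for peaks in truth.per_cell_peak_times_min:
            assert peaks == [30.0, 176.0, 296.0]

    def test_same_seed_reproduces_traces_and_truth(self):
        cfg = SimConfig(seed=42, n_cells=20)
        a, ta = simulate_ratio_traces(cfg)
        b, tb = simulate_ratio_traces(SimConfig(seed=42, n_cells=20))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)
        assert ta.per_cell_peak_times_min == tb.per_cell_peak_times_min

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(noise_sd=float("nan"))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_truth_peak_times_strictly_increasing_within_duration(self, seed):
        cfg = SimConfig(seed=seed, n_cells=3)
        _, truth = simulate_ratio_traces(cfg)
        for peaks in truth.per_cell_peak_times_min:
            assert all(b > a for a, b in zip(peaks, peaks[1:]))
            assert all(0 <= p <= cfg.duration_min for p in peaks)


class TestP65Rendering:
    def test_rendered_disk_ring_ratio_matches_trace(self):
        cfg = SimConfig(seed=0, n_cells=1, image_size=128, duration_min=6,
                        background_level=0.0, noise_sd=0.0)
        trace = RatioTrace(cell_id=0, times=cfg.times_min, values=np.full(2, 2.0))
        center = np.array([[64.0, 64.0]])
        stack = render_p65_stack([trace], cfg, noise=False, centers=center)
        rep = stack.channel("reporter")[0].astype(float)
        shape = rep.shape
        rr_n, cc_n = draw_disk((64, 64), cfg.nucleus_radius_px, shape=shape)
        nucleus = np.zeros(shape, bool)
        nucleus[rr_n, cc_n] = True
        rr_o, cc_o = draw_disk((64, 64), cfg.nucleus_radius_px + cfg.ring_width_px, shape=shape)
        ring = np.zeros(shape, bool)
        ring[rr_o, cc_o] = True
        ring &= ~nucleus
        ratio = rep[nucleus].mean() / rep[ring].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_zero_cells_gives_blank_stack(self):
        cfg = SimConfig(seed=0, n_cells=0, image_size=64, duration_min=6, noise_sd=0.0)
        stack = render_p65_stack([], cfg, noise=False)
        assert np.all(stack.frames == cfg.background_level)

    def test_component_count_matches_flood_fill_oracle(self):
        cfg = SimConfig(seed=7, n_cells=25, image_size=512, duration_min=6, noise_sd=0.0)
        traces, _ = simulate_ratio_traces(cfg)
        stack = render_p65_stack(traces, cfg, noise=False)
        for f in (0, stack.n_frames - 1):
            mask = stack.channel("nuclei")[f] > cfg.background_level
            assert flood_fill_count(mask) == 25

    def test_cells_exceeding_image_bounds_rejected(self):
        cfg = SimConfig(seed=0, n_cells=1, image_size=64, duration_min=6)
        trace = RatioTrace(cell_id=0, times=cfg.times_min, values=np.ones(2))
        with pytest.raises(ValueError, match="bounds"):
            render_p65_stack([trace], cfg, centers=np.array([[2.0, 2.0]]))
        big = SimConfig(seed=0, n_cells=500, image_size=64, duration_min=6)
        tr, _ = simulate_ratio_traces(big)
        with pytest.raises(ValueError):
            render_p65_stack(tr, big)


class TestSrxn1Stack:
    def test_onset_beyond_duration_is_background(self):
        cfg = SimConfig.srxn1_defaults(seed=1, n_cells=4, image_size=256,
                                       duration_min=240, noise_sd=0.0)
        cfg.srxn1.onset_min = 10_000.0
        cfg.srxn1.onset_sd_min = 0.0
        stack, _ = simulate_srxn1_stack(cfg, noise=False)
        assert np.all(stack.channel("reporter") == cfg.background_level)

    def test_endframe_qualifying_area_equals_cell_area(self):
        cfg = SimConfig.srxn1_defaults(seed=1, n_cells=1, image_size=128,
                                       duration_min=1440)
        cfg.srxn1.onset_min = 200.0
        cfg.srxn1.onset_sd_min = 0.0
        stack, truth = simulate_srxn1_stack(cfg, noise=False)
        (cr, cc0) = truth.cell_centers[0]
        rr, cc = draw_disk((cr, cc0), 2 * cfg.nucleus_radius_px, shape=(128, 128))
        end = stack.channel("reporter")[-1]
        assert int(np.sum(end > cfg.background_level)) == len(rr)

    def test_onset_groups_recovered_from_truth_half_rise(self):
        recovered = []
        for onset in (240.0, 960.0):
            cfg = SimConfig.srxn1_defaults(seed=5, n_cells=50)
            cfg.srxn1.onset_min = onset
            cfg.srxn1.onset_sd_min = 30.0
            traj, _ = srxn1_trajectories(cfg, np.random.default_rng(5))
            t = cfg.times_min
            half = cfg.srxn1.plateau / 2.0
            half_rise = [t[np.argmin(np.abs(row - half))] for row in traj]
            recovered.append(np.mean(half_rise))
        assert abs(recovered[0] - 240.0) <= 30.0
        assert abs(recovered[1] - 960.0) <= 30.0


class TestDeathSeries:
    def test_zero_hazard_means_no_positive_pixels(self):
        cfg = SimConfig.death_defaults(seed=2, n_cells=6, image_size=256,
                                       duration_min=120)
        cfg.death.baseline_hazard_per_h = 0.0
        stack, truth = simulate_death_series(cfg, with_tnf=True, noise=False)
        assert all(t is None for t in truth.per_cell_death_time_min)
        assert np.all(stack.channel("death") == cfg.background_level)

    def test_unit_multiplier_arms_statistically_indistinguishable(self):
        cfg = SimConfig.death_defaults(seed=3, n_cells=500)
        cfg.death.baseline_hazard_per_h = 0.05
        cfg.death.tnf_multiplier = 1.0
        d0 = draw_death_times(cfg, False, np.random.default_rng(10))
        d1 = draw_death_times(cfg, True, np.random.default_rng(11))
        f0 = np.mean([t is not None for t in d0])
        f1 = np.mean([t is not None for t in d1])
        p = (f0 * 500 + f1 * 500) / 1000
        se = np.sqrt(p * (1 - p) * (2 / 500))
        z = abs(f0 - f1) / se
        assert z < 3.0  # two-sample proportion test, alpha ~ 0.003

    def test_dead_fraction_matches_exponential_survival(self):
        h, T = 0.05, 24.0  # per hour, hours
        cfg = SimConfig.death_defaults(seed=4, n_cells=500)
        cfg.death.baseline_hazard_per_h = h
        times = draw_death_times(cfg, False, np.random.default_rng(12))
        frac = np.mean([t is not None for t in times])
        expect = 1.0 - np.exp(-h * T)
        se = np.sqrt(expect * (1 - expect) / 500)
        assert abs(frac - expect) < 3 * se

    def test_annexin_signal_cumulative_after_death(self):
        cfg = SimConfig.death_defaults(seed=6, n_cells=9, image_size=256,
                                       duration_min=720)
        cfg.death.baseline_hazard_per_h = 0.2
        stack, truth = simulate_death_series(cfg, with_tnf=False, noise=False)
        positives = [
            int(np.sum(stack.channel("death")[f] > cfg.background_level))
            for f in range(stack.n_frames)
        ]
        assert all(b >= a for a, b in zip(positives, positives[1:]))


class TestDegTable:
    def test_zero_effects_yield_no_filter_survivors(self):
        cfg = SimConfig(seed=8)
        cfg.deg.effect_nrf2 = cfg.deg.effect_nfkb = cfg.deg.model_effect = 0.0
        table, truth = simulate_deg_table(cfg)
        spec = FilterSpec(model_subset=["model_oxidative", "model_inflammatory"])
        survivors = filter_responsive(table, sorted(truth.planted_gene_blocks), spec)
        assert survivors == []

    def test_planted_blocks_recovered_by_clustering_at_zero_noise(self):
        from sklearn.metrics import adjusted_rand_score

        from toxsignal.genesets import cluster_heatmap

        cfg = SimConfig(seed=9)
        cfg.deg.lfc_noise_sd = 0.0
        table, truth = simulate_deg_table(cfg)
        planted = [g for g, b in truth.planted_gene_blocks.items() if b != "background"]
        result = cluster_heatmap(table, planted, sorted(set(table["treatment"])), k_genes=2)
        pred = [result.gene_labels[g] for g in planted]
        true = [truth.planted_gene_blocks[g] for g in planted]
        assert adjusted_rand_score(true, pred) == 1.0

    def test_fixed_seed_writes_byte_identical_tsv(self, tmp_path):
        for name in ("a.tsv", "b.tsv"):
            table, _ = simulate_deg_table(SimConfig(seed=10))
            write_deg_table(table, tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_large_effects_get_small_p(self):
        table, truth = simulate_deg_table(SimConfig(seed=11))
        sub = table[table["treatment"] == "dili_severe"]
        planted = {g for g, b in truth.planted_gene_blocks.items() if b == "nrf2_block"}
        p_planted = sub[sub["gene"].isin(planted)]["adj_p"]
        p_bg = sub[~sub["gene"].isin(planted) & sub["gene"].str.startswith("BG")]["adj_p"]
        assert p_planted.median() < 1e-6 < p_bg.median()
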