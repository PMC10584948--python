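"""Pore clustering, per-cluster/per-nucleus statistics, Monte-Carlo tuning."""

import numpy as np
import pytest

import npcstorm as ns
from npcstorm.errors import DegenerateClusterError, GeometryError
from npcstorm.npc_quant import (
    NOISE,
    ClusteringConfig,
    default_clustering_config,
    hull_area,
    match_centroids,
)

from conftest import make_table


class TestClusterLocalizations:
    def test_two_separated_blobs_found_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.normal((0.0, 0.0), 15.0, (50, 2))
        b = rng.normal((1000.0, 0.0), 15.0, (50, 2))
        pts = np.vstack([a, b])
        table = make_table(pts[:, 0], pts[:, 1])
        labels = ns.cluster_localizations(
            table, ClusteringConfig(min_cluster_size=10)
        )
        assert set(labels) == {0, 1}
        # each cluster contains only points generated for it
        assert len(set(labels[:50])) == 1
        assert len(set(labels[50:])) == 1
        assert labels[0] != labels[50]

    def test_fewer_points_than_min_size_all_noise(self):
        table = make_table(np.arange(5.0), np.zeros(5))
        labels = ns.cluster_localizations(table, ClusteringConfig(min_cluster_size=10))
        assert (labels == NOISE).all()

    def test_label_partition_and_min_size(self, small_field):
        table, _, _ = small_field
        cfg = default_clustering_config()
        labels = ns.cluster_localizations(table, cfg)
        assert len(labels) == len(table)
        for lab in np.unique(labels):
            if lab != NOISE:
                assert (labels == lab).sum() >= cfg.min_cluster_size

    def test_deterministic(self, small_field):
        table, _, _ = small_field
        l1 = ns.cluster_localizations(table)
        l2 = ns.cluster_localizations(table)
        assert np.array_equal(l1, l2)

    def test_csr_background_yields_few_spurious_clusters(self):
        """Uniform background alone produces far fewer clusters than a pore
        field: spurious-cluster density stays below 10% of the default pore
        density (HDBSCAN does report occasional low-density structures in
        pure noise, so exactly zero is not attainable)."""
        dens = []
        for s in range(12):
            params = ns.NPCFieldParams(npc_density=0.0, bg_rate=40.0, seed=600 + s)
            table, _ = ns.simulate_npc_field(params)
            labels = ns.cluster_localizations(
                table, ClusteringConfig(min_cluster_size=15)
            )
            n = len(np.unique(labels[labels != NOISE]))
            dens.append(n / params.roi.area)
        assert np.mean(dens) < 0.4  # vs 4.0 pores/µm² in a real field


class TestSummarizeCluster:
    def test_ideal_ring_is_exact(self):
        th = 2 * np.pi * np.arange(8) / 8
        x = 100.0 + 50.0 * np.cos(th)
        y = -40.0 + 50.0 * np.sin(th)
        table = make_table(x, y)
        c = ns.summarize_cluster(table, np.arange(8))
        assert c.centroid == pytest.approx([100.0, -40.0])
        assert c.diameter == pytest.approx(100.0)
        assert c.n_sml == 8

    def test_two_points(self):
        table = make_table([0.0, 60.0], [0.0, 0.0])
        c = ns.summarize_cluster(table, [0, 1])
        assert c.centroid == pytest.approx([30.0, 0.0])
        assert c.diameter == pytest.approx(60.0)

    def test_degenerate_cluster_raises(self):
        table = make_table([0.0], [0.0])
        with pytest.raises(DegenerateClusterError):
            ns.summarize_cluster(table, [0])

    def test_noisy_ring_diameter_matches_integral_oracle(self):
        """Mean diameter of fully-labeled noisy rings matches 2 x the
        numerically integrated mean radial distance of the ring(+)Gaussian
        model (the Rice mean) within 5 nm."""
        from scipy.stats import rice

        params = ns.NPCFieldParams(
            label_prob=1.0, bg_rate=0.0, roi=ns.disk_roi(3500.0), seed=8
        )
        table, truth = ns.simulate_npc_field(params)
        diams = []
        start = 0
        for blinks in truth.blink_counts:
            n = int(blinks.sum())
            if n >= 2:
                diams.append(
                    ns.summarize_cluster(table, np.arange(start, start + n)).diameter
                )
            start += n
        assert len(diams) >= 100
        r, sig = params.ring_diameter / 2.0, params.sigma_loc
        oracle = 2.0 * rice.mean(b=r / sig, scale=sig)
        assert np.mean(diams) == pytest.approx(oracle, abs=5.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 30, (20, 2))
        c1 = ns.summarize_cluster(make_table(pts[:, 0], pts[:, 1]), np.arange(20))
        c3 = ns.summarize_cluster(
            make_table(3 * pts[:, 0], 3 * pts[:, 1]), np.arange(20)
        )
        assert c3.diameter == pytest.approx(3 * c1.diameter)
        assert c3.centroid == pytest.approx(3 * c1.centroid)


class TestNucleusStats:
    def _clusters(self, table, sizes):
        out, start = [], 0
        for s in sizes:
            out.append(ns.summarize_cluster(table, np.arange(start, start + s)))
            start += s
        return out

    def test_density_arithmetic_with_roi(self):
        square = ns.NucleusROI(
            np.array([[0, 0], [1e4, 0], [1e4, 1e4], [0, 1e4]])
        )  # 100 µm²
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1e4, (1000, 2))
        table = make_table(pts[:, 0], pts[:, 1])
        clusters = self._clusters(table, [100] * 10)
        stats = ns.nucleus_stats(table, clusters, square)
        assert stats.area == pytest.approx(100.0)
        assert stats.npc_density == pytest.approx(0.10)
        assert stats.sml_density == pytest.approx(10.0)
        assert stats.mean_sml_per_cluster == pytest.approx(100.0)

    def test_zero_clusters_marked_undefined(self):
        table = make_table([0, 1000, 0, 1000], [0, 0, 1000, 1000])
        stats = ns.nucleus_stats(table, [], ns.disk_roi(2000.0))
        assert stats.n_npc == 0
        assert stats.npc_density == 0.0
        assert np.isnan(stats.mean_sml_per_cluster)
        assert np.isnan(stats.mean_diameter)

    def test_hull_fallback_area(self):
        table = make_table([0, 1e4, 1e4, 0], [0, 0, 1e4, 1e4])
        stats = ns.nucleus_stats(table, [])
        assert stats.area == pytest.approx(100.0)

    def test_hull_needs_three_points(self):
        with pytest.raises(GeometryError):
            hull_area(np.zeros((2, 2)))


class TestMatching:
    def test_greedy_matching_counts(self):
        truth = np.array([[0.0, 0.0], [500.0, 0.0]])
        rec = np.array([[10.0, 0.0], [490.0, 5.0], [2000.0, 0.0]])
        matched, p, r, f1 = match_centroids(rec, truth, 75.0)
        assert matched == 2
        assert p == pytest.approx(2 / 3)
        assert r == pytest.approx(1.0)

    def test_each_truth_matched_once(self):
        truth = np.array([[0.0, 0.0]])
        rec = np.array([[5.0, 0.0], [-5.0, 0.0]])
        matched, p, r, _ = match_centroids(rec, truth, 75.0)
        assert matched == 1
        assert p == pytest.approx(0.5)


class TestOptimizer:
    def test_single_candidate_degenerate(self):
        params = ns.NPCFieldParams(roi=ns.disk_roi(2000.0), seed=1)
        best, scores = ns.optimize_min_cluster_size(params, [10], n_reps=1, seed=2)
        assert best == 10
        assert set(scores["candidate"]) == {10}

    def test_zero_variance_field_ties_break_small(self):
        """Background-free pores with exactly 24 localizations each and wide
        spacing: every candidate <= 24 clusters perfectly (F1 = 1), so the
        tie-break returns the smallest; candidates > 24 find nothing."""
        params = ns.NPCFieldParams(
            roi=ns.disk_roi(2500.0),
            npc_density=2.0,
            min_separation=300.0,
            label_prob=1.0,
            mean_blinks=3.0,
            blink_law="fixed",
            bg_rate=0.0,
            seed=13,
        )
        best, scores = ns.optimize_min_cluster_size(
            params, [5, 10, 20, 30], n_reps=2, seed=4
        )
        mean_f1 = scores.groupby("candidate")["f1"].mean()
        assert mean_f1[5] == pytest.approx(1.0)
        assert mean_f1[10] == pytest.approx(1.0)
        assert mean_f1[20] == pytest.approx(1.0)
        assert mean_f1[30] < 0.5
        assert best == 5

    def test_all_zero_scores_warns_and_returns_smallest(self):
        params = ns.NPCFieldParams(
            roi=ns.disk_roi(1500.0), npc_density=0.0, bg_rate=5.0, seed=9
        )
        with pytest.warns(UserWarning, match="F1"):
            best, _ = ns.optimize_min_cluster_size(params, [50, 60], n_reps=1, seed=5)
        assert best == 50


class TestPipeline:
    def test_identical_inputs_identical_rows(self, small_field, tmp_path):
        table, _, _ = small_field
        cfg = ns.PipelineConfig(drift_correction=False)
        nuclei, clusters = ns.run_npc_pipeline(
            {"n1": table, "n2": table}, cfg, out_dir=tmp_path
        )
        a = nuclei.drop(columns="nucleus_id").iloc[0]
        b = nuclei.drop(columns="nucleus_id").iloc[1]
        assert (a == b).all()
        assert (tmp_path / "manifest.json").exists()

    def test_group_labels_preserved(self, tmp_path):
        """An 11-vs-9 nucleus study keeps one row per nucleus with its group."""
        inputs, groups = {}, {}
        for i in range(20):
            params = ns.NPCFieldParams(roi=ns.disk_roi(1200.0), seed=100 + i)
            inputs[f"n{i}"], _ = ns.simulate_npc_field(params)
            groups[f"n{i}"] = "UD" if i < 11 else "DF"
        cfg = ns.PipelineConfig(drift_correction=False)
        nuclei, _ = ns.run_npc_pipeline(inputs, cfg, groups=groups)
        assert len(nuclei) == 20
        assert (nuclei["group"] == "UD").sum() == 11
        assert (nuclei["group"] == "DF").sum() == 9

    def test_count_recovery_single_nucleus(self, default_field):
        table, truth, _ = default_field
        cfg = ns.PipelineConfig(drift_correction=False)
        stats, _ = ns.analyze_nucleus(table, cfg)
        assert abs(stats.n_npc - truth.n_npc) / truth.n_npc <= 0.10

    def test_errors_carry_nucleus_id(self):
        bad = make_table([0.0], [0.0])  # hull impossible
        with pytest.raises(Exception, match="nucleus 'x1'"):
            ns.run_npc_pipeline({"x1": bad}, ns.PipelineConfig(drift_correction=False))
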