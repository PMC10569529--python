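"""Normalized Ripley-K statistics: closed forms, oracles, invariances."""

import math

import numpy as np
import pytest

import cdc42polarity as cp
from cdc42polarity.fixtures import gaussian_cluster_pattern, uniform_pattern
from cdc42polarity.ripley import (
    DEFAULT_NBINS,
    RegimeScanResult,
    delta_statistic,
    logistic_boundaries,
    ripley_k,
)


def brute_force_k(points, geometry, nbins=DEFAULT_NBINS):
    """Independent oracle: direct all-pairs evaluation of the K formula.

    CDF(r) = #ordered pairs with d <= r / (N(N-1)), evaluated at the same
    grid edges, with no histogram accumulation.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if geometry.mode == "plane2d":
        L = geometry.L
        d = np.abs(pts[:, None, :] - pts[None, :, :])
        d = np.minimum(d, L - d)
        dist = np.sqrt((d**2).sum(-1))
        r_max = L / 2
    else:
        R = geometry.R
        c = np.clip(pts @ pts.T / R**2, -1, 1)
        dist = R * np.arccos(c)
        r_max = math.pi * R
    iu = ~np.eye(n, dtype=bool)
    dist = dist[iu]
    grid = np.linspace(0, r_max, nbins + 1)
    cdf = np.array([(dist <= r).mean() for r in grid])
    if geometry.mode == "plane2d":
        k_of_r = np.sqrt(geometry.A_m / math.pi * cdf) - grid
    else:
        R = geometry.R
        k_of_r = 4 * math.pi * R**2 * cdf - 2 * math.pi * R**2 * (1 - np.cos(grid / R))
    return grid, k_of_r


class TestClosedForms:
    def test_point_mass_limit_2d(self, plane):
        pts = np.tile([[4.0, 4.0]], (100, 1))
        kf = ripley_k(pts, plane)
        # all pairs coincide: K(r) = sqrt(A/pi) - r, maximum 5.0 at r -> 0
        assert kf.K == pytest.approx(math.sqrt(plane.A_m / math.pi), abs=1e-9)
        assert kf.K == pytest.approx(5.0, abs=1e-3)

    def test_point_mass_limit_3d(self, sphere):
        p = np.array([0.0, 0.0, sphere.R])
        kf = ripley_k(np.tile(p, (100, 1)), sphere)
        assert kf.K == pytest.approx(4 * math.pi * sphere.R**2, abs=1e-9)
        assert kf.K == pytest.approx(78.54, abs=0.01)

    @pytest.mark.parametrize("geom", ["plane", "sphere"])
    def test_uniform_patterns_score_near_zero(self, geom, plane, sphere):
        geo = plane if geom == "plane" else sphere
        ks = [
            ripley_k(uniform_pattern(3000, geo, seed=100 + i), geo).K
            for i in range(10)
        ]
        assert np.mean(ks) < 0.3 if geom == "plane" else np.mean(ks) < 5.0
        assert max(ks) < 1.5 if geom == "plane" else max(ks) < 30.0

    def test_tight_cluster_scores_stable_polarity(self, plane, sphere):
        pts2 = gaussian_cluster_pattern(3000, plane, sigma=0.05, seed=0)
        assert ripley_k(pts2, plane).K > 3.0
        pts3 = gaussian_cluster_pattern(3000, sphere, sigma=0.05, seed=0)
        assert ripley_k(pts3, sphere).K > 50.0

    def test_density_normalization(self, plane, rng):
        kf = ripley_k(rng.uniform(0, plane.L, (400, 2)), plane)
        dr = kf.P_r[1] - kf.P_r[0]
        assert kf.P_density.sum() * dr == pytest.approx(1.0)

    def test_degenerate_sizes(self, plane):
        with pytest.warns(UserWarning):
            assert ripley_k(np.zeros((1, 2)), plane).K == 0.0
        with pytest.warns(UserWarning):
            assert ripley_k(np.zeros((0, 2)), plane).K == 0.0


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("geom,n", [("plane", 200), ("sphere", 150)])
    def test_matches_direct_all_pairs_evaluation(self, geom, n, plane, sphere, rng):
        geo = plane if geom == "plane" else sphere
        # half the points form a loose cluster so the CDF is non-trivial
        pts = np.concatenate([
            uniform_pattern(n // 2, geo, rng),
            gaussian_cluster_pattern(n - n // 2, geo, sigma=0.3, seed=rng),
        ])
        kf = ripley_k(pts, geo)
        grid, k_oracle = brute_force_k(pts, geo)
        assert np.allclose(kf.r_grid, grid)
        assert np.allclose(kf.K_of_r, k_oracle, atol=1e-9)

    def test_two_distant_half_populations(self, plane):
        pts = np.concatenate([
            np.tile([[2.0, 2.0]], (40, 1)) + 1e-4 * np.arange(40)[:, None],
            np.tile([[6.5, 6.5]], (40, 1)) + 1e-4 * np.arange(40)[:, None],
        ])
        kf = ripley_k(pts, plane)
        _, k_oracle = brute_force_k(pts, plane)
        assert np.allclose(kf.K_of_r, k_oracle, atol=1e-9)
        assert kf.K == pytest.approx(k_oracle.max(), abs=1e-9)


class TestInvariances:
    def test_periodic_translation_2d(self, plane, rng):
        pts = gaussian_cluster_pattern(400, plane, sigma=0.4, seed=rng)
        k0 = ripley_k(pts, plane).K_of_r
        shifted = np.mod(pts + [3.7, 5.1], plane.L)
        assert np.allclose(ripley_k(shifted, plane).K_of_r, k0, atol=1e-9)

    def test_rotation_3d(self, sphere, rng):
        from scipy.spatial.transform import Rotation

        pts = gaussian_cluster_pattern(400, sphere, sigma=0.4, seed=rng)
        k0 = ripley_k(pts, sphere).K_of_r
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        assert np.allclose(ripley_k(pts @ rot.T, sphere).K_of_r, k0, atol=1e-9)

    @pytest.mark.parametrize("geom", ["plane", "sphere"])
    def test_clustering_strength_decreases_with_dispersion(self, geom, plane, sphere):
        geo = plane if geom == "plane" else sphere
        sigmas = [0.05, 0.1, 0.2, 0.5, 1.0]
        means = []
        for s in sigmas:
            ks = [
                ripley_k(gaussian_cluster_pattern(500, geo, s, seed=7 * i + 1), geo).K
                for i in range(20)
            ]
            means.append(np.mean(ks))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_literal_2d_form_available(self, plane, rng):
        pts = uniform_pattern(500, plane, rng)
        lit = ripley_k(pts, plane, literal_2d_form=True)
        # the literal printed form does not vanish for uniform patterns:
        # its expectation is r^2 - r over the grid, maximum ~ r_max^2
        assert lit.K > 1.0


class TestClassification:
    @pytest.mark.parametrize(
        "K, mode, expected",
        [
            (1.2, "plane2d", "unpolarized"),
            (1.5, "plane2d", "polarized"),
            (2.9, "plane2d", "polarized"),
            (3.0, "plane2d", "stable"),
            (29.0, "sphere3d", "unpolarized"),
            (30.0, "sphere3d", "polarized"),
            (50.0, "sphere3d", "stable"),
        ],
    )
    def test_thresholds_inclusive_on_polarized_side(self, K, mode, expected):
        assert cp.classify_state(K, mode) == expected


class TestRegimes:
    def test_delta_statistic_hand_counts(self):
        assert delta_statistic([2.0] * 200) == 200
        assert delta_statistic([1.0] * 100 + [2.0] * 100) == 0
        assert delta_statistic([0.2, 0.3, 1.6]) == -1

    def test_regime_scan_recovers_logistic_and_boundaries(self, rng):
        b_true, c_true, N = 0.25, 100.0, 200
        xs = np.arange(70, 131, 5)
        data = {}
        for x in xs:
            d = 2 * N / (1 + np.exp(-b_true * (x - c_true))) - N
            # build runs whose K samples produce Delta near d (with noise)
            runs = []
            for _ in range(4):
                dd = int(np.clip(d + rng.normal(0, 8), -N, N))
                n_above = (dd + N) // 2
                runs.append([2.0] * n_above + [0.5] * (N - n_above))
            data[float(x)] = runs
        res = cp.regime_scan(data, alpha=0.85)
        assert res.fit_ok
        assert res.logistic_b == pytest.approx(b_true, rel=0.25)
        assert res.logistic_c == pytest.approx(c_true, abs=2.0)
        # boundary closed form vs brute-force root finding
        from scipy.optimize import brentq

        def f(x, sign):
            return (2 * N / (1 + np.exp(-res.logistic_b * (x - res.logistic_c))) - N) / N - sign * 0.85

        lo = brentq(lambda x: f(x, -1), 0, res.logistic_c)
        hi = brentq(lambda x: f(x, +1), res.logistic_c, 300)
        assert res.boundaries[0] == pytest.approx(lo, abs=1e-6)
        assert res.boundaries[1] == pytest.approx(hi, abs=1e-6)
        # extremes classify as the pure regimes, middle as transient
        regimes = {r.x: r.regime for r in res.results}
        assert regimes[70.0] == "unpolarized"
        assert regimes[130.0] == "polarized"
        assert regimes[100.0] == "transient"

    def test_boundary_width_formula(self):
        lo, hi = logistic_boundaries(b=0.5, c=50.0, alpha=0.85)
        w = math.log(1.85 / 0.15) / 0.5
        assert (hi - lo) == pytest.approx(2 * w)


class TestTimingSummaries:
    def test_fraction_time_polarized(self):
        t = np.arange(0, 4001, 10.0)
        assert cp.fraction_time_polarized(t, np.full_like(t, 2.0)) == 1.0
        k = np.where(np.arange(len(t)) % 2 == 0, 1.0, 2.0)
        assert cp.fraction_time_polarized(t, k) == pytest.approx(0.5, abs=0.01)
        with pytest.raises(ValueError):
            cp.fraction_time_polarized(t, k, window=(5000, 6000))

    def test_time_to_threshold(self):
        t = [0.0, 10.0, 20.0, 30.0]
        assert cp.time_to_threshold(t, [0.5, 1.0, 3.2, 3.5], 3.0) == 20.0
        assert cp.time_to_threshold(t, [0.5, 1.0, 1.2, 1.4], 3.0) is None
        # a transient spike is rejected when persistence is required
        assert cp.time_to_threshold(t, [0.5, 3.5, 1.0, 3.5], 3.0, hold=15.0) is None
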