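"""Kernel-density typicality: closed forms, brute-force oracles, invariances."""

import numpy as np
import pytest

from typiselect.typicality import (
    TypicalityScorer,
    eval_log_density,
    fit_density,
    select_bandwidth,
    typicality_vector,
)


def brute_force_density(query, support, w):
    """Naive Eq.-style kernel mean: (1/n) sum of isotropic Gaussians."""
    support = np.atleast_2d(support)
    M = support.shape[1]
    const = (2 * np.pi) ** (-M / 2) * w ** (-M)
    vals = [const * np.exp(-0.5 * np.sum((query - s) ** 2) / w**2) for s in support]
    return float(np.mean(vals))


def brute_force_typicality(query, supports, w):
    f = np.array([brute_force_density(query, s, w) for s in supports])
    return f / f.sum()


class TestDensity:
    def test_single_point_closed_form(self):
        w = 0.7
        m = fit_density(np.zeros((1, 3)), w)
        expected = (2 * np.pi) ** (-1.5) * w**-3
        assert np.exp(eval_log_density(m, np.zeros(3))) == pytest.approx(expected, rel=1e-12)

    def test_far_query_underflows_linearly_but_not_in_log(self):
        m = fit_density(np.zeros((1, 3)), 0.1)
        far = np.full(3, 50.0)
        logd = eval_log_density(m, far)
        assert np.isfinite(logd)
        assert np.exp(logd) < 1e-300

    def test_matches_brute_force_kernel_sum(self, rng):
        support = rng.normal(size=(50, 3))
        w = 0.8
        m = fit_density(support, w)
        queries = rng.normal(size=(100, 3)) * 2
        got = np.exp(eval_log_density(m, queries))
        expected = np.array([brute_force_density(q, support, w) for q in queries])
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_duplicate_support_leaves_density_unchanged(self, rng):
        support = rng.normal(size=(20, 2))
        m1 = fit_density(support, 0.5)
        m2 = fit_density(np.vstack([support, support]), 0.5)
        q = rng.normal(size=2)
        assert eval_log_density(m1, q) == pytest.approx(eval_log_density(m2, q), rel=1e-12)

    def test_translation_invariance(self, rng):
        support = rng.normal(size=(20, 3))
        q = rng.normal(size=3)
        shift = np.array([10.0, -3.0, 7.0])
        m1 = fit_density(support, 0.5)
        m2 = fit_density(support + shift, 0.5)
        assert eval_log_density(m1, q) == pytest.approx(
            eval_log_density(m2, q + shift), rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_density(np.zeros((0, 3)), 1.0)
        with pytest.raises(ValueError):
            fit_density(np.zeros((2, 3)), 0.0)
        m = fit_density(np.zeros((2, 3)), 1.0)
        with pytest.raises(ValueError):
            eval_log_density(m, np.zeros(2))


class TestTypicalityVector:
    def test_single_subtype_is_one(self):
        m = fit_density(np.zeros((3, 2)), 1.0)
        np.testing.assert_allclose(typicality_vector(np.ones(2), [m]), [1.0])

    def test_mirror_symmetry_gives_half(self, rng):
        pts = rng.normal(size=(25, 3)) + np.array([3.0, 0, 0])
        mirror = pts * np.array([-1, 1, 1])
        models = [fit_density(pts, 1.0), fit_density(mirror, 1.0)]
        q = np.array([0.0, 0.5, -0.2])  # on the symmetry plane x=0
        np.testing.assert_allclose(typicality_vector(q, models), [0.5, 0.5], atol=1e-12)

    def test_matches_brute_force_ratio(self, rng):
        supports = [rng.normal(size=(15, 3)) + c for c in ([0, 0, 0], [2, 1, 0], [-1, 3, 1])]
        w = 0.9
        models = [fit_density(s, w) for s in supports]
        for _ in range(20):
            q = rng.normal(size=3) * 2
            np.testing.assert_allclose(
                typicality_vector(q, models),
                brute_force_typicality(q, supports, w),
                rtol=1e-10,
            )

    def test_rows_sum_to_one(self, two_cluster_coords):
        coords, labels = two_cluster_coords
        models = [fit_density(coords[labels == k], 0.5) for k in (0, 1)]
        T = typicality_vector(coords, models)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-9)
        assert (T >= 0).all() and (T <= 1).all()

    def test_mismatched_bandwidths_rejected(self):
        with pytest.raises(ValueError):
            typicality_vector(
                np.zeros(2),
                [fit_density(np.zeros((1, 2)), 1.0), fit_density(np.zeros((1, 2)), 2.0)],
            )

    def test_monotone_along_cluster_axis(self, two_cluster_coords):
        coords, labels = two_cluster_coords
        models = [fit_density(coords[labels == k], 1.0) for k in (0, 1)]
        mean_a = coords[labels == 0].mean(axis=0)
        mean_b = coords[labels == 1].mean(axis=0)
        ts = [
            typicality_vector(mean_a + f * (mean_b - mean_a), models)[0]
            for f in np.linspace(0, 1, 9)
        ]
        assert all(t1 >= t2 - 1e-12 for t1, t2 in zip(ts, ts[1:]))


class TestBandwidth:
    def test_fixed_strategy(self, two_cluster_coords):
        coords, labels = two_cluster_coords
        assert select_bandwidth(coords, labels, "fixed:0.5") == 0.5

    def test_scott_rule_closed_form(self):
        g = np.random.default_rng(0)
        X = g.standard_normal((1000, 3))
        w = select_bandwidth(X, np.zeros(1000), "scott")
        # sd ~ 1, so w ~ n^(-1/7)
        assert w == pytest.approx(1000 ** (-1 / 7), rel=0.05)

    def test_spread_returns_interior_grid_value(self, two_cluster_coords):
        coords, labels = two_cluster_coords
        from typiselect.typicality import _median_pairwise

        med = _median_pairwise(coords)
        w = select_bandwidth(coords, labels, "spread")
        grid = np.geomspace(0.05 * med, 5.0 * med, 25)
        assert grid[0] < w < grid[-1]

    def test_unknown_strategy_rejected(self, two_cluster_coords):
        coords, labels = two_cluster_coords
        with pytest.raises(ValueError):
            select_bandwidth(coords, labels, "nope")


class TestScorer:
    def test_own_typicality_all_one_for_single_subtype(self, rng):
        X = rng.normal(size=(10, 3))
        s = TypicalityScorer(bandwidth="fixed:1.0").fit(X, np.zeros(10, dtype=int))
        np.testing.assert_allclose(s.own_typicality(), 1.0)

    def test_cluster_center_scores_higher_than_midpoint(self, two_cluster_coords):
        coords, labels = two_cluster_coords
        # append one case at cluster-0 center and one midway between clusters
        center = coords[labels == 0].mean(axis=0)
        mid = coords.mean(axis=0)
        X = np.vstack([coords, center, mid])
        y = np.concatenate([labels, [0, 0]])
        s = TypicalityScorer(bandwidth="fixed:1.0").fit(X, y)
        own = s.own_typicality()
        assert own[-2] > own[-1]

    def test_shared_kernel_constant_cancels(self, two_cluster_coords):
        """Scaling all K kernel constants by c > 0 cannot change the ratio."""
        coords, labels = two_cluster_coords
        s = TypicalityScorer(bandwidth="fixed:0.8").fit(coords, labels)
        T = s.transform()
        for c in (0.1, 7.3):
            # scaling every subtype's kernel constant by c shifts all log
            # densities by log(c); recompute the ratio with that shift
            L = np.stack([eval_log_density(m, coords) + np.log(c) for m in s.models_], axis=-1)
            L = L - L.max(axis=-1, keepdims=True)
            T2 = np.exp(L)
            T2 /= T2.sum(axis=-1, keepdims=True)
            np.testing.assert_allclose(T2, T, rtol=1e-10)

    def test_leave_one_out_lowers_own_score(self, two_cluster_coords):
        coords, labels = two_cluster_coords
        s_in = TypicalityScorer(bandwidth="fixed:0.5").fit(coords, labels)
        s_loo = TypicalityScorer(bandwidth="fixed:0.5", leave_one_out=True).fit(coords, labels)
        # removing one's own kernel cannot raise one's own-subtype density
        T_in = s_in.transform()
        T_loo = s_loo.transform()
        col = [int(y) for y in labels]
        own_in = T_in[np.arange(len(labels)), col]
        own_loo = T_loo[np.arange(len(labels)), col]
        assert (own_loo <= own_in + 1e-9).all()

    def test_empty_subtype_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            TypicalityScorer(bandwidth="spread").fit(X, np.array([0, 0, 0, 1]))
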