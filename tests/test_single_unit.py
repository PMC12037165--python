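"""auROC machinery, permutation significance, and the independence battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graspcode import single_unit as su


def brute_force_auroc(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive pairwise-comparison oracle: P(a>b) + 0.5 P(a==b)."""
    wins = sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b)
    return wins / (len(a) * len(b))


class TestAurocTimecourse:
    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 16, 2)
            vals = rng.choice([0.0, 1.0, 2.0, 3.5, 7.0], size=(1, n1 + n2, 4))
            pos = np.zeros(n1 + n2, bool)
            pos[:n1] = True
            got = su.auroc_timecourse(vals, pos)
            for b in range(4):
                want = brute_force_auroc(vals[0, pos, b], vals[0, ~pos, b])
                assert got[0, b] == pytest.approx(want, abs=1e-12)

    def test_perfect_separation_is_one(self):
        vals = np.concatenate([np.full((1, 5, 3), 10.0), np.zeros((1, 5, 3))], axis=1)
        pos = np.array([True] * 5 + [False] * 5)
        assert np.all(su.auroc_timecourse(vals, pos) == 1.0)

    def test_identical_distributions_average_half(self, rng):
        vals = np.tile(rng.poisson(5, (1, 1, 50)).astype(float), (1, 40, 1))
        pos = np.array([True, False] * 20)
        # all-tied data gives exactly 0.5 per bin
        assert np.all(su.auroc_timecourse(vals, pos) == 0.5)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(2, 12, 5))
        pos = np.zeros(12, bool)
        pos[rng.choice(12, 5, replace=False)] = True
        a = su.auroc_timecourse(vals, pos)
        b = su.auroc_timecourse(vals, ~pos)
        np.testing.assert_allclose(a + b, 1.0, atol=1e-12)

    def test_too_few_trials_per_class_rejected(self, rng):
        vals = rng.normal(size=(1, 5, 3))
        with pytest.raises(ValueError, match=">=2 trials"):
            su.auroc_timecourse(vals, np.array([True, False, False, False, False]))


class TestPermutationMask:
    def test_strong_static_effect_detected(self, rng):
        # 3:1 rate ratio, 30 trials/class: the effect window must be masked
        n_bins = 40
        pos = np.array([True] * 30 + [False] * 30)
        hit = 0
        for _ in range(20):
            rates = rng.poisson(10, (1, 60, n_bins)).astype(float)
            rates[:, pos, 10:30] = rng.poisson(30, (30, 20))
            res = su.permutation_mask(rates, pos, np.arange(n_bins), n_perm=1000, rng=rng)
            hit += res.mask[0, 12:28].all()
        assert hit >= 19  # >=95% coverage of the effect window interior

    def test_null_units_rarely_flagged(self, rng):
        rates = rng.poisson(8, (50, 60, 50)).astype(float)
        pos = np.array([True, False] * 30)
        res = su.permutation_mask(rates, pos, np.arange(50), n_perm=1000, rng=rng)
        assert res.encodes.mean() <= 0.05

    def test_insufficient_permutations_rejected(self, rng):
        rates = rng.normal(size=(1, 10, 3))
        pos = np.array([True] * 5 + [False] * 5)
        with pytest.raises(ValueError, match="n_perm"):
            su.permutation_mask(rates, pos, np.arange(3), n_perm=100, alpha=0.001)


def test_classify_selectivity_counts(rng):
    bins = np.arange(10)
    pos = np.array([True] * 15 + [False] * 15)
    rates = rng.poisson(8, (30, 30, 10)).astype(float)
    rates[:10, pos, :] += 15  # grip-selective block
    g = su.permutation_mask(rates, pos, bins, n_perm=1000, rng=rng)
    f = su.permutation_mask(rates, rng.permutation(pos), bins, n_perm=1000, rng=rng)
    labels, counts = su.classify_selectivity(g, f)
    assert counts["grip_only"] >= 9
    assert sum(counts.values()) == 30


class TestIndependence:
    def test_type_one_error_near_nominal(self, rng):
        # independent auROC pairs: rejection rate within [0.5a, 2a] at a=0.01
        alpha, n_sim = 0.01, 500
        rejections = 0
        for _ in range(n_sim):
            g = rng.uniform(0.2, 0.8, 60)
            f = rng.uniform(0.2, 0.8, 60)
            _, p, _ = su.marginal_independence_test(g, f, n_perm=400, rng=rng)
            rejections += p < alpha
        rate = rejections / n_sim
        assert 0.5 * alpha <= rate <= 2 * alpha

    def test_perfect_dependence_detected(self, rng):
        g = rng.uniform(0.0, 1.0, 100)
        _, p, _ = su.marginal_independence_test(g, g, n_perm=500, rng=rng)
        assert p < 0.01

    def test_degenerate_histogram_rejected(self):
        g = np.full(30, 0.55)
        with pytest.raises(ValueError, match="degenerate"):
            su.marginal_independence_test(g, g, rng=0)


class TestEllipseAngle:
    def test_vertical_scatter_is_90_degrees(self, rng):
        pts = np.column_stack([np.full(50, 0.5), rng.uniform(0, 1, 50)])
        theta, _, _ = su.ellipse_angle(pts)
        assert theta == pytest.approx(90.0)

    def test_diagonal_scatter_is_45_degrees(self):
        v = np.linspace(0, 1, 30)
        theta, _, _ = su.ellipse_angle(np.column_stack([v, v]))
        assert theta == pytest.approx(45.0)

    def test_matches_analytic_eigenvector_angle(self, rng):
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        pts = rng.multivariate_normal([0.5, 0.5], cov, size=20000)
        evals, evecs = np.linalg.eigh(cov)
        want = np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])) % 180
        theta, _, _ = su.ellipse_angle(pts)
        assert theta == pytest.approx(want, abs=2.0)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            su.ellipse_angle(np.full((10, 2), 0.5))


class TestStrengthCorrelation:
    def test_self_correlation_is_one(self, rng):
        d = rng.uniform(0, 0.5, (40, 30))
        r, _, _ = su.strength_correlation(d, d, n_shuffle=50, alpha=0.05, rng=rng)
        np.testing.assert_allclose(r, 1.0)

    def test_planted_unit_level_correlation_detected(self, rng):
        base = rng.uniform(0, 0.4, (60, 30))
        noise = rng.uniform(0, 0.4, (60, 30))
        dg = base
        df = 0.9 * base + 0.1 * noise  # rho ~ 0.9 across units
        _, _, mask = su.strength_correlation(dg, df, n_shuffle=1000, rng=rng)
        assert mask.any()

    def test_independent_series_rarely_flagged(self, rng):
        flagged = 0
        for _ in range(20):
            dg = rng.uniform(0, 0.5, (60, 30))
            df = rng.uniform(0, 0.5, (60, 30))
            _, _, mask = su.strength_correlation(dg, df, n_shuffle=1000, rng=rng)
            flagged += mask.any()
        assert flagged <= 2


class TestCrossTemporalCorrelation:
    def test_constructed_shift_puts_ridge_at_lag(self, rng):
        n_units, n_bins, shift = 80, 60, 10  # +200 ms at 20 ms bins
        dg = rng.uniform(0, 0.5, (n_units, n_bins))
        df = np.roll(dg, shift, axis=1)  # force = grip shifted +200 ms
        lags, r, _, _ = su.cross_temporal_correlation(dg, df, n_shuffle=10, rng=rng)
        mean_r = np.nanmean(r, axis=0)
        assert lags[np.nanargmax(mean_r)] == pytest.approx(200.0)

    def test_lag_zero_column_equals_strength_correlation(self, rng):
        dg = rng.uniform(0, 0.5, (30, 25))
        df = rng.uniform(0, 0.5, (30, 25))
        lags, r, _, _ = su.cross_temporal_correlation(dg, df, n_shuffle=10, rng=rng)
        r0, _, _ = su.strength_correlation(dg, df, n_shuffle=10, rng=rng)
        col = np.flatnonzero(lags == 0.0)[0]
        np.testing.assert_allclose(r[:, col], r0, atol=1e-12)

    def test_independent_series_sparse_significance(self, rng):
        dg = rng.uniform(0, 0.5, (60, 40))
        df = rng.uniform(0, 0.5, (60, 40))
        _, _, _, mask = su.cross_temporal_correlation(dg, df, n_shuffle=1000, rng=rng)
        assert mask.mean() < 0.01
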