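"""Interarray normalization: RSE and the median/quantile baselines."""

import numpy as np
import pytest
from scipy import stats

from kinorm.internorm import (
    RSEParams,
    detect_affected,
    local_median_center_pair,
    median_center,
    quantile_normalize,
    rse_normalize,
    spot_means,
    substrate_pvalues,
)
from kinorm.intranorm import gradient_correct
from kinorm.simulate import SimulationConfig, simulate_experiment

from conftest import brute_force_nearest, random_table


class TestSpotMeans:
    def test_plain_mean(self, small_layout, rng):
        t = random_table(small_layout, rng)
        t.values[:, 0, 0] = [8.0, 9.0, 10.0]
        assert spot_means(t)[0, 0] == pytest.approx(9.0)

    def test_flagged_replicate_excluded(self, small_layout, rng):
        t = random_table(small_layout, rng)
        t.values[:, 0, 0] = [8.0, 99.0, 10.0]
        t.flags["artifact"][1, 0, 0] = True
        assert spot_means(t)[0, 0] == pytest.approx(9.0)

    def test_all_flagged_is_missing(self, small_layout, rng):
        t = random_table(small_layout, rng)
        t.flags["artifact"][:, 0, 0] = True
        assert np.isnan(spot_means(t)[0, 0])


class TestLocalMedianCenter:
    def test_constant_shift_recovered(self, small_layout, rng):
        a = random_table(small_layout, rng)
        b = a.copy()
        c = 1.8
        b.values = a.values + c
        na, nb, m = local_median_center_pair(a, b)
        np.testing.assert_allclose(m, c, atol=1e-12)
        np.testing.assert_allclose(nb.values - na.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(na.values, a.values + c / 2, atol=1e-12)

    def test_identical_tables_unchanged(self, small_layout, rng):
        a = random_table(small_layout, rng)
        na, nb, m = local_median_center_pair(a, a.copy())
        np.testing.assert_allclose(m, 0.0, atol=1e-12)
        np.testing.assert_allclose(na.values, a.values)

    def test_offsets_match_brute_force(self, small_layout, rng):
        a = random_table(small_layout, rng)
        b = random_table(small_layout, rng)
        _, _, m = local_median_center_pair(a, b, n_neighbors=5)
        d = spot_means(b) - spot_means(a)
        eligible = np.isfinite(d).ravel()
        for i in [0, 9, 33, 63]:
            idx = brute_force_nearest(small_layout, i, eligible, 4)
            pool = np.concatenate([[i], idx])  # self included interarray
            assert m.ravel()[i] == pytest.approx(np.median(d.ravel()[pool]))

    def test_anchor_a_moves_only_b(self, small_layout, rng):
        a = random_table(small_layout, rng)
        b = a.copy()
        b.values = a.values + 1.0
        na, nb, _ = local_median_center_pair(a, b, anchor="a")
        np.testing.assert_allclose(na.values, a.values)
        np.testing.assert_allclose(nb.values, a.values, atol=1e-12)


class TestDetectAffected:
    def test_identical_triplicates_not_affected(self, small_layout, rng):
        a = random_table(small_layout, rng)
        assert not detect_affected(a, a.copy()).any()

    def test_clear_shift_detected_and_matches_hand_t(self, small_layout, rng):
        a = random_table(small_layout, rng)
        b = a.copy()
        a.values[:, 0, 0] = [10.0, 10.1, 9.9]
        b.values[:, 0, 0] = [12.0, 12.1, 11.9]
        p = substrate_pvalues(a, b)
        # pooled two-sample t computed by the closed formula
        x, y = np.array([10.0, 10.1, 9.9]), np.array([12.0, 12.1, 11.9])
        sp2 = (x.var(ddof=1) * 2 + y.var(ddof=1) * 2) / 4
        t_hand = (y.mean() - x.mean()) / np.sqrt(sp2 * (2 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        assert p[0, 0] == pytest.approx(p_hand, rel=1e-10)
        assert detect_affected(a, b, alpha=0.1)[0, 0]

    def test_null_calibration_near_alpha(self):
        """With no true effects ~10% of substrates trip the p < 0.1 test."""
        cfg = SimulationConfig(n_patients=2, effect_size=0.0, gradient_strength=0.0,
                               array_effect_range=(0.0, 0.0), seed=7)
        exp = simulate_experiment(cfg)
        fracs = [detect_affected(a, b, alpha=0.1).mean() for a, b in exp.pairs]
        assert np.mean(fracs) == pytest.approx(0.10, abs=0.03)

    def test_insufficient_replicates_skipped(self, small_layout, rng):
        a = random_table(small_layout, rng)
        b = a.copy()
        b.values[:, 0, 0] += 5.0             # huge effect...
        a.flags["artifact"][:2, 0, 0] = True  # ...but only 1 usable replicate
        assert not detect_affected(a, b)[0, 0]


class TestRSE:
    def test_identical_slides_converge_immediately(self, small_layout, rng):
        a = random_table(small_layout, rng)
        res = rse_normalize(a, a.copy())
        assert res.converged
        assert res.iterations == 1
        assert res.normalization_set.all()
        np.testing.assert_allclose(res.offsets, 0.0, atol=1e-12)

    def test_pure_array_effect_recovered(self):
        """Slide B = slide A - 1.5 with no induced spots: the offsets
        recover 1.5 and only ~alpha of substrates are excluded."""
        cfg = SimulationConfig(n_patients=1, effect_size=0.0, n_induced=1,
                               gradient_strength=0.0,
                               array_effect_range=(0.0, 0.0), seed=13)
        exp = simulate_experiment(cfg)
        a, b = exp.pairs[0]
        b = b.copy()
        b.values = b.values - 1.5
        res = rse_normalize(a, b)
        assert np.median(res.offsets) == pytest.approx(-1.5, abs=0.05)
        assert res.excluded.mean() < 0.2

    def test_swap_symmetry(self, mid_layout):
        cfg = SimulationConfig(n_patients=1, layout=mid_layout, n_induced=40,
                               seed=23)
        exp = simulate_experiment(cfg)
        a, b = exp.pairs[0]
        r1 = rse_normalize(a, b)
        r2 = rse_normalize(b, a)
        np.testing.assert_allclose(r1.offsets, -r2.offsets, atol=1e-12)
        assert np.array_equal(r1.normalization_set, r2.normalization_set)

    def test_converged_set_survives_final_test(self, mid_layout):
        cfg = SimulationConfig(n_patients=1, layout=mid_layout, n_induced=40,
                               seed=29)
        exp = simulate_experiment(cfg)
        a, b = exp.pairs[0]
        a, b = gradient_correct(a).table, gradient_correct(b).table
        res = rse_normalize(a, b)
        if res.converged and res.iterations < RSEParams().max_iterations:
            p = substrate_pvalues(res.table_a, res.table_b)
            final_affected = np.where(np.isnan(p), False, p < 0.1)
            # no substrate in the converged set tested significant at the end
            assert not (final_affected & res.normalization_set).any() or \
                res.set_sizes[-1] != res.set_sizes[-2]  # cycle-union fallback


class TestBaselines:
    def test_median_centering_equalizes_medians(self, small_layout, rng):
        a = random_table(small_layout, rng)
        b = random_table(small_layout, rng)
        a.values += 9 - np.median(a.values)
        b.values += 11 - np.median(b.values)
        ca, cb = median_center([a, b])
        assert np.median(ca.values) == pytest.approx(10.0)
        assert np.median(cb.values) == pytest.approx(10.0)

    def test_median_centering_identity_for_equal_tables(self, small_layout, rng):
        a = random_table(small_layout, rng)
        ca, cb = median_center([a, a.copy()])
        np.testing.assert_allclose(ca.values, a.values)
        np.testing.assert_allclose(cb.values, a.values)

    def test_quantile_small_example(self, small_layout):
        """(1,2,3) and (4,5,6) both become (2.5, 3.5, 4.5) padded across
        the table; checked on the first three cells with the rest tied."""
        a = random_table(small_layout, np.random.default_rng(0))
        b = a.copy()
        a.values[:] = 0.0
        b.values[:] = 0.0
        a.values[0, 0, :3] = [1, 2, 3]
        b.values[0, 0, :3] = [4, 5, 6]
        qa, qb = quantile_normalize([a, b])
        np.testing.assert_allclose(qa.values[0, 0, :3], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(qb.values[0, 0, :3], [2.5, 3.5, 4.5])

    def test_quantile_identity_for_identical_tables(self, small_layout, rng):
        a = random_table(small_layout, rng)
        qa, qb = quantile_normalize([a, a.copy()])
        np.testing.assert_allclose(qa.values, a.values, atol=1e-12)
        np.testing.assert_allclose(qb.values, a.values, atol=1e-12)

    def test_quantile_matches_brute_force(self, small_layout, rng):
        a = random_table(small_layout, rng)
        b = random_table(small_layout, rng)
        qa, qb = quantile_normalize([a, b])
        # brute force: mean of order statistics, assigned by rank
        va, vb = a.values.ravel(), b.values.ravel()
        ref = (np.sort(va) + np.sort(vb)) / 2
        np.testing.assert_allclose(np.sort(qa.values.ravel()), ref, atol=1e-12)
        np.testing.assert_allclose(qa.values.ravel(),
                                   ref[np.argsort(np.argsort(va))], atol=1e-12)

    def test_quantile_preserves_missing(self, small_layout, rng):
        a = random_table(small_layout, rng)
        b = random_table(small_layout, rng)
        a.values[0, 0, 0] = np.nan
        qa, _ = quantile_normalize([a, b])
        assert np.isnan(qa.values[0, 0, 0])
        assert np.isfinite(qa.values[0, 0, 1])
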