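"""Detection metrics, cLOD, screening projection, split harnesses."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq


from themis.metrics import (
    ScoredCohort,
    association_profiles,
    auc_with_ci,
    clod,
    grouped_split_harness,
    rank_auc,
    repeated_split_harness,
    screening_projection,
    sensitivity_at_specificity,
    wilson_interval,
)


def _cohort(scores_h, scores_c):
    scores = np.concatenate([scores_h, scores_c])
    labels = ["healthy"] * len(scores_h) + ["cancer"] * len(scores_c)
    return ScoredCohort([f"s{i}" for i in range(len(scores))], labels, scores)


class TestAUC:
    def test_perfect_separation(self):
        c = _cohort([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        auc, lo, hi = auc_with_ci(c, n_boot=100, seed=0)
        assert auc == 1.0 and hi == 1.0

    def test_matches_all_pairs_oracle_with_ties(self, rng):
        for _ in range(5):
            h = np.round(rng.random(25), 1)  # rounding induces ties
            ca = np.round(rng.random(20), 1)
            auc = rank_auc(
                np.array([False] * 25 + [True] * 20), np.concatenate([h, ca])
            )
            wins = sum((c > x) + 0.5 * (c == x) for c in ca for x in h)
            assert auc == pytest.approx(wins / (25 * 20))

    def test_null_scores_near_half(self, rng):
        c = _cohort(rng.random(250), rng.random(250))
        auc, _, _ = auc_with_ci(c, n_boot=50, seed=1)
        assert 0.45 <= auc <= 0.55

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        c = _cohort(rng.normal(0.3, 0.1, 50).clip(0, 1), rng.normal(0.6, 0.1, 50).clip(0, 1))
        auc, lo, hi = auc_with_ci(c, n_boot=500, seed=2)
        assert lo <= auc <= hi


class TestSensitivityAtSpecificity:
    def test_printed_wilson_interval_for_197_of_238(self):
        lo, hi = wilson_interval(197, 238)
        assert round(100 * 197 / 238) == 83
        assert round(100 * lo) == 77 and round(100 * hi) == 87

    def test_zero_successes_lower_bound_zero(self):
        lo, hi = wilson_interval(0, 50)
        assert lo == 0.0 and hi > 0

    def test_wilson_equals_score_test_inversion(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 400))
            k = int(rng.integers(0, n + 1))
            lo, hi = wilson_interval(k, n)
            phat = k / n
            z = 1.959964

            def score(p):
                return (phat - p) / np.sqrt(p * (1 - p) / n)

            if 0 < k < n:
                lo_oracle = brentq(lambda p: score(p) - z, 1e-12, phat)
                hi_oracle = brentq(lambda p: score(p) + z, phat, 1 - 1e-12)
                assert lo == pytest.approx(lo_oracle, abs=1e-6)
                assert hi == pytest.approx(hi_oracle, abs=1e-6)

    def test_threshold_achieves_target_and_next_lower_does_not(self, rng):
        h = rng.random(200)
        ca = rng.random(100) * 0.5 + 0.5
        c = _cohort(h, ca)
        thr, sens, (lo, hi) = sensitivity_at_specificity(c, specificity=0.95)
        assert (h < thr).mean() >= 0.95
        lower = np.max(np.unique(np.concatenate([h, ca]))[
            np.unique(np.concatenate([h, ca])) < thr
        ])
        assert (h < lower).mean() < 0.95
        assert lo <= sens <= hi


class TestCLOD:
    def _simulate(self, rng, n=200, midpoint=1e-3, slope=5.0):
        vaf = 10 ** rng.uniform(-4.5, -1.5, n)
        p = 1 / (1 + np.exp(-slope * (np.log10(vaf) - np.log10(midpoint))))
        return (rng.random(n) < p).astype(int), vaf

    def test_parameter_recovery_within_factor_1p5(self):
        rng = np.random.default_rng(12)
        detected, vaf = self._simulate(rng)
        lod, lo, hi = clod(detected, vaf)
        assert 1e-3 / 1.5 <= lod <= 1e-3 * 1.5
        assert lo <= lod <= hi

    def test_all_detected_errors(self):
        with pytest.raises(ValueError):
            clod(np.ones(20, int), np.full(20, 1e-3))

    def test_doubling_vaf_doubles_lod(self):
        rng = np.random.default_rng(5)
        detected, vaf = self._simulate(rng)
        lod1, *_ = clod(detected, vaf)
        lod2, *_ = clod(detected, 2 * vaf)
        assert lod2 == pytest.approx(2 * lod1, rel=1e-6)


class TestScreeningProjection:
    def test_published_worked_example(self):
        tp, fp, ppv = screening_projection(0.83, 0.99, 0.015, 100_000)
        assert tp == pytest.approx(1245.0)
        assert fp == pytest.approx(985.0)
        assert round(100 * ppv) == 56

    def test_perfect_test(self):
        tp, fp, ppv = screening_projection(1.0, 1.0, 0.02, 1000)
        assert fp == 0 and ppv == 1.0

    def test_population_conserved(self, rng):
        for _ in range(5):
            sens, spec = rng.random(), rng.random()
            inc, pop = rng.uniform(0.001, 0.1), 100_000
            tp, fp, _ = screening_projection(sens, spec, inc, pop)
            fn = pop * inc * (1 - sens)
            tn = pop * (1 - inc) * spec
            assert tp + fn + fp + tn == pytest.approx(pop)


class TestAssociations:
    def test_zero_matrices_give_zero_fractions(self):
        Z = np.zeros((10, 40))
        _, frac = association_profiles(Z, Z, Z)
        assert all(v == 0.0 for v in frac.values())

    def test_planted_common_alteration_fraction(self, rng):
        n, w = 40, 300
        Z = rng.normal(0, 1, size=(n, w))
        altered = np.zeros(w, bool)
        altered[: int(0.3 * w)] = True
        Z[:, altered] += 3.0
        _, frac = association_profiles(Z, np.zeros((n, w)), np.zeros((n, w)))
        assert frac["fsi"] == pytest.approx(0.30, abs=0.02)

    def test_profile_correlations_match_covariance_oracle(self, rng):
        A = rng.normal(0, 1, size=(3, 50))
        B = 0.5 * A + rng.normal(0, 1, size=(3, 50))
        df, _ = association_profiles(A, B, rng.normal(0, 1, (3, 50)))
        for i in range(3):
            x, y = A[i], B[i]
            expected = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
            assert df.loc[i, "pcc_fsi_mfr"] == pytest.approx(expected, abs=1e-12)


class TestHarnesses:
    @staticmethod
    def _fit_score(Xtr, ytr, Xte):
        mu1 = Xtr[ytr == 1].mean(axis=0)
        mu0 = Xtr[ytr == 0].mean(axis=0)
        return Xte @ (mu1 - mu0)

    def test_grouped_combinations_follow_product_rule(self, rng):
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, 5)) + 2 * y[:, None]
        sites_h = np.where(y == 0, rng.choice(["h1", "h2"], n), None)
        sites_c = np.where(y == 1, rng.choice(["c1", "c2", "c3"], n), None)
        df = grouped_split_harness(
            X, y, {"healthy": sites_h, "cancer": sites_c}, self._fit_score
        )
        assert len(df) == 2 * 3

    def test_site_free_data_has_small_auc_spread(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, 5)) + 2.5 * y[:, None]
        sites = rng.choice(["a", "b", "c", "d"], n)
        df = grouped_split_harness(
            X, y,
            {"healthy": np.where(y == 0, sites, None),
             "cancer": np.where(y == 1, sites, None)},
            self._fit_score,
        )
        assert df["test_auc"].max() - df["test_auc"].min() < 0.1

    def test_repeated_split_deterministic_and_single_repeat(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, 4)) + y[:, None]
        a = repeated_split_harness(X, y, self._fit_score, n_repeats=3, seed=5)
        b = repeated_split_harness(X, y, self._fit_score, n_repeats=3, seed=5)
        pd.testing.assert_frame_equal(a, b)
        one = repeated_split_harness(X, y, self._fit_score, n_repeats=1, seed=5)
        assert len(one) == 1
        assert one.loc[0, "test_auc"] == a.loc[0, "test_auc"]

    def test_strong_signal_interquartile_range_small(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, 5)) + 3 * y[:, None]
        df = repeated_split_harness(X, y, self._fit_score, n_repeats=30, seed=1)
        q1, q3 = df["test_auc"].quantile([0.25, 0.75])
        assert q3 - q1 < 0.05


class TestScoredCohort:
    def test_score_bounds_validated(self):
        with pytest.raises(ValueError):
            ScoredCohort(["a"], ["healthy"], np.array([1.2]))
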