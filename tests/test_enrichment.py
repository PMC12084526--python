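"""Logistic enrichment fitting: contingency oracle, statsmodels cross-check,
separation/Firth path, clustered errors, Bonferroni flags."""

import math

import numpy as np
import pytest

import drugsea as ds
from drugsea.enrichment import (
    DegenerateDataError,
    bonferroni_adjust,
    fit_enrichment,
    fit_enrichment_clustered,
    fit_logistic_firth,
)


def rows_from_arrays(y, x2, x1=None, classes=None):
    x1 = np.ones_like(np.asarray(y)) if x1 is None else x1
    return [ds.DesignRow(
        drug_id=f"d{i}", y=int(y[i]), x1=int(x1[i]), x2=float(x2[i]),
        implicated_targets=frozenset({"g"}) if x2[i] else frozenset(),
        class_label=None if classes is None else classes[i])
        for i in range(len(y))]


def two_by_two(a, b, c, d):
    """Rows for a 2x2 table: a=(y1,x1), b=(y1,x0), c=(y0,x1), d=(y0,x0)."""
    y = [1] * (a + b) + [0] * (c + d)
    x2 = [1] * a + [0] * b + [1] * c + [0] * d
    return rows_from_arrays(y, x2)


class TestContingencyOracle:
    def test_hand_counted_table(self):
        # treatments: 2 overlap / 1 not; non-treatments: 1 overlap / 6 not
        res = fit_enrichment(two_by_two(2, 1, 1, 6), include_x1=False)
        assert res.or2 == pytest.approx((2 * 6) / (1 * 1), rel=1e-6)
        assert res.n_overlap_treat == 2 and res.n_overlap_nontreat == 1

    def test_random_tables_match_cross_product(self):
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 60:
            a, b, c, d = rng.integers(1, 40, size=4)
            res = fit_enrichment(two_by_two(a, b, c, d), include_x1=False)
            assert res.or2 == pytest.approx((a * d) / (b * c), rel=1e-6)
            checked += 1

    def test_null_case_flat(self):
        # same overlap rate in both outcome groups, balanced
        res = fit_enrichment(two_by_two(10, 10, 10, 10), include_x1=False)
        assert abs(res.beta2) < 1e-6 and res.wald_p > 0.5


class TestAgainstStatsmodels:
    def test_coefficients_and_ses_match(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 400
        x1 = rng.integers(1, 20, size=n)
        x2 = (rng.uniform(size=n) < 0.3).astype(float)
        eta = -1.5 + 0.05 * x1 + 0.8 * x2
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        res = fit_enrichment(rows_from_arrays(y, x2, x1))
        X = sm.add_constant(np.column_stack([x1, x2]))
        ref = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10)
        assert res.beta0 == pytest.approx(ref.params[0], abs=1e-6)
        assert res.beta1 == pytest.approx(ref.params[1], abs=1e-6)
        assert res.beta2 == pytest.approx(ref.params[2], abs=1e-6)
        assert res.se2 == pytest.approx(ref.bse[2], rel=1e-5)
        assert res.wald_p == pytest.approx(ref.pvalues[2], rel=1e-4)

    def test_estimates_invariant_to_row_permutation(self):
        rng = np.random.default_rng(9)
        y = (rng.uniform(size=100) < 0.3).astype(int)
        x2 = (rng.uniform(size=100) < 0.4).astype(float)
        x1 = rng.integers(1, 10, size=100)
        rows = rows_from_arrays(y, x2, x1)
        shuffled = list(rows)
        rng.shuffle(shuffled)
        a, b = fit_enrichment(rows), fit_enrichment(shuffled)
        assert a.beta2 == pytest.approx(b.beta2, abs=1e-10)
        assert a.se2 == pytest.approx(b.se2, abs=1e-10)


class TestDegenerateInputs:
    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDataError, match="degenerate predictor"):
            fit_enrichment(rows_from_arrays([0, 1, 0, 1], [1, 1, 1, 1]))

    def test_one_class_outcome_rejected(self):
        with pytest.raises(DegenerateDataError, match="constant"):
            fit_enrichment(rows_from_arrays([1, 1, 1], [0, 1, 0]))


class TestSeparation:
    def test_perfect_separation_flagged_and_finite(self):
        # every treatment overlaps, no non-treatment does
        y = [1] * 5 + [0] * 20
        x2 = [1] * 5 + [0] * 20
        res = fit_enrichment(rows_from_arrays(y, x2))
        assert res.separation_flag and res.fit_method == "firth"
        assert math.isfinite(res.or2) and res.or2 > 1
        assert math.isfinite(res.ci95[0]) and math.isfinite(res.ci95[1])
        assert 0 < res.wald_p <= 1

    def test_randomized_separation_suite_always_finite(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(20, 120))
            y = (rng.uniform(size=n) < rng.uniform(0.1, 0.5)).astype(int)
            if y.sum() in (0, n):
                continue
            x1 = rng.integers(1, 25, size=n)
            res = fit_enrichment(rows_from_arrays(y, y.copy(), x1))  # x2 == y
            assert res.fit_method == "firth" and res.separation_flag
            assert math.isfinite(res.beta2) and math.isfinite(res.se2)

    def test_firth_shrinks_relative_to_diverged_mle(self):
        y = [1] * 4 + [0] * 16
        x2 = np.array([1.0] * 4 + [0.0] * 16)
        X = np.column_stack([np.ones(20), x2])
        firth = fit_logistic_firth(X, np.array(y, dtype=float))
        assert firth.converged and abs(firth.beta[1]) < 15


class TestClustered:
    def _rows(self, seed=12, n=200, classes=8):
        rng = np.random.default_rng(seed)
        labels = [f"C{rng.integers(classes)}" for _ in range(n)]
        y = (rng.uniform(size=n) < 0.3).astype(int)
        x2 = (rng.uniform(size=n) < 0.4).astype(float)
        x1 = rng.integers(1, 12, size=n)
        return rows_from_arrays(y, x2, x1, labels)

    def test_singleton_clusters_equal_hc0(self):
        import statsmodels.api as sm

        rows = self._rows()
        for i, r in enumerate(rows):
            r.class_label = f"solo{i}"
        res = fit_enrichment_clustered(rows)
        y = np.array([r.y for r in rows])
        X = sm.add_constant(np.column_stack([[r.x1 for r in rows],
                                             [r.x2 for r in rows]]))
        ref = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10,
                                 cov_type="HC0")
        assert res.se2 == pytest.approx(ref.bse[2], rel=1e-6)

    def test_point_estimates_unchanged_by_clustering(self):
        rows = self._rows()
        plain, clustered = fit_enrichment(rows), fit_enrichment_clustered(rows)
        assert clustered.beta2 == pytest.approx(plain.beta2, abs=1e-12)
        assert clustered.se2 != pytest.approx(plain.se2)
        # duplicating every row into a 2-member cluster keeps estimates
        doubled = []
        for i, r in enumerate(rows):
            for copy in range(2):
                doubled.append(ds.DesignRow(f"{r.drug_id}_{copy}", r.y, r.x1, r.x2,
                                            r.implicated_targets, f"pair{i}"))
        res2 = fit_enrichment_clustered(doubled)
        assert res2.beta2 == pytest.approx(plain.beta2, abs=1e-8)

    def test_single_cluster_rejected(self):
        rows = self._rows()
        for r in rows:
            r.class_label = "only"
        with pytest.raises(ValueError, match="single cluster"):
            fit_enrichment_clustered(rows)

    def test_within_class_correlation_inflates_se_on_average(self):
        # a shared class effect hits both the overlap propensity and the
        # outcome, so scores correlate within class and the naive variance
        # understates the truth; the sandwich should exceed it on average
        rng = np.random.default_rng(77)
        naive_ses, clus_ses = [], []
        for _ in range(200):
            n_class, per = 20, 10
            labels, x2, y = [], [], []
            for c in range(n_class):
                u = rng.normal()  # latent class effect
                p_overlap = 1 / (1 + np.exp(-u))
                p_case = 1 / (1 + np.exp(-(-0.8 + 1.2 * u)))
                for _ in range(per):
                    labels.append(f"C{c}")
                    x2.append(float(rng.uniform() < p_overlap))
                    y.append(int(rng.uniform() < p_case))
            try:
                naive = fit_enrichment(rows_from_arrays(y, x2, classes=labels))
                clus = fit_enrichment_clustered(rows_from_arrays(y, x2, classes=labels))
            except (DegenerateDataError, ValueError):
                continue
            naive_ses.append(naive.se2)
            clus_ses.append(clus.se2)
        assert np.mean(clus_ses) > np.mean(naive_ses)


class TestBonferroni:
    BASE = None

    def _result(self, p):
        from dataclasses import replace
        if TestBonferroni.BASE is None:
            TestBonferroni.BASE = fit_enrichment(two_by_two(8, 4, 4, 8), include_x1=False)
        return replace(TestBonferroni.BASE, wald_p=p)

    def test_threshold_and_adjusted_p(self):
        results = [self._result(0.01)] + [self._result(0.5)] * 7
        flagged = bonferroni_adjust(results, alpha=0.05)
        assert flagged[0].significant is False  # 0.01 > 0.05/8
        assert flagged[0].adjusted_p == pytest.approx(0.08)
        results = [self._result(1e-4)] + [self._result(0.5)] * 7
        flagged = bonferroni_adjust(results, alpha=0.05)
        assert flagged[0].significant is True
        assert flagged[0].adjusted_p == pytest.approx(8e-4)

    def test_single_test_is_identity(self):
        flagged = bonferroni_adjust([self._result(0.04)], alpha=0.05)
        assert flagged[0].significant is True
        assert flagged[0].adjusted_p == pytest.approx(0.04)
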