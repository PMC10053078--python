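"""Cohort summary, rank tests, clinical regressions and oncoprint ordering."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from arvc import cohort_stats as cs


def _clinical(n, rng, treatments=("docetaxel", "enzalutamide"), missing=0):
    frame = pd.DataFrame(
        {
            "patient_id": [f"S{i:03d}" for i in range(n)],
            "age_at_biopsy": rng.integers(46, 86, size=n).astype(float),
            "n_treatment_lines": rng.integers(1, 6, size=n).astype(float),
        }
    )
    for t in treatments:
        frame[t] = rng.integers(0, 2, size=n).astype(float)
    if missing:
        cols = ["n_treatment_lines", *treatments]
        frame.loc[frame.index[:missing], cols] = np.nan
    return frame


class TestCohortSummary:
    def test_percentages_match_hand_tally(self):
        rng = np.random.default_rng(0)
        clin = _clinical(60, rng, missing=10)
        summary = cs.cohort_summary(clin).set_index("characteristic")
        for t in ["docetaxel", "enzalutamide"]:
            vals = clin[t].dropna()
            assert summary.at[t, "n_evaluable"] == 50
            assert summary.at[t, "count"] == (vals == 1).sum()
            assert summary.at[t, "percent"] == round(100 * (vals == 1).mean(), 1)
        age = clin["age_at_biopsy"]
        assert summary.at["age_at_biopsy", "median"] == age.median()
        assert summary.at["age_at_biopsy", "min"] == age.min()

    def test_zero_evaluable_column_reports_missing_percent(self):
        clin = _clinical(5, np.random.default_rng(1))
        clin["cabazitaxel"] = np.nan
        summary = cs.cohort_summary(clin).set_index("characteristic")
        assert np.isnan(summary.at["cabazitaxel", "percent"])
        assert summary.at["cabazitaxel", "n_evaluable"] == 0

    def test_empty_table_gives_empty_summary(self):
        clin = _clinical(0, np.random.default_rng(2))
        summary = cs.cohort_summary(clin)
        assert (summary["n_evaluable"] == 0).all()


class TestSingleTreatmentSubset:
    def test_groups_and_retention(self):
        rng = np.random.default_rng(3)
        rows = []
        spec = [("docetaxel", 14), ("enzalutamide", 11), ("cabazitaxel", 3)]
        treatments = [t for t, _ in spec]
        i = 0
        for t, n in spec:
            for _ in range(n):
                row = {"patient_id": f"P{i:03d}", "age_at_biopsy": 60.0,
                       "n_treatment_lines": 1.0}
                row.update({u: float(u == t) for u in treatments})
                rows.append(row)
                i += 1
        # multi-treatment patients are excluded from the subset
        rows.append({"patient_id": "P999", "age_at_biopsy": 70.0,
                     "n_treatment_lines": 2.0,
                     **{u: 1.0 for u in treatments}})
        sizes, retained = cs.single_treatment_subset(pd.DataFrame(rows), min_group=10)
        assert sizes.sum() == 28
        assert dict(sizes) == {"docetaxel": 14, "enzalutamide": 11, "cabazitaxel": 3}
        assert set(retained["treatment_group"]) == {"docetaxel", "enzalutamide"}
        assert len(retained) == 25


def exact_mw_enumeration(x, y):
    """Independent oracle: two-sided p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum(np.sum(a > ys) + 0.5 * np.sum(a == ys) for a in xs)

    observed = u_stat(range(n))
    m = len(pooled)
    us = [u_stat(c) for c in itertools.combinations(range(m), n)]
    mean_u = len(x) * len(y) / 2.0
    dev = abs(observed - mean_u)
    p = np.mean([abs(u - mean_u) >= dev - 1e-12 for u in us])
    return observed, p


class TestMannWhitney:
    @pytest.mark.parametrize("sizes", [(3, 3), (6, 6), (4, 5)])
    def test_matches_exhaustive_enumeration(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        for _ in range(5):
            x = rng.normal(size=sizes[0])
            y = rng.normal(size=sizes[1])
            u, p = cs.mann_whitney(x, y)
            u_ref, p_ref = exact_mw_enumeration(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_minimal_p_when_groups_fully_separated_at_3_3(self):
        # all 20 assignments: the observed split is one of the 2 extremes
        u, p = cs.mann_whitney(np.array([10.0, 11, 12]), np.array([1.0, 2, 3]))
        assert u == 9.0
        assert p == pytest.approx(2 / 20)

    def test_identical_distributions_give_p_near_one(self):
        x = np.arange(20.0)
        u, p = cs.mann_whitney(x, x)
        assert p > 0.9

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            cs.mann_whitney(np.array([]), np.array([1.0]))


class TestAnyVariantComparison:
    def test_location_shift_detected_and_degenerate_status(self):
        rng = np.random.default_rng(4)
        samples = [f"S{i}" for i in range(60)]
        pos = pd.DataFrame({"V": [i < 30 for i in range(60)]}, index=samples)
        ar = pd.Series(
            np.r_[rng.normal(2.0, 1, 30), rng.normal(0.0, 1, 30)], index=samples
        )
        res = cs.any_variant_vs_ar_expression(ar, pos)
        assert res.status == "ok" and res.p < 0.001
        all_pos = pd.DataFrame({"V": [True] * 60}, index=samples)
        assert cs.any_variant_vs_ar_expression(ar, all_pos).status == "degenerate"

    def test_rejection_rate_under_location_shift_matches_monte_carlo_power(self):
        """Empirical rejection rate at alpha=0.05 for a fixed shift agrees
        with a Monte-Carlo estimate of the test's power within 3%."""
        rng = np.random.default_rng(5)
        n, shift, reps = 40, 0.8, 300
        samples = [f"S{i}" for i in range(2 * n)]
        pos = pd.DataFrame({"V": [i < n for i in range(2 * n)]}, index=samples)

        def reject(rng):
            ar = pd.Series(
                np.r_[rng.normal(shift, 1, n), rng.normal(0, 1, n)], index=samples
            )
            return cs.any_variant_vs_ar_expression(ar, pos).p < 0.05

        rate = np.mean([reject(rng) for _ in range(reps)])
        # independent oracle: t-test-free direct MC of the same statistic
        oracle_rng = np.random.default_rng(6)
        from scipy.stats import mannwhitneyu

        oracle = np.mean(
            [
                mannwhitneyu(
                    oracle_rng.normal(shift, 1, n), oracle_rng.normal(0, 1, n),
                    alternative="two-sided",
                ).pvalue
                < 0.05
                for _ in range(reps)
            ]
        )
        assert abs(rate - oracle) < 0.05


def bh_step_up(pvals):
    """Hand-computed Benjamini-Hochberg step-up oracle."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestPerCountGroups:
    def _frame(self, groups):
        rows, n_pos = [], {}
        i = 0
        for g, vals in groups.items():
            for v in vals:
                sid = f"S{i}"
                rows.append((sid, v))
                n_pos[sid] = g
                i += 1
        ar = pd.Series(dict(rows))
        return ar, pd.Series(n_pos)

    def test_single_comparison_q_equals_p(self):
        ar, npos = self._frame({0: [1.0, 2, 3, 8], 1: [4.0, 5, 6, 7]})
        out = cs.per_count_group_tests(ar, npos)
        assert len(out) == 1
        assert out.loc[0, "q"] == pytest.approx(out.loc[0, "p"])

    def test_q_values_match_step_up_oracle(self):
        rng = np.random.default_rng(7)
        groups = {k: rng.normal(k * 0.8, 1, 12) for k in range(4)}
        ar, npos = self._frame(groups)
        out = cs.per_count_group_tests(ar, npos)
        ok = out[out["status"] == "ok"]
        assert len(ok) == 6
        np.testing.assert_allclose(ok["q"].to_numpy(), bh_step_up(ok["p"].to_numpy()))
        # BH never shrinks below p and is monotone in sorted-p order
        assert (ok["q"] >= ok["p"] - 1e-12).all()
        s = ok.sort_values("p")
        assert s["q"].is_monotonic_increasing

    def test_singleton_groups_skipped_with_notice(self):
        ar, npos = self._frame({0: [1.0, 2, 3], 1: [5.0], 2: [6.0, 7, 8]})
        out = cs.per_count_group_tests(ar, npos)
        skipped = out[out["status"] == "skipped"]
        assert set(zip(skipped["group_a"], skipped["group_b"])) == {(0, 1), (1, 2)}

    def test_permuted_labels_give_uniform_p(self):
        """Under label permutation the p-value distribution is uniform
        (KS test over 500 permutations at alpha=0.01)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(8)
        vals = rng.normal(size=30)
        samples = [f"S{i}" for i in range(30)]
        ar = pd.Series(vals, index=samples)
        ps = []
        for _ in range(500):
            labels = pd.Series(rng.permutation([0] * 15 + [1] * 15), index=samples)
            out = cs.per_count_group_tests(ar, labels)
            ps.append(out.loc[0, "p"])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestUnivariateScreen:
    def _pair(self, n, rng, noise=1.0, slope=0.0):
        clin = _clinical(n, rng)
        age = clin["age_at_biopsy"]
        y = slope * age + noise * rng.normal(size=n)
        rel = pd.DataFrame({"V": y.to_numpy()}, index=clin["patient_id"].to_numpy())
        return clin, rel

    def test_perfect_linear_fit_recovers_slope(self):
        rng = np.random.default_rng(9)
        clin, rel = self._pair(50, rng, noise=0.0, slope=0.3)
        out = cs.univariate_screen(clin, rel).set_index("covariate")
        row = out.loc["age_at_biopsy"]
        assert row["slope"] == pytest.approx(0.3, abs=1e-10)
        assert row["p"] < 1e-12 and row["significant"]

    def test_constant_covariate_flagged_inestimable(self):
        rng = np.random.default_rng(10)
        clin, rel = self._pair(30, rng)
        clin["docetaxel"] = 1.0
        out = cs.univariate_screen(clin, rel).set_index("covariate")
        assert out.loc["docetaxel", "status"] == "inestimable"
        assert not out.loc["docetaxel", "significant"]

    def test_two_point_dataset_inestimable(self):
        rng = np.random.default_rng(11)
        clin, rel = self._pair(2, rng)
        out = cs.univariate_screen(clin, rel)
        assert (out["status"] == "inestimable").all()

    def test_null_false_flag_rate_close_to_alpha(self):
        """Covariate independent of response: ~5% flagged at alpha=0.05."""
        rng = np.random.default_rng(12)
        flags = []
        for _ in range(300):
            clin, rel = self._pair(40, rng)
            out = cs.univariate_screen(clin, rel, covariates=["age_at_biopsy"])
            flags.append(bool(out["significant"].iloc[0]))
        assert abs(np.mean(flags) - 0.05) < 0.025

    def test_undefined_relative_expression_dropped(self):
        rng = np.random.default_rng(13)
        clin, rel = self._pair(40, rng)
        rel.iloc[:10, 0] = np.nan
        out = cs.univariate_screen(clin, rel)
        assert (out["n"] == 30).all()


class TestMultivariate:
    def test_single_feature_coincides_with_univariate(self):
        rng = np.random.default_rng(14)
        clin = _clinical(60, rng)
        y = 0.2 * clin["age_at_biopsy"] + rng.normal(size=60)
        rel = pd.DataFrame({"V": y.to_numpy()}, index=clin["patient_id"].to_numpy())
        uni = cs.univariate_screen(clin, rel, covariates=["age_at_biopsy"])
        multi = cs.multivariate_model(clin, rel, ["age_at_biopsy"])
        assert multi.loc[0, "coef"] == pytest.approx(uni.loc[0, "slope"])
        assert multi.loc[0, "p"] == pytest.approx(uni.loc[0, "p"])

    def test_all_zero_response_gives_zero_coefficients(self):
        rng = np.random.default_rng(15)
        clin = _clinical(30, rng)
        rel = pd.DataFrame({"V": np.zeros(30)}, index=clin["patient_id"].to_numpy())
        multi = cs.multivariate_model(clin, rel, ["age_at_biopsy", "docetaxel"])
        ok = multi[multi["status"] == "ok"]
        assert np.allclose(ok["coef"], 0.0)

    def test_collinear_feature_dropped_with_notice(self):
        rng = np.random.default_rng(16)
        clin = _clinical(40, rng)
        clin["age_copy"] = clin["age_at_biopsy"]
        y = rng.normal(size=40)
        rel = pd.DataFrame({"V": y}, index=clin["patient_id"].to_numpy())
        multi = cs.multivariate_model(clin, rel, ["age_at_biopsy", "age_copy"])
        assert (multi.loc[multi["feature"] == "age_copy", "status"]
                == "collinear-dropped").all()

    def test_true_covariate_retained_null_near_alpha(self):
        """With one strongly associated and one null covariate, the true one
        is retained almost always and the null near the nominal 5% rate."""
        rng = np.random.default_rng(17)
        true_kept, null_kept = [], []
        for _ in range(60):
            clin = _clinical(200, rng)
            y = 0.6 * clin["docetaxel"] + rng.normal(size=200)
            rel = pd.DataFrame({"V": y.to_numpy()}, index=clin["patient_id"].to_numpy())
            multi = cs.multivariate_model(
                clin, rel, ["docetaxel", "enzalutamide"]
            ).set_index("feature")
            true_kept.append(bool(multi.loc["docetaxel", "retained"]))
            null_kept.append(bool(multi.loc["enzalutamide", "retained"]))
        assert np.mean(true_kept) >= 0.9
        assert np.mean(null_kept) <= 0.2

    def test_unbiased_coefficient_recovery(self):
        """OLS estimates average to the true coefficients over seeds."""
        rng = np.random.default_rng(18)
        coefs = []
        for _ in range(200):
            clin = _clinical(80, rng)
            y = 0.25 * clin["age_at_biopsy"] - 0.5 * clin["docetaxel"] + rng.normal(size=80)
            rel = pd.DataFrame({"V": y.to_numpy()}, index=clin["patient_id"].to_numpy())
            multi = cs.multivariate_model(
                clin, rel, ["age_at_biopsy", "docetaxel"]
            ).set_index("feature")
            coefs.append((multi.loc["age_at_biopsy", "coef"],
                          multi.loc["docetaxel", "coef"]))
        coefs = np.array(coefs)
        for mean, se, truth in zip(
            coefs.mean(axis=0), coefs.std(axis=0, ddof=1) / np.sqrt(len(coefs)),
            (0.25, -0.5),
        ):
            assert abs(mean - truth) < 2 * se + 1e-9


class TestOncoprint:
    def test_hand_computed_binary_sort(self):
        pos = pd.DataFrame(
            {
                "A": [True, True, False, False],   # prevalence 2
                "B": [True, False, True, False],   # prevalence 2 (name tie-break)
                "C": [False, False, False, True],  # prevalence 1
            },
            index=["s1", "s2", "s3", "s4"],
        )
        sample_order, variant_order = cs.oncoprint_order(pos)
        assert variant_order == ["A", "B", "C"]
        # bit patterns in (A,B,C) order: s1=110, s2=100, s3=010, s4=001
        assert sample_order == ["s1", "s2", "s3", "s4"]

    def test_all_negative_preserves_id_order_under_tie_break(self):
        pos = pd.DataFrame(
            {"A": [False] * 3, "B": [False] * 3}, index=["s1", "s2", "s3"]
        )
        sample_order, _ = cs.oncoprint_order(pos)
        assert sample_order == ["s1", "s2", "s3"]

    def test_input_permutation_invariance(self):
        rng = np.random.default_rng(19)
        pos = pd.DataFrame(
            rng.random((12, 4)) < 0.4,
            index=[f"s{i}" for i in range(12)],
            columns=list("ABCD"),
        )
        base = cs.oncoprint_order(pos)
        shuffled = pos.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2
        )
        assert cs.oncoprint_order(shuffled) == base
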