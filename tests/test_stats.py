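"""Cohort statistics: bootstrap CIs, spline basis, trends, overlaps, regressions."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from afpanel.grouping import GroupAssignment, Participant
from afpanel.stats import (
    DEFAULT_AGE_BINS, StatsError, bootstrap_proportion_ci, fit_age_trend,
    gene_breakdown, group_covariate_table, prevalence_by_age, rcs_basis,
    syndrome_overlap, vus_burden_regression,
)


def _p(i, age, sex="female", **kw):
    return Participant(id=f"P{i:04d}", sex=sex, age_dx=age,
                       age_enroll=min(age + 2, 65), **kw)


def _a(i, group, quals=()):
    return GroupAssignment(f"P{i:04d}", group, tuple(quals))


class TestBootstrap:
    def test_exact_proportion_and_rounding(self):
        est = bootstrap_proportion_ci(20, 119, 10_000, seed=0)
        assert est.pct == 16.8
        assert est.ci_low <= est.pct <= est.ci_high

    def test_matches_exact_binomial_quantiles(self):
        # independent oracle: the resampled count is Binomial(n, k/n), so the
        # percentile CI must sit within one lattice step of the exact
        # binomial 2.5/97.5% quantiles
        n, k = 100, 50
        est = bootstrap_proportion_ci(k, n, 100_000, seed=5)
        lo_exact = scipy.stats.binom.ppf(0.025, n, k / n) / n * 100
        hi_exact = scipy.stats.binom.ppf(0.975, n, k / n) / n * 100
        assert abs(est.ci_low - lo_exact) <= 100 / n
        assert abs(est.ci_high - hi_exact) <= 100 / n

    def test_deterministic_given_seed(self):
        a = bootstrap_proportion_ci(20, 119, 10_000, seed=42)
        b = bootstrap_proportion_ci(20, 119, 10_000, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_degenerate_zero_numerator(self):
        est = bootstrap_proportion_ci(0, 100, 1000, seed=0)
        assert est.pct == est.ci_low == est.ci_high == 0.0

    def test_degenerate_full_numerator(self):
        est = bootstrap_proportion_ci(100, 100, 1000, seed=0)
        assert est.pct == est.ci_low == est.ci_high == 100.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StatsError):
            bootstrap_proportion_ci(5, 0)
        with pytest.raises(StatsError):
            bootstrap_proportion_ci(-1, 10)
        with pytest.raises(StatsError):
            bootstrap_proportion_ci(11, 10)


class TestPrevalenceByAge:
    def test_single_bin_equals_whole_cohort(self):
        people = [_p(i, 20 + (i % 40)) for i in range(100)]
        assigns = [_a(i, 1 if i < 13 else 4) for i in range(100)]
        out = prevalence_by_age(assigns, people, bins=[("all", 0, 66)], n_boot=2000)
        assert len(out) == 1
        assert out[0].numerator == 13 and out[0].denominator == 100
        assert out[0].pct == 13.0

    def test_bins_must_partition(self):
        people = [_p(0, 10), _p(1, 30)]
        with pytest.raises(StatsError, match="partition"):
            prevalence_by_age([_a(0, 4), _a(1, 4)], people,
                              bins=[("x", 20, 66)], n_boot=100)

    def test_empty_bin_rejected(self):
        people = [_p(0, 40), _p(1, 45)]
        assigns = [_a(0, 1), _a(1, 4)]
        with pytest.raises(StatsError, match="empty"):
            prevalence_by_age(assigns, people,
                              bins=[("young", 0, 30), ("old", 30, 66)], n_boot=100)

    def test_per_bin_seeds_differ_but_are_deterministic(self):
        people = [_p(i, age) for i, age in enumerate([25] * 50 + [45] * 50)]
        assigns = [_a(i, 1 if i % 10 == 0 else 4) for i in range(100)]
        bins = [("<30", 0, 30), ("30+", 30, 66)]
        r1 = prevalence_by_age(assigns, people, bins=bins, n_boot=2000, seed=3)
        r2 = prevalence_by_age(assigns, people, bins=bins, n_boot=2000, seed=3)
        assert [(e.ci_low, e.ci_high) for e in r1] == [(e.ci_low, e.ci_high) for e in r2]
        assert r1[0].seed != r1[1].seed


class TestRcsBasis:
    def test_shape_and_linear_column(self):
        x = np.linspace(0, 10, 50)
        B = rcs_basis(x, [2.0, 5.0, 8.0])
        assert B.shape == (50, 2)
        np.testing.assert_allclose(B[:, 0], x)

    def test_linear_in_the_tails(self):
        knots = [10.0, 30.0, 50.0]
        left = rcs_basis(np.array([0.0, 1.0, 2.0]), knots)[:, 1]
        np.testing.assert_allclose(left, 0.0)  # below first knot: pure linear
        xr = np.array([60.0, 61.0, 62.0, 63.0])
        right = rcs_basis(xr, knots)[:, 1]
        d2 = np.diff(right, 2)
        np.testing.assert_allclose(d2, 0.0, atol=1e-8)  # linear above last knot

    def test_too_few_knots_rejected(self):
        with pytest.raises(StatsError):
            rcs_basis(np.arange(5.0), [1.0, 2.0])


class TestFitAgeTrend:
    def _cohort(self, or_per_decade=1.5, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        ages = rng.integers(18, 66, size=n)
        beta = np.log(or_per_decade)
        x = -ages / 10.0
        alpha = -1.8
        p = 1 / (1 + np.exp(-(alpha + beta * x)))
        y = rng.random(n) < p
        people = [_p(i, int(a)) for i, a in enumerate(ages)]
        assigns = [_a(i, 1 if y[i] else 4) for i in range(n)]
        return people, assigns

    def test_recovers_known_or(self):
        people, assigns = self._cohort(or_per_decade=1.5, n=8000, seed=1)
        fit = fit_age_trend(assigns, people)
        assert fit.ci_low < 1.5 < fit.ci_high
        assert fit.or_per_decade == pytest.approx(1.5, rel=0.25)
        assert not fit.separation_flag

    def test_sign_convention_younger_more_findings(self):
        people, assigns = self._cohort(or_per_decade=1.8, n=8000, seed=2)
        fit = fit_age_trend(assigns, people)
        assert fit.or_per_decade > 1.0  # earlier diagnosis → higher odds

    def test_null_is_not_rejected_on_average(self):
        people, assigns = self._cohort(or_per_decade=1.0, n=3000, seed=3)
        fit = fit_age_trend(assigns, people)
        assert fit.p_value > 0.001
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_multivariable_includes_covariates(self):
        people, assigns = self._cohort(n=3000, seed=4)
        rng = np.random.default_rng(0)
        people = [
            Participant(id=p.id, sex="male" if rng.random() < 0.7 else "female",
                        age_dx=p.age_dx, age_enroll=p.age_enroll,
                        race="White" if rng.random() < 0.95 else "Black",
                        ethnicity="hispanic" if rng.random() < 0.05 else "non_hispanic")
            for p in people
        ]
        fit = fit_age_trend(assigns, people, model="multivariable")
        assert fit.model == "multivariable"
        assert np.isfinite(fit.or_per_decade)

    def test_multivariable_drops_constant_covariate_with_warning(self):
        people, assigns = self._cohort(n=2000, seed=7)  # all-female helper cohort
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_age_trend(assigns, people, model="multivariable")
        assert np.isfinite(fit.or_per_decade)

    def test_unknown_model_rejected(self):
        people, assigns = self._cohort(n=500, seed=5)
        with pytest.raises(StatsError):
            fit_age_trend(assigns, people, model="bayesian")

    def test_single_class_rejected(self):
        people = [_p(i, 40) for i in range(10)]
        assigns = [_a(i, 4) for i in range(10)]
        with pytest.raises(StatsError):
            fit_age_trend(assigns, people)

    def test_separation_flagged(self):
        # outcome perfectly separated by age
        people = [_p(i, 20 if i < 50 else 60) for i in range(100)]
        assigns = [_a(i, 1 if i < 50 else 4) for i in range(100)]
        fit = fit_age_trend(assigns, people)
        assert fit.separation_flag

    def test_spline_pvalues_returned(self):
        people, assigns = self._cohort(n=3000, seed=6)
        fit = fit_age_trend(assigns, people)
        assert 0.0 <= fit.spline_f_p_overall <= 1.0
        assert 0.0 <= fit.spline_f_p_nonlinear <= 1.0
        assert len(fit.knots) == 3


class TestSyndromeOverlap:
    def test_multi_gene_carrier_counted_once_per_syndrome(self, panel):
        assigns = [
            _a(0, 1, [("chr2-1-A-T", "TTN", "P"), ("chr2-2-A-T", "TTN", "P")]),
            _a(1, 1, [("chr14-1-A-T", "MYH7", "P")]),
            _a(2, 2),
        ]
        out = {s.syndrome: s for s in syndrome_overlap(assigns, panel)}
        assert out["DCM"].n_all_genes == 1  # the double-TTN carrier, once
        assert out["HCM"].n_all_genes == 1
        assert out["DCM"].n_major_genes == 1  # TTN definitive for DCM

    def test_major_restriction_drops_limited_genes(self, panel):
        # MYH6 is DCM-limited: counts for all-genes but not major-genes
        assigns = [_a(0, 1, [("chr14-1-A-T", "MYH6", "P")])]
        out = {s.syndrome: s for s in syndrome_overlap(assigns, panel)}
        assert out["DCM"].n_all_genes == 1
        assert out["DCM"].n_major_genes == 0

    def test_non_group1_ignored(self, panel):
        assigns = [_a(0, 2, [("chr14-1-A-T", "MYH7", "VUS")])]
        out = syndrome_overlap(assigns, panel)
        assert all(s.n_all_genes == 0 for s in out)


class TestGeneBreakdown:
    def _fixture_frames(self):
        classified = pd.DataFrame(
            {
                "participant_id": ["P0000", "P0001", "P0001", "P0002", "P0003"],
                "gene": ["TTN", "TTN", "MYH7", "HFE", "MYH7"],
                "variant_id": [f"chr1-{i + 1}-A-T" for i in range(5)],
                "zygosity": ["het"] * 5,
                "coarse_tier": ["P", "P", "VUS", "P", "VUS"],
            }
        )
        people = [_p(0, 30), _p(1, 40), _p(2, 50), _p(3, 60)]
        assigns = [
            _a(0, 1, [("chr1-1-A-T", "TTN", "P")]),
            _a(1, 1, [("chr1-2-A-T", "TTN", "P")]),
            _a(2, 3, [("chr1-4-A-T", "HFE", "P")]),
            _a(3, 2, [("chr1-5-A-T", "MYH7", "VUS")]),
        ]
        return classified, assigns, people

    def test_dominant_category(self, panel):
        classified, assigns, people = self._fixture_frames()
        out = gene_breakdown(classified, assigns, people, panel, "dominant_plp")
        assert out.loc[0, "gene"] == "TTN"
        assert out.loc[0, "n_variants"] == 2
        assert out.loc[0, "pct_of_category"] == 100.0
        assert out.loc[0, "age_dx_median"] == 35.0

    def test_vus_category_counts_all_participants(self, panel):
        classified, assigns, people = self._fixture_frames()
        out = gene_breakdown(classified, assigns, people, panel, "vus")
        assert out["n_variants"].sum() == 2
        assert set(out["gene"]) == {"MYH7"}

    def test_recessive_category(self, panel):
        classified, assigns, people = self._fixture_frames()
        out = gene_breakdown(classified, assigns, people, panel, "recessive_plp")
        assert out["gene"].tolist() == ["HFE"]

    def test_unknown_category_rejected(self, panel):
        classified, assigns, people = self._fixture_frames()
        with pytest.raises(StatsError):
            gene_breakdown(classified, assigns, people, panel, "benign")


class TestVusBurden:
    def test_recovers_exact_linear_relationship(self, panel):
        genes = ["TTN", "MYH7", "HFE", "KCNQ1", "RYR2", "FLNC"]
        counts = {g: 5.0 + 2.0 * panel.gene(g).transcript_length_kbp for g in genes}
        out = vus_burden_regression(counts, panel)
        assert out["beta_per_kbp"] == pytest.approx(2.0, abs=1e-9)
        assert out["intercept"] == pytest.approx(5.0, abs=1e-8)
        assert out["excess_table"]["excess"].abs().max() < 1e-8

    def test_excess_table_orders_by_residual(self, panel):
        genes = ["TTN", "MYH7", "HFE", "KCNQ1"]
        counts = {g: 1.0 + 1.0 * panel.gene(g).transcript_length_kbp for g in genes}
        counts["MYH7"] += 50  # inject an excess
        out = vus_burden_regression(counts, panel)
        assert out["excess_table"].loc[0, "gene"] == "MYH7"

    def test_needs_three_genes(self, panel):
        with pytest.raises(StatsError):
            vus_burden_regression({"TTN": 10, "MYH7": 5}, panel)


class TestCovariateTable:
    def test_fixture_counts_and_test_columns(self, cohort, assignments):
        df = group_covariate_table(cohort.participants, assignments)
        male = df[df.covariate == "male"].iloc[0]
        assert male["group1"].startswith("89 ")
        assert male["group2"].startswith("594 ")
        assert 0 <= male["p_value"] <= 1
        age = df[df.covariate == "age_dx"].iloc[0]
        assert age["summary"] == "median (IQR)"

    def test_hf_enrichment_detected_in_fixture(self, cohort, assignments):
        df = group_covariate_table(cohort.participants, assignments)
        hf = df[df.covariate == "hf"].iloc[0]
        # group 1: 36/131 = 27.5% vs ~15% elsewhere
        assert hf["group1"] == "36 (27.5)"
        assert hf["p_value"] < 0.01

    def test_constant_covariate_skipped_with_warning(self):
        people = [_p(i, 40, sex="female") for i in range(20)]
        assigns = [_a(i, 1 if i < 5 else 4) for i in range(20)]
        with pytest.warns(UserWarning, match="male"):
            df = group_covariate_table(people, assigns)
        assert "male" not in set(df["covariate"])
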