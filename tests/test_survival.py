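import math

import numpy as np
import pandas as pd
import pytest
from lifelines.exceptions import ConvergenceWarning
from scipy import integrate, stats

from cbcprs.survival import (
    AGE_GROUPS,
    assign_bands,
    compute_percentile_bands,
    fit_age_group_models,
    fit_cox_categorical,
    fit_cox_continuous,
    fit_interaction,
    harrell_c,
    km_cumulative_risk,
    predict_band_hrs,
    rcs_basis,
    rcs_linearity_check,
    schoenfeld_ph_test,
)
from tests.conftest import make_intervals


def simple_df(n, t, event, z, entry=0.01):
    return pd.DataFrame(
        {
            "entry": entry,
            "exit": t,
            "event": event,
            "stratum": "s",
            "cluster": [f"f{i}" for i in range(n)],
            "z": z,
            "age_bc1": 40.0,
            "birth_year": 1950,
            "birth_cohort_q": "Q1",
        }
    )


class TestContinuousFit:
    def test_null_effect_under_permutation(self, midsize_intervals):
        iv = midsize_intervals.copy()
        rng = np.random.default_rng(5)
        iv["z"] = rng.permutation(iv["z"].to_numpy())
        fit = fit_cox_continuous(iv)
        assert abs(fit.coefficients["z"]) < 3 * fit.robust_se["z"]

    def test_recovers_generative_hazard_ratio(self):
        # mean over replicates within 3 Monte-Carlo SEs of log(1.5)
        betas = [
            fit_cox_continuous(
                make_intervals(4000, seed=100 + r, beta_true=math.log(1.5))
            ).coefficients["z"]
            for r in range(5)
        ]
        se = np.std(betas, ddof=1) / math.sqrt(len(betas))
        assert abs(np.mean(betas) - math.log(1.5)) < 3 * se

    def test_duplication_leaves_cluster_robust_se_unchanged(self):
        iv = make_intervals(1500, seed=31)
        dup = pd.concat([iv, iv], ignore_index=True)
        f1, f2 = fit_cox_continuous(iv), fit_cox_continuous(dup)
        f1n = fit_cox_continuous(iv, robust=False)
        f2n = fit_cox_continuous(dup, robust=False)
        # same estimate (up to the Efron tie correction on duplicated times)
        assert f2.coefficients["z"] == pytest.approx(f1.coefficients["z"], abs=0.01)
        # cluster sandwich is invariant; naive SE shrinks by 1/sqrt(2)
        assert f2.robust_se["z"] == pytest.approx(f1.robust_se["z"], rel=0.02)
        assert f2n.robust_se["z"] / f1n.robust_se["z"] == pytest.approx(
            1 / math.sqrt(2), rel=0.01
        )

    def test_strata_relabelling_invariance(self, midsize_intervals):
        iv = midsize_intervals.copy()
        f1 = fit_cox_continuous(iv)
        mapping = {s: f"X{s}" for s in iv["stratum"].unique()}
        iv["stratum"] = iv["stratum"].map(mapping)
        f2 = fit_cox_continuous(iv)
        assert f2.coefficients["z"] == pytest.approx(f1.coefficients["z"], abs=1e-10)

    def test_no_events_rejected(self):
        df = simple_df(10, np.arange(1, 11.0), np.zeros(10, int), np.zeros(10))
        with pytest.raises(ValueError):
            fit_cox_continuous(df)

    def test_separable_data_reports_nonconvergence(self):
        rng = np.random.default_rng(2)
        z = np.concatenate([np.ones(20), -np.ones(20)])
        t = np.concatenate([rng.uniform(1.1, 2, 20), rng.uniform(3, 4, 20)])
        df = simple_df(40, t, np.ones(40, int), z)
        with pytest.warns(ConvergenceWarning):
            fit_cox_continuous(df, adjust_birth_cohort=False)


class TestPercentileBands:
    def test_rank_data_band_assignment(self):
        bands = compute_percentile_bands(np.arange(1.0, 101.0))
        label = assign_bands(np.array([50.5]), bands)[0]
        assert label == "40-60"

    def test_extreme_scores_fall_in_top_band(self):
        bands = compute_percentile_bands(np.arange(1.0, 101.0))
        labels = assign_bands(np.array([150.0, 200.0]), bands)
        assert set(labels) == {"95-100"}

    def test_normal_quantile_edges(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal(200_000)
        bands = compute_percentile_bands(z)
        expected = stats.norm.ppf(np.array(bands.percentiles) / 100)
        np.testing.assert_allclose(bands.edges, expected, atol=0.02)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            compute_percentile_bands(np.arange(50.0))

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            compute_percentile_bands(np.zeros(1000))


class TestCategoricalFit:
    def test_reference_band_not_among_terms(self, midsize_intervals):
        iv = midsize_intervals
        bands = compute_percentile_bands(iv.loc[iv["event"] == 0, "z"].to_numpy())
        fit = fit_cox_categorical(iv, bands)
        assert not any("40_60" in t for t in fit.coefficients)

    def test_null_effect_band_hrs_near_one(self, null_intervals):
        iv = null_intervals
        bands = compute_percentile_bands(iv.loc[iv["event"] == 0, "z"].to_numpy())
        fit = fit_cox_categorical(iv, bands)
        for term, hr in fit.hr.items():
            if term.startswith("band_"):
                lo, hi = fit.ci95_low[term], fit.ci95_high[term]
                assert lo < 1.0 < hi or abs(math.log(hr)) < 3.5 * fit.robust_se[term]


class TestPredictedBandHrs:
    def test_zero_beta_gives_unit_hrs(self):
        bands = compute_percentile_bands(np.arange(1.0, 101.0))
        assert all(v == pytest.approx(1.0) for v in predict_band_hrs(0.0, bands).values())

    def test_matches_quadrature_oracle(self):
        # independent oracle: direct numerical integration of e^{beta z} phi(z)
        beta = math.log(1.12)
        bands = compute_percentile_bands(np.arange(1.0, 101.0))
        top = integrate.quad(
            lambda x: math.exp(beta * x) * stats.norm.pdf(x), 1.6449, 10
        )[0] / 0.05
        ref = integrate.quad(
            lambda x: math.exp(beta * x) * stats.norm.pdf(x), -0.2533, 0.2533
        )[0] / (stats.norm.cdf(0.2533) - stats.norm.cdf(-0.2533))
        expected = top / ref
        got = predict_band_hrs(beta, bands)["95-100"]
        assert got == pytest.approx(expected, abs=1e-3)
        assert got == pytest.approx(1.26, abs=0.01)

    def test_reflection_symmetry(self):
        # z -> -z maps the bottom band onto the top band and negates beta,
        # and the reference band is symmetric, so the HRs coincide exactly
        bands = compute_percentile_bands(np.arange(1.0, 101.0))
        beta = 0.3
        hr_pos = predict_band_hrs(beta, bands)
        hr_neg = predict_band_hrs(-beta, bands)
        assert hr_pos["0-5"] == pytest.approx(hr_neg["95-100"], rel=1e-9)


class TestInteractionAndSubgroups:
    def test_null_interaction(self, midsize_intervals):
        fit = fit_interaction(midsize_intervals)
        assert abs(fit.coefficients["z_age"]) < 3 * fit.robust_se["z_age"]

    def test_age_group_boundaries(self):
        # age exactly 40 belongs to 40-50; exactly 50 to >=50
        assert AGE_GROUPS[1][1] <= 40 < AGE_GROUPS[1][2]
        assert AGE_GROUPS[2][1] <= 50
        iv = make_intervals(2000, seed=33)
        iv = iv.copy()
        iv.loc[iv.index[:50], "age_bc1"] = 40.0
        iv.loc[iv.index[50:100], "age_bc1"] = 50.0
        fits = fit_age_group_models(iv)
        n_by_group = {g: f.n_subjects for g, f in fits.items()}
        mid = ((iv["age_bc1"] >= 40) & (iv["age_bc1"] < 50)).sum()
        old = (iv["age_bc1"] >= 50).sum()
        assert n_by_group["40-50"] == mid
        assert n_by_group[">=50"] == old

    def test_negative_interaction_orders_age_group_hrs(self):
        # strong negative age interaction: per-group HRs decrease with age
        iv = make_intervals(
            30_000, seed=34, beta_true=1.2, gamma_true=-0.025
        )
        fits = fit_age_group_models(iv)
        hrs = [fits[g].hr["z"] for g in ("<40", "40-50", ">=50")]
        assert hrs[0] > hrs[1] > hrs[2]


class TestDiagnostics:
    def test_ph_p_value_in_unit_interval(self, midsize_intervals):
        fit = fit_cox_continuous(midsize_intervals)
        p = schoenfeld_ph_test(fit, midsize_intervals)
        assert 0.0 <= p <= 1.0

    def test_ph_test_detects_time_varying_effect(self):
        # lognormal accelerated-failure data violates proportional hazards
        rng = np.random.default_rng(1)
        n = 5000
        z = rng.standard_normal(n)
        t = np.exp(0.5 * rng.standard_normal(n) - 0.5 * z) + 0.02
        df = simple_df(n, t, np.ones(n, int), z)
        fit = fit_cox_continuous(df, adjust_birth_cohort=False)
        assert schoenfeld_ph_test(fit, df) < 0.01

    def test_ph_test_refuses_tiny_event_count(self):
        df = simple_df(12, np.arange(1.0, 13.0), np.ones(12, int), np.zeros(12))
        df.loc[5:, "event"] = 0
        fit_df = df.copy()
        fit_df["z"] = np.random.default_rng(0).standard_normal(12)
        fit = fit_cox_continuous(fit_df, adjust_birth_cohort=False)
        with pytest.raises(ValueError):
            schoenfeld_ph_test(fit, fit_df)

    def test_rcs_detects_quadratic_effect(self):
        rng = np.random.default_rng(3)
        n = 5000
        z = rng.standard_normal(n)
        t = rng.exponential(1 / np.exp(0.5 * z**2)) + 0.02
        df = simple_df(n, t, np.ones(n, int), z)
        assert rcs_linearity_check(df) < 0.01

    def test_rcs_accepts_linear_effect(self, midsize_intervals):
        assert rcs_linearity_check(midsize_intervals) > 0.001

    def test_rcs_basis_smoothness_and_tail_linearity(self):
        knots = np.array([-1.0, 0.0, 1.5])
        x = np.linspace(-4, 4, 8001)
        y = rcs_basis(x, knots)[:, 0]
        d2 = np.gradient(np.gradient(y, x), x)
        # second derivative continuous at the knots
        for k in knots:
            i = np.searchsorted(x, k)
            assert abs(d2[i + 2] - d2[i - 2]) < 0.05
        # linear (zero curvature) beyond the boundary knots
        assert np.allclose(d2[x < -1.5], 0.0, atol=1e-6)
        assert np.allclose(d2[x > 2.0], 0.0, atol=1e-6)


class TestHarrellC:
    def test_random_score_near_half(self, midsize_intervals):
        iv = midsize_intervals.copy()
        iv["noise"] = np.random.default_rng(4).standard_normal(len(iv))
        c = harrell_c(iv, score_col="noise")
        assert abs(c.c - 0.5) < 0.02

    def test_perfect_score_is_one(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(1.1, 20, 500)
        df = simple_df(500, t, np.ones(500, int), -t, entry=1.0)
        assert harrell_c(df).c == pytest.approx(1.0)

    def test_matches_scikit_survival_without_truncation(self):
        # independent implementation on plain right-censored data
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(7)
        n = 3000
        z = rng.standard_normal(n)
        t = rng.exponential(1 / np.exp(0.4 * z))
        cens = rng.exponential(1.5, n)
        obs = np.minimum(t, cens)
        ev = t <= cens
        df = simple_df(n, obs + 1.001, ev.astype(int), z, entry=1.0)
        mine = harrell_c(df).c
        ref = concordance_index_censored(ev, obs, z)[0]
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_cluster_bootstrap_ci_brackets_estimate(self, midsize_intervals):
        res = harrell_c(midsize_intervals, n_bootstrap=50, seed=1)
        lo, hi = res.ci95
        assert lo <= res.c <= hi

    def test_no_comparable_pairs_rejected(self):
        df = simple_df(3, [2.0, 3.0, 4.0], [0, 0, 0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            harrell_c(df)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        df = simple_df(
            4, [3.0, 5.0, 4.0, 6.0], [1, 1, 0, 0], np.zeros(4), entry=1.0
        )
        risk, _ = km_cumulative_risk(df, 6.0)
        assert risk == pytest.approx(0.625)

    def test_no_events_zero_risk(self):
        df = simple_df(5, [2.0, 3, 4, 5, 6], np.zeros(5, int), np.zeros(5), entry=1.0)
        risk, _ = km_cumulative_risk(df, 10.0)
        assert risk == 0.0

    def test_uncensored_matches_empirical_cdf(self):
        rng = np.random.default_rng(9)
        t = 1.0 + rng.exponential(5, 400)
        df = simple_df(400, t, np.ones(400, int), np.zeros(400), entry=1.0)
        risk, _ = km_cumulative_risk(df, 8.0)
        assert risk == pytest.approx((t <= 8.0).mean(), abs=1e-9)
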