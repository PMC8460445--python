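import math

import numpy as np
import pandas as pd
import pytest

from cbcprs.simulate import (
    DEFAULT_MISSINGNESS,
    SimulationConfig,
    generate_cohort,
    generate_families_genotypes,
    generate_variant_panel,
    inject_missingness,
    simulate_study,
)


class TestVariantPanel:
    def test_single_variant_boundary(self):
        panel = generate_variant_panel(1, seed=0)
        assert len(panel) == 1
        assert 0.01 < panel["eaf"].iloc[0] < 0.5
        assert panel["effect_allele"].iloc[0] != panel["other_allele"].iloc[0]

    def test_seed_determinism(self):
        a = generate_variant_panel(50, seed=7)
        b = generate_variant_panel(50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_raw_score_variance_rescaled_to_target(self):
        panel = generate_variant_panel(313, seed=1, variance_target=1.0)
        for col in ("weight_overall", "weight_erpos", "weight_erneg"):
            var = np.sum(2 * panel["eaf"] * (1 - panel["eaf"]) * panel[col] ** 2)
            assert abs(var - 1.0) < 1e-9

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ValueError):
            generate_variant_panel(0)


class TestGenotypes:
    def test_founder_allele_frequency_matches_panel(self):
        # rare variant: empirical EAF within 3 binomial SEs of the target
        panel = generate_variant_panel(1, seed=3)
        panel.loc[0, "eaf"] = 0.01
        n = 50_000
        geno, _ = generate_families_genotypes(
            panel, n, family_size_probs=(1.0, 0.0, 0.0), seed=5
        )
        freq = geno.to_numpy().mean() / 2
        se = math.sqrt(0.01 * 0.99 / (2 * n))
        assert abs(freq - 0.01) < 3 * se

    def test_hwe_genotype_proportions(self):
        panel = generate_variant_panel(1, seed=3)
        p = panel["eaf"].iloc[0]
        n = 20_000
        geno, _ = generate_families_genotypes(
            panel, n, family_size_probs=(1.0, 0.0, 0.0), seed=11
        )
        g = geno.to_numpy().ravel()
        for count, expected in [(0, (1 - p) ** 2), (1, 2 * p * (1 - p)), (2, p**2)]:
            obs = (g == count).mean()
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(obs - expected) < 3 * se

    def test_singletons_are_uncorrelated(self):
        panel = generate_variant_panel(1, seed=3)
        geno, fam = generate_families_genotypes(
            panel, 4000, family_size_probs=(1.0, 0.0, 0.0), seed=2
        )
        assert fam.nunique() == 4000
        g = geno.to_numpy().ravel()
        r = np.corrcoef(g[::2], g[1::2])[0, 1]
        assert abs(r) < 0.05

    def test_sibling_genotype_correlation_is_half(self):
        # full sibs share on average half their alleles
        panel = generate_variant_panel(1, seed=3)
        n_pairs = 6000
        geno, fam = generate_families_genotypes(
            panel, 2 * n_pairs, family_size_probs=(0.0, 1.0, 0.0), seed=9
        )
        g = geno.to_numpy().ravel()
        sib1, sib2 = g[::2], g[1::2]
        r = np.corrcoef(sib1, sib2)[0, 1]
        assert abs(r - 0.5) < 3 / math.sqrt(n_pairs)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            generate_families_genotypes(
                generate_variant_panel(1).iloc[:0], 10, seed=0
            )


class TestCohort:
    def test_zero_age_sd_gives_constant_age(self):
        cfg = SimulationConfig(n_subjects=50, age_bc1_sd=0.0, seed=1)
        rec = generate_cohort(cfg, np.zeros(50))
        assert np.allclose(rec["age_bc1"], cfg.age_bc1_mean)

    def test_single_country_single_stratum(self):
        cfg = SimulationConfig(n_subjects=50, n_countries=1, seed=1)
        rec = generate_cohort(cfg, np.zeros(50))
        assert rec["country"].nunique() == 1

    def test_age_mean_matches_configuration(self):
        from scipy import stats

        cfg = SimulationConfig(n_subjects=20_000, seed=4)
        rec = generate_cohort(cfg, np.zeros(20_000))
        lo, hi = cfg.age_bc1_bounds
        a = (lo - cfg.age_bc1_mean) / cfg.age_bc1_sd
        b = (hi - cfg.age_bc1_mean) / cfg.age_bc1_sd
        expected = stats.truncnorm.mean(a, b, loc=cfg.age_bc1_mean, scale=cfg.age_bc1_sd)
        se = rec["age_bc1"].std() / math.sqrt(len(rec))
        assert abs(rec["age_bc1"].mean() - expected) < 3 * se


class TestEvents:
    def test_closed_form_event_fraction_without_censoring(self):
        # constant hazard, no effect, administrative horizon T:
        # event fraction = 1 - exp(-lambda * (T - 1))
        lam, horizon = 0.05, 11.0
        cfg = SimulationConfig(
            n_subjects=20_000,
            beta_true=0.0,
            hazard_rates=(lam,),
            baseline_lag_logmu=math.log(horizon - 1.0),
            baseline_lag_logsd=0.0,
            rrm_fraction=0.0,
            death_fraction=0.0,
            calibrate_events=False,
            seed=6,
        )
        rec = generate_cohort(cfg, np.zeros(20_000))
        frac = rec["age_cbc"].notna().mean()
        expected = 1 - math.exp(-lam * (horizon - 1.0))
        se = math.sqrt(expected * (1 - expected) / 20_000)
        assert abs(frac - expected) < 3 * se

    def test_event_fraction_calibration(self):
        cfg = SimulationConfig(n_subjects=10_000, target_event_fraction=0.21, seed=7)
        rec = generate_cohort(cfg, np.random.default_rng(0).standard_normal(10_000))
        se = math.sqrt(0.21 * 0.79 / 10_000)
        assert abs(rec["age_cbc"].notna().mean() - 0.21) < 3 * se

    def test_overflow_guard(self):
        cfg = SimulationConfig(n_subjects=100, gamma_true=10.0, seed=1)
        with pytest.raises(OverflowError):
            generate_cohort(cfg, np.full(100, 3.0))

    def test_event_times_respect_delayed_entry(self):
        cfg = SimulationConfig(n_subjects=5000, seed=8)
        rec = generate_cohort(cfg, np.zeros(5000))
        cbc = rec.dropna(subset=["age_cbc"])
        assert (cbc["age_cbc"] - cbc["age_bc1"] >= 1.0).all()


class TestMissingness:
    def test_rate_zero_is_identity(self):
        cfg = SimulationConfig(n_subjects=200, seed=2)
        rec = generate_cohort(cfg, np.zeros(200))
        out, _ = inject_missingness(rec, {"er_bc1": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, rec)

    def test_rate_one_blanks_everything(self):
        cfg = SimulationConfig(n_subjects=200, seed=2)
        rec = generate_cohort(cfg, np.zeros(200))
        out, _ = inject_missingness(rec, {"er_bc1": 1.0}, seed=1)
        assert (out["er_bc1"] == "unknown").all()

    def test_mcar_rate_recovered(self):
        n = 5189
        cfg = SimulationConfig(n_subjects=n, seed=2)
        rec = generate_cohort(cfg, np.zeros(n))
        out, truth = inject_missingness(rec, {"er_bc1": 0.56}, seed=3)
        frac = (out["er_bc1"] == "unknown").mean()
        assert abs(frac - 0.56) < 0.02
        # hidden truth channel retains the original values
        masked = out["er_bc1"] == "unknown"
        assert truth.loc[masked, "er_bc1"].isin(["negative", "positive"]).all()

    def test_invalid_rate_rejected(self):
        cfg = SimulationConfig(n_subjects=10, seed=2)
        rec = generate_cohort(cfg, np.zeros(10))
        with pytest.raises(ValueError):
            inject_missingness(rec, {"er_bc1": 1.5}, seed=1)


def test_full_study_seed_determinism():
    cfg = SimulationConfig(n_subjects=300, n_variants=20, seed=99)
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    pd.testing.assert_frame_equal(a["records"], b["records"])
    pd.testing.assert_frame_equal(a["genotypes"], b["genotypes"])
    pd.testing.assert_frame_equal(a["panel"], b["panel"])


def test_default_missingness_magnitudes_sane():
    assert set(DEFAULT_MISSINGNESS) >= {"er_bc1", "node_status", "cbc_er_status"}
    assert all(0 < v < 1 for v in DEFAULT_MISSINGNESS.values())
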