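"""Synthetic cohort generator: moment fidelity, determinism, copula."""

import numpy as np
import pandas as pd
import pytest

from gxepower import (
    CohortSpec,
    inject_missing_genotypes,
    simulate_activity,
    simulate_bmi,
    simulate_cohort,
    simulate_genotypes,
    simulate_grs_direct,
    simulate_multi_cohort,
)
from gxepower.cohort import DEFAULT_RISK_FREQS, latent_correlation
from gxepower.grs import PANEL_RSIDS, hwe_chisq


class TestGenotypes:
    def test_columns_follow_panel_order(self):
        geno = simulate_genotypes(10, seed=0)
        assert geno.loci == list(PANEL_RSIDS)
        assert geno.loci[0] == "rs1121980"  # FTO leads the panel

    def test_binomial_moments_and_hwe(self):
        n = 50_000
        geno = simulate_genotypes(n, freqs=[0.4] * 12, seed=1)
        dosage_se = np.sqrt(2 * 0.4 * 0.6 / n)
        means = geno.dosages.mean(axis=0)
        assert np.all(np.abs(means - 0.8) < 3 * dosage_se)
        counts = geno.genotype_counts()
        for locus in geno.loci:
            n0, n1, n2 = counts.loc[locus]
            _, p = hwe_chisq(int(n0), int(n1), int(n2))
            assert p > 0.001

    def test_extreme_frequency_boundary(self):
        geno = simulate_genotypes(5_000, freqs=[0.999999] + [0.5] * 11, seed=2)
        assert (geno.dosages.iloc[:, 0] == 2).mean() > 0.999

    def test_bad_frequency_names_locus(self):
        with pytest.raises(ValueError, match="rs7498665"):
            simulate_genotypes(10, freqs=[0.5, 1.5] + [0.5] * 10, seed=0)

    def test_default_frequencies_match_grs_moments(self):
        # arithmetic identity: sum 2f and sum 2f(1-f) of the default panel
        f = np.array(DEFAULT_RISK_FREQS)
        assert np.isclose((2 * f).sum(), 11.2, atol=1e-3)
        assert np.isclose((2 * f * (1 - f)).sum(), 5.06, atol=5e-3)


class TestDirectGRS:
    def test_zero_variance_is_constant(self):
        grs = simulate_grs_direct(100, mean=11.2, variance=0.0, seed=0)
        assert np.all(grs == 11.2)

    def test_moments_at_large_n(self):
        n = 100_000
        grs = simulate_grs_direct(n, 11.2, 5.06, seed=3)
        mean_se = np.sqrt(5.06 / n)
        assert abs(grs.mean() - 11.2) < 3 * mean_se
        var_se = 5.06 * np.sqrt(2 / (n - 1))
        assert abs(grs.var(ddof=1) - 5.06) < 3 * var_se

    def test_seed_determinism(self):
        a = simulate_grs_direct(1000, seed=7)
        b = simulate_grs_direct(1000, seed=7)
        c = simulate_grs_direct(1000, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            simulate_grs_direct(10, variance=-1.0)


class TestActivity:
    def test_independent_marginal(self):
        n = 100_000
        grs = simulate_grs_direct(n, seed=4)
        act = simulate_activity(grs, p_inactive=0.30, rho=0.0, seed=5)
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs((1 - act.mean()) - 0.30) < 3 * se
        assert abs(np.corrcoef(grs, act)[0, 1]) < 0.01

    def test_balanced_split_maximizes_variance(self):
        grs = simulate_grs_direct(200_000, seed=6)
        act = simulate_activity(grs, p_inactive=0.5, rho=0.0, seed=6)
        assert abs(act.var() - 0.25) < 0.003

    def test_copula_hits_target_correlation(self):
        n = 200_000
        grs = simulate_grs_direct(n, seed=8)
        act = simulate_activity(grs, p_inactive=0.30, rho=0.2, seed=9)
        assert abs(np.corrcoef(grs, act)[0, 1] - 0.2) < 0.02
        # marginal preserved despite correlation
        assert abs((1 - act.mean()) - 0.30) < 3 * np.sqrt(0.21 / n)

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            latent_correlation(0.9, 0.05)

    def test_empty_grs_rejected(self):
        with pytest.raises(ValueError):
            simulate_activity(np.array([]), 0.3, 0.0, 0)


class TestBMI:
    def test_noiseless_model_is_exact(self):
        spec = CohortSpec(n_participants=100, beta_ge=0.0, sigma_bmi=0.0, seed=0)
        grs = np.array([10.0, 12.0, 14.0])
        act = np.array([0.0, 1.0, 1.0])
        bmi = simulate_bmi(grs, act, spec, seed=0)
        expected = spec.intercept + spec.beta_g * grs + spec.beta_e * act
        assert np.allclose(bmi, expected)

    def test_defaults_carry_study_effect_sizes(self):
        spec = CohortSpec(n_participants=10)
        assert spec.beta_g == 0.154
        assert spec.beta_e == -0.313
        assert spec.sigma_bmi == 3.5

    def test_nonconformable_rejected(self):
        spec = CohortSpec(n_participants=10)
        with pytest.raises(ValueError):
            simulate_bmi(np.zeros(3), np.zeros(4), spec)


class TestMissingness:
    def test_rate_zero_identity(self, tiny_genotypes):
        out = inject_missing_genotypes(tiny_genotypes, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.dosages, tiny_genotypes.dosages)

    def test_rate_one_all_missing(self, tiny_genotypes):
        out = inject_missing_genotypes(tiny_genotypes, 1.0, seed=1)
        assert out.dosages.isna().all().all()

    def test_rate_recovered_at_scale(self):
        geno = simulate_genotypes(5_000, seed=10)
        out = inject_missing_genotypes(geno, 0.05, seed=11)
        frac = out.dosages.isna().mean().mean()
        se = np.sqrt(0.05 * 0.95 / (5_000 * 12))
        assert abs(frac - 0.05) < 3 * se


class TestCohortAndMultiCohort:
    def test_same_spec_same_seed_bitwise_identical(self):
        spec = CohortSpec(n_participants=2_000, seed=21)
        a, b = simulate_cohort(spec), simulate_cohort(spec)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = simulate_cohort(CohortSpec(n_participants=2_000, seed=22))
        assert not a.data["bmi"].equals(c.data["bmi"])

    def test_genotype_built_grs_in_allele_range(self):
        cohort = simulate_cohort(
            CohortSpec(n_participants=3_000, with_genotypes=True, seed=5))
        assert cohort.genotypes is not None
        assert cohort.data["grs"].between(0, 24).all()
        # moments inherit the HWE arithmetic identity sums
        assert abs(cohort.data["grs"].mean() - 11.2) < 0.15

    def test_cpai_consistent_with_binary(self, base_cohort):
        d = base_cohort.data
        assert ((d["activity_cpai"] == 1) == (d["activity_binary"] == 0)).all()

    def test_zero_between_cohort_sd_shares_effect(self):
        specs = [CohortSpec(n_participants=500, cohort_id=f"c{i}", seed=0)
                 for i in range(4)]
        cohorts = simulate_multi_cohort(specs, 0.0, master_seed=3)
        betas = {c.spec.beta_ge for c in cohorts}
        assert betas == {-0.07}
        assert len({c.spec.seed for c in cohorts}) == 4

    def test_large_consortium_sizes_supported(self):
        # 11 cohorts totalling the consortium's 111,421 participants
        sizes = [10_129] * 10 + [10_131]
        assert sum(sizes) == 111_421
        specs = [CohortSpec(n_participants=s, cohort_id=f"c{i}", seed=0)
                 for i, s in enumerate(sizes)]
        cohorts = simulate_multi_cohort(specs, 0.01, master_seed=1)
        assert sum(len(c) for c in cohorts) == 111_421

    def test_cohorts_reproducible_piecewise(self):
        specs = [CohortSpec(n_participants=300, cohort_id=f"c{i}", seed=0)
                 for i in range(3)]
        full = simulate_multi_cohort(specs, 0.0, master_seed=9)
        again = simulate_multi_cohort(specs, 0.0, master_seed=9)
        for a, b in zip(full, again):
            pd.testing.assert_frame_equal(a.data, b.data)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_multi_cohort([CohortSpec(n_participants=10)], -0.1)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_participants=0),
        dict(n_participants=10, p_inactive=0.0),
        dict(n_participants=10, grs_variance=0.0),
        dict(n_participants=10, sigma_bmi=-1.0),
        dict(n_participants=10, rho_grs_activity=1.0),
        dict(n_participants=10, beta_ge=float("nan")),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)
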