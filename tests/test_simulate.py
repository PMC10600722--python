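import numpy as np
import pytest

from triomr.simulate import (ScenarioConfig, apply_design, simulate_cohort,
                             simulate_parents, transmit)
from triomr.snps import replicate_panel
from tests.test_snps import make_snp


class TestSimulateParents:
    def test_column_mean_matches_hwe_expectation(self):
        snp = make_snp(eaf=0.5)
        G_m, G_f = simulate_parents(10_000, [snp], seed=1)
        se = np.sqrt(2 * 0.5 * 0.5 / 10_000)
        assert abs(G_m.mean() - 1.0) < 3 * se
        assert abs(G_f.mean() - 1.0) < 3 * se

    def test_rare_allele_limit_gives_zero_column(self):
        snp = make_snp(eaf=1e-9)
        G_m, _ = simulate_parents(10_000, [snp], seed=1)
        assert np.all(G_m == 0)

    def test_same_seed_is_deterministic(self, small_panel):
        a = simulate_parents(100, small_panel, seed=7)
        b = simulate_parents(100, small_panel, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rejects_empty_cohort(self, small_panel):
        with pytest.raises(ValueError):
            simulate_parents(0, small_panel, seed=1)


class TestTransmit:
    def test_homozygous_parents_force_offspring_genotype(self):
        G = np.full((50, 2), 2.0)
        assert np.all(transmit(G, G, seed=0) == 2.0)

    def test_het_by_ref_cross_transmits_half(self):
        G_m = np.full((20_000, 1), 1.0)
        G_f = np.zeros((20_000, 1))
        G_o = transmit(G_m, G_f, seed=3)
        se = 0.5 / np.sqrt(20_000)
        assert abs(G_o.mean() - 0.5) < 3 * se

    def test_allele_frequency_conserved_under_random_mating(self):
        snp = make_snp(eaf=0.3)
        G_m, G_f = simulate_parents(10_000, [snp], seed=5)
        G_o = transmit(G_m, G_f, seed=6)
        parental_eaf = (G_m.mean() + G_f.mean()) / 4
        se = np.sqrt(2 * 0.3 * 0.7 / 10_000) / 2
        assert abs(G_o.mean() / 2 - parental_eaf) < 3 * se

    def test_offspring_consistent_with_mendelian_transmission(self, small_panel):
        G_m, G_f = simulate_parents(500, small_panel, seed=9)
        G_o = transmit(G_m, G_f, seed=10)
        lo = (G_m == 2).astype(float) + (G_f == 2).astype(float)
        hi = (G_m > 0).astype(float) + (G_f > 0).astype(float)
        assert np.all(G_o >= lo) and np.all(G_o <= hi)

    def test_fractional_parental_genotypes_rejected(self):
        G = np.full((5, 1), 0.7)
        with pytest.raises(ValueError, match="fractional"):
            transmit(G, np.zeros((5, 1)), seed=0)


class TestScenarios:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_families=0)
        with pytest.raises(ValueError):
            ScenarioConfig(sib_fraction=1.5)
        with pytest.raises(ValueError):
            ScenarioConfig(missing_father_fraction=0.7, missing_mother_fraction=0.4)
        with pytest.raises(ValueError):
            ScenarioConfig(sigma_bw=0.0)

    def test_intrauterine_scenario_couples_maternal_score_to_outcome(self, mc_panel):
        cfg = ScenarioConfig.intrauterine_causal(
            n_families=50_000, seed=2, n_outcomes=1, item_level=False)
        cohort = simulate_cohort(mc_panel, cfg)
        s_m = cohort.latents["S_m_true"].to_numpy()
        y = cohort.liabilities.iloc[:, 0].to_numpy()
        cov = np.cov(s_m, y)[0, 1]
        # closed form: delta_U_ndd * gamma_mU * var(S_m)
        expected = 0.5 * 3.0 * s_m.var()
        assert cov > 0
        assert abs(cov - expected) < 0.3 * expected

    def test_pleiotropy_scenario_covariance_structure(self, mc_panel):
        cfg = ScenarioConfig.fetal_pleiotropic(
            n_families=50_000, seed=4, n_outcomes=1, item_level=False)
        cohort = simulate_cohort(mc_panel, cfg)
        s_o = cohort.latents["S_o_fetal"].to_numpy()
        # fetal-weighted maternal score, same weights as the causal offspring score
        s_m_fet = cohort.latents["S_m_true"]  # maternal-weighted; use G_m directly
        from triomr.simulate import true_scores
        s_m_fet = true_scores(cohort.G_m, mc_panel, "fetal")
        y = cohort.liabilities.iloc[:, 0].to_numpy()
        cov_o = np.cov(s_o, y)[0, 1]
        cov_m = np.cov(s_m_fet, y)[0, 1]
        assert cov_o < 0  # theta_pleio = -1
        # transmission induces exactly half the offspring covariance
        assert abs(cov_m - 0.5 * cov_o) < 0.15 * abs(cov_o)

    def test_null_scenario_outcomes_are_pure_noise(self, mc_panel):
        cfg = ScenarioConfig.null(n_families=20_000, seed=6, n_outcomes=1,
                                  item_level=False)
        cohort = simulate_cohort(mc_panel, cfg)
        y = cohort.liabilities.iloc[:, 0].to_numpy()
        for col in ("S_m_true", "S_o_fetal", "S_f_fetal"):
            r = np.corrcoef(cohort.latents[col], y)[0, 1]
            assert abs(r) < 3 / np.sqrt(len(y))


class TestApplyDesign:
    def test_no_missingness_keeps_all_trios(self, null_cohort, small_panel):
        cfg = ScenarioConfig.null(n_families=100, seed=1)
        cohort = simulate_cohort(small_panel, cfg)
        out = apply_design(cohort, 0.0, 0.0, seed=2)
        assert np.all(np.asarray(out.design) == "trio")

    def test_design_counts_match_multinomial_expectation(self, small_panel):
        cfg = ScenarioConfig.null(n_families=10_000, seed=3)
        cohort = simulate_cohort(small_panel, cfg)
        out = apply_design(cohort, 0.3, 0.1, seed=4)
        n_trio = int((np.asarray(out.design) == "trio").sum())
        tol = 3 * np.sqrt(10_000 * 0.6 * 0.4)
        assert abs(n_trio - 6000) < tol

    def test_overlapping_fractions_rejected(self, null_cohort):
        with pytest.raises(ValueError, match="sum"):
            apply_design(null_cohort, 0.8, 0.4, seed=0)

    def test_same_seed_reproduces_cohort_exactly(self, small_panel):
        cfg = ScenarioConfig.null(n_families=200, seed=42, sib_fraction=0.2,
                                  missing_father_fraction=0.1, n_outcomes=2)
        a = simulate_cohort(small_panel, cfg)
        b = simulate_cohort(small_panel, cfg)
        assert np.array_equal(a.G_o, b.G_o)
        assert a.phenotypes.equals(b.phenotypes)
        assert np.array_equal(np.asarray(a.design), np.asarray(b.design))

    def test_siblings_share_parents(self, small_panel):
        cfg = ScenarioConfig.null(n_families=100, seed=5, sib_fraction=0.5)
        cohort = simulate_cohort(small_panel, cfg)
        assert cohort.n_children == 150
        fam = cohort.family_index
        for f in range(50):
            rows = np.flatnonzero(fam == f)
            assert len(rows) == 2
            assert np.array_equal(cohort.G_m[rows[0]], cohort.G_m[rows[1]])
            assert np.array_equal(cohort.G_f[rows[0]], cohort.G_f[rows[1]])
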