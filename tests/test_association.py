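import numpy as np
import pandas as pd
import pytest

from htcp.association import (
    AlleleCountTable,
    AssociationConfig,
    RankDeficiencyError,
    SeparationError,
    allelic_or_2x2,
    bonferroni,
    demographic_comparison,
    fit_logistic_additive,
    pool_and_associate,
    risk_allele_frequency,
    simulate_case_control_genotypes,
    wald_inference,
)
from htcp.genotypes import GenotypeDosageMatrix


def _binary_data(a, b, c, d):
    """Exposure/status vectors for a 2x2 (exposed/unexposed x case/control)."""
    dose = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    y = np.array([1.0] * (a + b) + [0.0] * (c + d))
    return dose, y


class TestRiskAlleleFrequency:
    def test_basic(self):
        assert risk_allele_frequency(np.array([2.0, 1, 1, 0])) == 0.5

    def test_all_zero(self):
        assert risk_allele_frequency(np.zeros(4)) == 0.0

    def test_fractional_dosages_and_missing(self):
        d = np.array([0.5, 1.5, np.nan])
        assert risk_allele_frequency(d) == pytest.approx(0.5)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            risk_allele_frequency(np.array([np.nan]))

    def test_binomial_sampling_recovery(self):
        rng = np.random.default_rng(0)
        p = 0.363
        draws = rng.binomial(2, p, size=10_000).astype(float)
        se = np.sqrt(p * (1 - p) / (2 * 10_000))
        assert abs(risk_allele_frequency(draws) - p) <= 3 * se


class TestLogisticFit:
    def test_unadjusted_or_equals_cross_product(self):
        dose, y = _binary_data(30, 20, 10, 40)
        fit = fit_logistic_additive(dose, y)
        beta, _ = fit.coef("dosage")
        assert np.exp(beta) == pytest.approx(6.0, rel=1e-8)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        age = rng.normal(70, 8, n)
        y = (rng.random(n) <
             1 / (1 + np.exp(-(-2 + 0.5 * g + 0.02 * age)))).astype(float)
        fit = fit_logistic_additive(g, y, covariates=age[:, None],
                                    covariate_names=["age"])
        X = sm.add_constant(np.column_stack([g, age]))
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-5)

    def test_complete_separation_diagnosed(self):
        with pytest.raises(SeparationError):
            fit_logistic_additive(np.array([2.0, 2, 2, 0, 0, 0]),
                                  np.array([1.0, 1, 1, 0, 0, 0]))

    def test_constant_dosage_is_rank_deficient(self):
        with pytest.raises(RankDeficiencyError):
            fit_logistic_additive(np.ones(10),
                                  np.array([1.0] * 5 + [0.0] * 5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_additive(np.array([0.0, 1]), np.array([1.0, 1]))

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, 200).astype(float)
        y = (rng.random(200) < 0.4).astype(float)
        perm = rng.permutation(200)
        b1, _ = fit_logistic_additive(g, y).coef("dosage")
        b2, _ = fit_logistic_additive(g[perm], y[perm]).coef("dosage")
        assert b1 == pytest.approx(b2, abs=1e-9)

    def test_dosage_beta_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(6)
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        age = rng.normal(70, 8, n)
        y = (rng.random(n) < 0.3).astype(float)
        b1, _ = fit_logistic_additive(g, y, age[:, None]).coef("dosage")
        b2, _ = fit_logistic_additive(g, y, (age[:, None] - 70) / 8).coef("dosage")
        assert b1 == pytest.approx(b2, abs=1e-7)

    def test_parameter_recovery_with_covariates(self):
        truth = np.log(2.0)
        m, ph = simulate_case_control_genotypes(
            2000, 2000, raf_population=0.3, or_per_allele=2.0, seed=77,
            covariate_model={"age": (70.0, 8.0, 0.03),
                             "sex": (0.5, 0.0, 0.4)})
        cov = ph[["age", "sex"]].to_numpy()
        y = (ph.status == "CASE").to_numpy(float)
        fit = fit_logistic_additive(m.dosages.iloc[:, 0].to_numpy(), y, cov,
                                    covariate_names=["age", "sex"])
        b, se = fit.coef("dosage")
        assert abs(b - truth) <= 3 * se


class TestWaldInference:
    def test_null_beta(self):
        or_, ci, p = wald_inference(0.0, 1.0)
        assert or_ == 1.0
        assert p == pytest.approx(1.0)
        assert ci[0] < 1.0 < ci[1]

    def test_recovers_se_from_published_interval(self):
        # invert the CI formula on the anchor OR 2.43 (1.55-3.79)
        se = (np.log(3.79) - np.log(1.55)) / (2 * 1.959963984540054)
        or_, ci, p = wald_inference(np.log(2.43), se)
        assert ci[0] == pytest.approx(1.55, abs=0.01)
        assert ci[1] == pytest.approx(3.79, abs=0.01)

    def test_p_monotone_in_z(self):
        ps = [wald_inference(b, 1.0)[2] for b in (0.5, 1.0, 2.0, 3.0)]
        assert ps == sorted(ps, reverse=True)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_inference(1.0, 0.0)


class TestAllelic2x2:
    def test_symmetric_table(self):
        or_, _, p = allelic_or_2x2(AlleleCountTable(10, 10, 10, 10))
        assert or_ == 1.0
        assert p == pytest.approx(1.0)

    def test_cross_product(self):
        or_, _, _ = allelic_or_2x2(AlleleCountTable(30, 20, 10, 40))
        assert or_ == pytest.approx(6.0)

    def test_zero_cell_continuity_correction(self):
        or_, ci, _ = allelic_or_2x2(AlleleCountTable(10, 5, 0, 12))
        assert np.isfinite(or_) and np.isfinite(ci[1])

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            allelic_or_2x2(AlleleCountTable(0, 0, 5, 5))

    def test_agrees_with_logistic_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b, c, d = rng.integers(3, 60, size=4)
            or_, _, _ = allelic_or_2x2(AlleleCountTable(a, b, c, d))
            dose, y = _binary_data(a, b, c, d)
            beta, _ = fit_logistic_additive(dose, y).coef("dosage")
            assert or_ == pytest.approx(np.exp(beta), rel=1e-6)


class TestBonferroni:
    def test_panel_threshold(self):
        assert bonferroni(0.05, 11) == pytest.approx(0.05 / 11)

    def test_single_test(self):
        assert bonferroni(0.05, 1) == 0.05

    def test_table_anchor_p_is_significant(self):
        assert 2.3e-4 < bonferroni(0.05, 11)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)

    def test_flagging_monotone_in_alpha(self):
        m, ph = simulate_case_control_genotypes(150, 300, 0.3, 2.0, seed=4)
        empty = GenotypeDosageMatrix(m.dosages.iloc[0:0], dict(m.risk_allele))
        hi = pool_and_associate(m, empty, ph,
                                AssociationConfig(covariates=(), m_tests=1))
        lo = pool_and_associate(m, empty, ph,
                                AssociationConfig(covariates=(), m_tests=1,
                                                  alpha=0.001))
        for r_hi, r_lo in zip(hi, lo):
            if r_lo.significant:
                assert r_hi.significant


class TestPoolAndAssociate:
    def _split(self, m, k):
        ids = m.sample_ids
        first = GenotypeDosageMatrix(m.dosages.loc[ids[:k]],
                                     dict(m.risk_allele))
        second = GenotypeDosageMatrix(m.dosages.loc[ids[k:]],
                                      dict(m.risk_allele))
        return first, second

    def test_merge_invariance(self):
        m, ph = simulate_case_control_genotypes(80, 160, 0.35, 2.0, seed=12)
        empty = GenotypeDosageMatrix(m.dosages.iloc[0:0], dict(m.risk_allele))
        whole = pool_and_associate(m, empty, ph,
                                   AssociationConfig(covariates=()))
        a, b = self._split(m, 100)
        halves = pool_and_associate(a, b, ph, AssociationConfig(covariates=()))
        assert whole[0].or_ == pytest.approx(halves[0].or_, rel=1e-12)
        assert whole[0].p == pytest.approx(halves[0].p, rel=1e-12)

    def test_overlapping_samples_error(self):
        m, ph = simulate_case_control_genotypes(20, 20, 0.3, 1.5, seed=13)
        with pytest.raises(ValueError, match="overlapping"):
            pool_and_associate(m, m, ph, AssociationConfig(covariates=()))

    def test_missing_dosage_reduces_that_snp_only(self):
        m, ph = simulate_case_control_genotypes(60, 120, 0.35, 2.0, seed=14)
        dos = m.dosages.copy()
        dos["snp2"] = dos["snp1"].to_numpy()
        dos.loc[dos.index[0], "snp2"] = np.nan  # one failed call at snp2
        m2 = GenotypeDosageMatrix(dos, {"snp1": "A", "snp2": "A"})
        empty = GenotypeDosageMatrix(dos.iloc[0:0], {"snp1": "A", "snp2": "A"})
        res = {r.snp_id: r for r in pool_and_associate(
            m2, empty, ph, AssociationConfig(covariates=(), m_tests=2))}
        assert res["snp1"].n_cases + res["snp1"].n_controls == 180
        assert res["snp2"].n_cases + res["snp2"].n_controls == 179
        assert res["snp2"].n_dropped_missing_dosage == 1

    def test_ancestry_filter_bookkeeping(self):
        """61 cases with 4 non-European + 167 controls with 25 -> 57/142."""
        m, ph = simulate_case_control_genotypes(61, 167, 0.363, 2.43, seed=15)
        ph["ancestry_european"] = True
        case_idx = ph.index[ph.status == "CASE"][:4]
        ctrl_idx = ph.index[ph.status == "CONTROL"][:25]
        ph.loc[case_idx, "ancestry_european"] = False
        ph.loc[ctrl_idx, "ancestry_european"] = False
        empty = GenotypeDosageMatrix(m.dosages.iloc[0:0], dict(m.risk_allele))
        res = pool_and_associate(m, empty, ph,
                                 AssociationConfig(covariates=()))
        assert res[0].n_cases == 57
        assert res[0].n_controls == 142

    def test_allelic_2x2_method(self):
        m, ph = simulate_case_control_genotypes(100, 200, 0.35, 2.0, seed=16)
        empty = GenotypeDosageMatrix(m.dosages.iloc[0:0], dict(m.risk_allele))
        res = pool_and_associate(
            m, empty, ph,
            AssociationConfig(covariates=(), method="allelic_2x2"))
        assert res[0].method == "allelic_2x2"
        assert res[0].or_ > 0


class TestGenotypeSimulator:
    def test_hwe_proportions(self):
        m, ph = simulate_case_control_genotypes(
            5000, 5000, 0.363, 1.0, seed=31)
        # with OR=1 the case/control genotypes are plain HWE draws
        g = m.dosages.iloc[:, 0].to_numpy()
        n = g.size
        p = 0.363
        for k, expected in [(0, (1 - p) ** 2), (1, 2 * p * (1 - p)),
                            (2, p ** 2)]:
            se = np.sqrt(n * expected * (1 - expected))
            assert abs((g == k).sum() - n * expected) <= 3 * se

    def test_null_beta_within_3se(self):
        m, ph = simulate_case_control_genotypes(500, 500, 0.3, 1.0, seed=32)
        y = (ph.status == "CASE").to_numpy(float)
        b, se = fit_logistic_additive(
            m.dosages.iloc[:, 0].to_numpy(), y).coef("dosage")
        assert abs(b) <= 3 * se

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_case_control_genotypes(10, 10, 1.2, 2.0, seed=1)
        with pytest.raises(ValueError):
            simulate_case_control_genotypes(10, 10, 0.3, -1.0, seed=1)

    def test_deterministic_given_seed(self):
        m1, p1 = simulate_case_control_genotypes(50, 50, 0.3, 2.0, seed=9)
        m2, p2 = simulate_case_control_genotypes(50, 50, 0.3, 2.0, seed=9)
        assert m1.dosages.equals(m2.dosages)
        assert p1.equals(p2)

    def test_planted_or_recovery_grid(self):
        # median estimated OR within 10% of truth across the planted grid
        for truth in (1.0, 1.5, 2.0, 2.76):
            ests = []
            for rep in range(30):
                m, ph = simulate_case_control_genotypes(
                    2000, 2000, 0.3, truth, seed=40_000 + rep)
                y = (ph.status == "CASE").to_numpy(float)
                b, _ = fit_logistic_additive(
                    m.dosages.iloc[:, 0].to_numpy(), y).coef("dosage")
                ests.append(np.exp(b))
            assert np.median(ests) == pytest.approx(truth, rel=0.10)


class TestDemographicComparison:
    def _pheno(self, rng, n_cases=150, n_controls=300, age_gap=0.0):
        return pd.DataFrame({
            "status": ["CASE"] * n_cases + ["CONTROL"] * n_controls,
            "age": np.concatenate([rng.normal(69.3 + age_gap, 8, n_cases),
                                   rng.normal(69.3, 8, n_controls)]),
            "smoking_ever": rng.integers(0, 2, n_cases + n_controls),
        })

    def test_identical_binary_proportions_give_p_one(self):
        df = pd.DataFrame({
            "status": ["CASE"] * 10 + ["CONTROL"] * 10,
            "smoking_ever": [0, 1] * 10,
        })
        out = demographic_comparison(df)
        row = out[out.variable == "smoking_ever"].iloc[0]
        assert row.p == pytest.approx(1.0)

    def test_planted_age_gap_detected(self):
        rng = np.random.default_rng(50)
        out = demographic_comparison(
            self._pheno(rng, n_cases=2000, n_controls=2000, age_gap=9.0))
        row = out[out.variable == "age"].iloc[0]
        assert row.p < 1e-10
        assert row.cases - row.controls == pytest.approx(9.0, abs=1.0)

    def test_chi2_equals_squared_two_proportion_z(self):
        from scipy import stats as ss

        df = pd.DataFrame({
            "status": ["CASE"] * 40 + ["CONTROL"] * 60,
            "smoking_ever": [1] * 25 + [0] * 15 + [1] * 20 + [0] * 40,
        })
        out = demographic_comparison(df)
        chi2 = out[out.variable == "smoking_ever"].iloc[0].statistic
        p1, p2, n1, n2 = 25 / 40, 20 / 60, 40, 60
        pool = 45 / 100
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert chi2 == pytest.approx(z ** 2)

    def test_zero_variance_is_undefined(self):
        df = pd.DataFrame({
            "status": ["CASE"] * 3 + ["CONTROL"] * 3,
            "bmi": [25.0] * 6,
        })
        out = demographic_comparison(df)
        assert not out[out.variable == "bmi"].iloc[0].defined
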