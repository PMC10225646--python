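"""Two-stage least squares and its sensitivity machinery."""

import numpy as np
import pytest

from gestmr.cohort import (
    CohortConfig,
    MetaboliteArchitecture,
    Relatedness,
    simulate_cohort,
    snp_ids,
)
from gestmr.instruments import Instrument, genetic_risk_score
from gestmr.mr import leave_one_out, refit_excluding, tsls, wu_hausman

from conftest import make_genotypes


class TestTsls:
    def test_exposure_as_own_instrument_degenerates_to_ols(self, rng):
        x = rng.standard_normal(200)
        y = 0.3 * x + rng.standard_normal(200)
        est = tsls(y, x, x)
        assert est.beta_iv == pytest.approx(est.ols_beta, abs=1e-12)
        assert est.wu_hausman_stat == 0.0 and est.wu_hausman_p == 1.0

    def test_tiny_worked_dataset_equals_ratio_oracle(self):
        """n = 8 fixture: β_IV must equal the hand-computable projected
        ratio cov(y, z)/cov(x, z) and the full 2SLS matrix formula."""
        y = np.array([2.1, 1.9, 3.2, 2.8, 4.0, 3.6, 5.1, 4.7])
        x = np.array([1.0, 0.8, 1.9, 1.7, 3.1, 2.9, 4.2, 3.8])
        z = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        est = tsls(y, x, z)
        yc, xc, zc = y - y.mean(), x - x.mean(), z - z.mean()
        ratio = (zc @ yc) / (zc @ xc)
        assert est.beta_iv == pytest.approx(ratio, abs=1e-10)
        # explicit projection-matrix 2SLS: (X'PzX)^-1 X'Pz y with intercept
        C = np.ones((8, 1))
        Zf = np.column_stack([z, C])
        W = np.column_stack([x, C])
        Pz = Zf @ np.linalg.inv(Zf.T @ Zf) @ Zf.T
        beta_mat = np.linalg.solve(W.T @ Pz @ W, W.T @ Pz @ y)[0]
        assert est.beta_iv == pytest.approx(beta_mat, abs=1e-10)

    def test_ci_contains_point_estimate_and_uses_observed_residuals(self, rng):
        z = rng.standard_normal(500)
        u = rng.standard_normal(500)
        x = 0.5 * z + u + rng.standard_normal(500)
        y = 0.2 * x + 0.8 * u + rng.standard_normal(500)
        est = tsls(y, x, z)
        lo, hi = est.ci95
        assert lo < est.beta_iv < hi
        assert hi - lo == pytest.approx(2 * 1.96 * est.se)

    def test_weight_rescaling_invariance(self, rng):
        X = rng.binomial(2, 0.3, size=(300, 3)).astype(float)
        geno = make_genotypes(X)
        x = X @ [0.2, 0.3, 0.1] + rng.standard_normal(300)
        y = 0.25 * x + rng.standard_normal(300)
        w = [("rs000001", 0.2, "A"), ("rs000002", 0.3, "A"), ("rs000003", 0.1, "A")]
        grs1 = genetic_risk_score(Instrument("m", "c", w), geno)
        w5 = [(s, 5 * b, a) for s, b, a in w]
        grs5 = genetic_risk_score(Instrument("m", "c", w5), geno)
        est1, est5 = tsls(y, x, grs1), tsls(y, x, grs5)
        assert est1.beta_iv == pytest.approx(est5.beta_iv, abs=1e-12)
        assert est1.se == pytest.approx(est5.se, abs=1e-12)

    def test_allele_flip_invariance(self, rng):
        X = rng.binomial(2, 0.4, size=(300, 2)).astype(float)
        geno = make_genotypes(X)
        x = X @ [0.3, 0.2] + rng.standard_normal(300)
        y = 0.2 * x + rng.standard_normal(300)
        a = Instrument("m", "c", [("rs000001", 0.3, "A"), ("rs000002", 0.2, "A")])
        # flipping an allele negates its weight and recodes dosage: same TSLS
        f = Instrument("m", "c", [("rs000001", -0.3, "G"), ("rs000002", 0.2, "A")])
        est_a = tsls(y, x, genetic_risk_score(a, geno))
        est_f = tsls(y, x, genetic_risk_score(f, geno))
        assert est_a.beta_iv == pytest.approx(est_f.beta_iv, abs=1e-12)

    def test_collinear_covariates_rejected(self, rng):
        z = rng.standard_normal(100)
        x = z + rng.standard_normal(100)
        y = x + rng.standard_normal(100)
        c = rng.standard_normal(100)
        with pytest.raises(ValueError):
            tsls(y, x, z, covariates=np.column_stack([c, 2 * c]))

    def test_confounded_recovery_beats_ols(self):
        """True β = 0.2 with confounding: TSLS CIs cover the truth while the
        OLS point estimate is materially biased (20 replicate cohorts)."""
        from gestmr.experiments import _fit_one_rep, _one_metabolite_config
        covered, ols_bias, iv_bias = 0, [], []
        for r in range(20):
            est = _fit_one_rep(_one_metabolite_config(3000, 4000 + r))
            lo, hi = est.ci95
            covered += lo <= 0.2 <= hi
            ols_bias.append(est.ols_beta - 0.2)
            iv_bias.append(est.beta_iv - 0.2)
        assert covered >= 17
        assert abs(np.mean(ols_bias)) > 3 * abs(np.mean(iv_bias))


class TestWuHausman:
    def test_exogenous_design_keeps_moderate_pvalues(self, rng):
        rej = 0
        for _ in range(200):
            z = rng.standard_normal(400)
            x = 0.4 * z + rng.standard_normal(400)
            y = 0.2 * x + rng.standard_normal(400)
            _, p = wu_hausman(y, x, z)
            rej += p < 0.05
        assert 1 <= rej <= 25  # ≈ 5% of 200 with slack

    def test_strong_confounding_detected(self, rng):
        ps = []
        for _ in range(20):
            z = rng.standard_normal(2000)
            u = rng.standard_normal(2000)
            x = 0.5 * z + u + 0.5 * rng.standard_normal(2000)
            y = 0.2 * x + u + 0.5 * rng.standard_normal(2000)
            _, p = wu_hausman(y, x, z)
            ps.append(p)
        assert np.median(ps) < 0.01


class TestSensitivity:
    def _instrumented_cohort(self, seed=77, pleiotropic=False):
        effects = [0.3, 0.3, 0.3, 0.3]
        arch = MetaboliteArchitecture(
            name="met", class_label="c",
            causal_snps=tuple(zip(snp_ids(4), effects)))
        pleio = (("rs000001", "fasting", 0.08),) if pleiotropic else ()
        cfg = CohortConfig(n_per_stratum=3000, m_snps=4, n_chromosomes=2,
                           strata=("SA",), maf_range_per_stratum={"SA": (0.3, 0.3)},
                           relatedness=Relatedness(0, 0.0), metabolites=(arch,),
                           causal_effects={"met": (0.1, 0.0)},
                           pleiotropy=pleio, seed=seed)
        geno, pheno, truth = simulate_cohort(cfg)["SA"]
        instr = Instrument("met", "c", [(s, e, "A") for s, e in zip(snp_ids(4), effects)])
        x = pheno["met"].to_numpy()
        y = np.log(pheno["fasting_glucose"].to_numpy())
        return geno, instr, x, y

    def test_single_snp_instrument_returns_empty_table_with_reason(self, rng):
        X = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        geno = make_genotypes(X)
        instr = Instrument("m", "c", [("rs000001", 0.2, "A")])
        x = X[:, 0] + rng.standard_normal(100)
        y = x + rng.standard_normal(100)
        tab = leave_one_out(instr, geno, y, x)
        assert tab.empty and "single-SNP" in tab.attrs["reason"]

    def test_two_snp_loo_equals_single_snp_wald_ratios(self, rng):
        X = rng.binomial(2, 0.3, size=(2000, 2)).astype(float)
        geno = make_genotypes(X)
        x = X @ [0.3, 0.25] + rng.standard_normal(2000)
        y = 0.2 * x + rng.standard_normal(2000)
        instr = Instrument("m", "c", [("rs000001", 0.3, "A"), ("rs000002", 0.25, "A")])
        tab = leave_one_out(instr, geno, y, x).set_index("excluded_snp")
        for excl, remaining in (("rs000001", 1), ("rs000002", 0)):
            g = X[:, remaining]
            gc, xc, yc = g - g.mean(), x - x.mean(), y - y.mean()
            wald = (gc @ yc) / (gc @ xc)
            assert tab.loc[excl, "beta_iv"] == pytest.approx(wald, abs=1e-10)

    def test_exchangeable_snps_give_stable_loo(self):
        geno, instr, x, y = self._instrumented_cohort()
        full = tsls(y, x, genetic_risk_score(instr, geno))
        tab = leave_one_out(instr, geno, y, x)
        assert np.all(np.abs(tab["beta_iv"] - full.beta_iv) < 4 * full.se)

    def test_pleiotropic_snp_exclusion_moves_estimate_toward_truth(self):
        geno, instr, x, y = self._instrumented_cohort(pleiotropic=True)
        full = tsls(y, x, genetic_risk_score(instr, geno))
        tab = leave_one_out(instr, geno, y, x).set_index("excluded_snp")
        bias_full = abs(full.beta_iv - 0.1)
        bias_wo_pleio = abs(tab.loc["rs000001", "beta_iv"] - 0.1)
        others = [abs(tab.loc[s, "beta_iv"] - 0.1) for s in tab.index if s != "rs000001"]
        assert bias_wo_pleio < bias_full
        assert bias_wo_pleio < min(others)

    def test_refit_excluding_zero_weight_snp_is_noop(self, rng):
        X = rng.binomial(2, 0.3, size=(500, 3)).astype(float)
        geno = make_genotypes(X)
        x = X @ [0.3, 0.2, 0.0] + rng.standard_normal(500)
        y = 0.2 * x + rng.standard_normal(500)
        instr = Instrument("m", "c", [("rs000001", 0.3, "A"), ("rs000002", 0.2, "A"),
                                      ("rs000003", 0.0, "A")])
        full = tsls(y, x, genetic_risk_score(instr, geno))
        refit, report = refit_excluding(instr, "rs000003", geno, y, x)
        assert refit.beta_iv == pytest.approx(full.beta_iv, abs=1e-12)

    def test_refit_excluding_reduces_pleiotropy_bias_and_reports_significance(self):
        geno, instr, x, y = self._instrumented_cohort(pleiotropic=True)
        refit, report = refit_excluding(instr, "rs000001", geno, y, x)
        full = tsls(y, x, genetic_risk_score(instr, geno))
        assert abs(refit.beta_iv - 0.1) < abs(full.beta_iv - 0.1)
        assert set(report) >= {"significant_before", "significant_after", "removed"}

    def test_removal_emptying_instrument_fails(self, rng):
        X = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        geno = make_genotypes(X)
        instr = Instrument("m", "c", [("rs000001", 0.2, "A")])
        with pytest.raises(ValueError):
            refit_excluding(instr, "rs000001", geno,
                            rng.standard_normal(100), rng.standard_normal(100))

    def test_dominant_weight_removal_equals_remaining_wald_ratio(self, rng):
        X = rng.binomial(2, 0.3, size=(1500, 2)).astype(float)
        geno = make_genotypes(X)
        x = X @ [0.5, 0.1] + rng.standard_normal(1500)
        y = 0.3 * x + rng.standard_normal(1500)
        instr = Instrument("m", "c", [("rs000001", 0.5, "A"), ("rs000002", 0.1, "A")])
        refit, _ = refit_excluding(instr, "rs000001", geno, y, x)
        g = X[:, 1]
        gc, xc, yc = g - g.mean(), x - x.mean(), y - y.mean()
        assert refit.beta_iv == pytest.approx((gc @ yc) / (gc @ xc), abs=1e-10)
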