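"""Mixed-model association scan: REML behaviour, GLS oracles, λ diagnostics,
threshold semantics."""

import numpy as np
import pandas as pd
import pytest

from gestmr import genetics, mlma
from gestmr.cohort import CohortConfig, Relatedness, family_random_effect, simulate_genotypes


def _sib_cohort(n_pairs=250, m=300, seed=1, maf=(0.1, 0.5), n=None):
    n = 2 * n_pairs if n is None else n
    cfg = CohortConfig(n_per_stratum=n, m_snps=m, n_chromosomes=5,
                       strata=("SA",), maf_range_per_stratum={"SA": maf},
                       relatedness=Relatedness(n_pairs, 0.25), seed=seed)
    return simulate_genotypes(cfg)["SA"]


class TestReml:
    def test_null_heritability_pinned_near_zero(self):
        """σ²_g = 0 phenotype: estimate stays below 5% of total variance.
        A sparse GRM panel (m=200 at n=1000) keeps relatedness contrast high."""
        cfg = CohortConfig(n_per_stratum=1000, m_snps=200, strata=("SA",),
                           maf_range_per_stratum={"SA": (0.1, 0.5)},
                           relatedness=Relatedness(0, 0.0), seed=2)
        geno = simulate_genotypes(cfg)["SA"]
        grm = genetics.compute_grm(geno, maf_min=0.05)
        rng = np.random.default_rng(7)
        y = rng.standard_normal(1000)
        vc = mlma.reml_variance_components(y, None, grm)
        assert vc.sigma2_g < 0.05 * (vc.sigma2_g + vc.sigma2_e)

    def test_h2_recovered_on_sib_cohort(self):
        """h² = 0.5 phenotype drawn from the realised GRM: mean estimate over
        20 seeds within ±0.1."""
        rng = np.random.default_rng(11)
        ests = []
        for seed in range(20):
            geno = _sib_cohort(n_pairs=250, m=300, seed=200 + seed)
            grm = genetics.compute_grm(geno, maf_min=0.05)
            L = np.linalg.cholesky(grm.matrix + 1e-6 * np.eye(500))
            y = np.sqrt(0.5) * (L @ rng.standard_normal(500)) \
                + np.sqrt(0.5) * rng.standard_normal(500)
            ests.append(mlma.reml_variance_components(y, None, grm).h2)
        assert abs(np.mean(ests) - 0.5) < 0.1

    def test_identity_grm_flagged_nonidentifiable(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(80)
        vc = mlma.reml_variance_components(y, None, np.eye(80))
        assert not vc.identifiable

    def test_nonfinite_phenotype_rejected(self):
        with pytest.raises(ValueError):
            mlma.reml_variance_components(np.array([1.0, np.nan]), None, np.eye(2))


class TestScan:
    def test_zero_sigma_g_reduces_to_ols(self):
        """With the variance ratio at the null boundary the GLS scan must
        reproduce plain OLS effects and SEs."""
        geno = _sib_cohort(n_pairs=0, m=60, seed=5, n=400)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(geno.n)  # pure noise → σ̂²_g ≈ 0
        covar = rng.standard_normal((geno.n, 2))
        rec_mlma = mlma.mlma_scan(y, covar, geno, maf_min=0.05)
        vcs = rec_mlma.attrs["variance_components"]
        rec_ols = mlma.mlma_scan(y, covar, geno, grm_policy="none", maf_min=0.05)
        merged = rec_mlma.merge(rec_ols, on="snp_id", suffixes=("_m", "_o"))
        boundary = all(v.h2 < 1e-3 for v in vcs.values())
        if boundary:
            assert np.allclose(merged["beta_m"], merged["beta_o"], atol=1e-6)

    def test_fast_path_matches_dense_gls(self):
        """Eigendecomposition path equals explicit V⁻¹ GLS on a toy cohort."""
        from gestmr.experiments import mlma_dense_oracle_check
        res = mlma_dense_oracle_check(3)
        assert res["max_beta_diff"] < 1e-8
        assert res["max_se_diff"] < 1e-8

    def test_loo_snp_matches_downdated_dense_solve(self):
        geno = _sib_cohort(n_pairs=30, m=20, seed=6)
        rng = np.random.default_rng(6)
        y = rng.standard_normal(geno.n)
        rec = mlma.mlma_scan(y, None, geno, grm_policy="loo_snp", maf_min=0.05)
        vc = rec.attrs["variance_components"]["global"]
        X = geno.dosages.astype(float)
        maf = genetics.compute_maf(X)
        keep = np.nonzero((maf > 0) & (maf >= 0.05))[0]
        Z, _ = genetics._standardise(X[:, keep])
        S = Z @ Z.T
        j_local = 0
        j = keep[j_local]
        A_j = (S - np.outer(Z[:, j_local], Z[:, j_local])) / (len(keep) - 1)
        V = vc.sigma2_g * A_j + vc.sigma2_e * np.eye(geno.n)
        b, s = mlma.dense_gls_effect(y, np.ones((geno.n, 1)), X[:, j], V)
        row = rec.set_index("snp_id").loc[geno.snps.index[j]]
        assert row["beta"] == pytest.approx(b, abs=1e-10)
        assert row["se"] == pytest.approx(s, abs=1e-10)

    def test_causal_snp_reaches_suggestive_significance(self):
        """0.5-SD per-allele effect at MAF ≈ 0.3, n = 1000 → p ≤ 1e-5 in
        nearly every replicate."""
        hits = 0
        for seed in range(20):
            cfg = CohortConfig(n_per_stratum=1000, m_snps=40, n_chromosomes=2,
                               strata=("SA",), maf_range_per_stratum={"SA": (0.3, 0.3)},
                               relatedness=Relatedness(250, 0.25), seed=700 + seed)
            geno = simulate_genotypes(cfg)["SA"]
            rng = np.random.default_rng(800 + seed)
            g = geno.column("rs000001")
            y = 0.5 * g + family_random_effect(geno.family_ids, 0.25, 0.5, rng) \
                + np.sqrt(0.75) * rng.standard_normal(1000)
            rec = mlma.mlma_scan(y, None, geno, maf_min=0.05)
            p = rec.set_index("snp_id").loc["rs000001", "p"]
            hits += p <= 1e-5
        assert hits >= 19

    def test_global_policy_shows_proximal_contamination(self):
        """Including the causal SNP's own chromosome in the GRM absorbs part
        of its signal: the global-GRM χ² is deflated relative to LOCO."""
        cfg = CohortConfig(n_per_stratum=600, m_snps=100, n_chromosomes=2,
                           strata=("SA",), maf_range_per_stratum={"SA": (0.3, 0.3)},
                           relatedness=Relatedness(150, 0.25), seed=31)
        geno = simulate_genotypes(cfg)["SA"]
        rng = np.random.default_rng(31)
        g = geno.column("rs000001")
        y = 1.0 * g + rng.standard_normal(600)
        chi = {}
        for policy in ("loco_chromosome", "global"):
            rec = mlma.mlma_scan(y, None, geno, grm_policy=policy, maf_min=0.05)
            row = rec.set_index("snp_id").loc["rs000001"]
            chi[policy] = (row["beta"] / row["se"]) ** 2
        assert chi["global"] < chi["loco_chromosome"]

    def test_test_snps_mask_restricts_scan(self):
        geno = _sib_cohort(n_pairs=50, m=40, seed=8)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(geno.n)
        mask = np.zeros(40, dtype=bool)
        mask[:10] = True
        rec = mlma.mlma_scan(y, None, geno, maf_min=0.05, test_snps=mask)
        assert set(rec["snp_id"]) <= set(geno.snps.index[:10])


class TestDiagnostics:
    def _records(self, chi2, maf):
        se = np.ones_like(chi2)
        return pd.DataFrame({"beta": np.sqrt(chi2), "se": se, "maf": maf})

    def test_lambda_one_at_null_median(self):
        rec = self._records(np.full(50, mlma.CHI2_NULL_MEDIAN), np.full(50, 0.3))
        d = mlma.genomic_inflation(rec)
        assert d.lambda_overall == pytest.approx(1.0)
        assert not d.inflated_overall

    @pytest.mark.parametrize("lam,expected", [(1.15, True), (1.1, True), (1.05, False)])
    def test_inflation_flag_threshold(self, lam, expected):
        rec = self._records(np.full(60, lam * mlma.CHI2_NULL_MEDIAN), np.full(60, 0.3))
        d = mlma.genomic_inflation(rec)
        assert d.inflated[">=0.1"] is expected

    def test_maf_bins_fixed_and_small_bins_flagged(self):
        maf = np.r_[np.full(30, 0.0005), np.full(5, 0.02), np.full(40, 0.3)]
        rec = self._records(np.full(75, mlma.CHI2_NULL_MEDIAN), maf)
        d = mlma.genomic_inflation(rec)
        assert set(d.lambda_by_maf_bin) == {"<0.001", "[0.01,0.05)", ">=0.1"}
        assert d.reliable["<0.001"] and not d.reliable["[0.01,0.05)"]

    def test_null_scan_lambda_near_one(self):
        geno = _sib_cohort(n_pairs=0, m=400, seed=9, n=600)
        rng = np.random.default_rng(9)
        lams = []
        for _ in range(10):
            y = rng.standard_normal(geno.n)
            rec = mlma.mlma_scan(y, None, geno, grm_policy="none", maf_min=0.05)
            lams.append(mlma.genomic_inflation(rec).lambda_overall)
        assert 0.9 < np.mean(lams) < 1.1


class TestThresholds:
    @pytest.mark.parametrize("p,suggestive,gws", [
        (1e-5, True, False),   # inclusive at the suggestive threshold
        (5e-8, True, False),   # strict at genome-wide significance
        (1e-9, True, True),
        (1e-4, False, False),
    ])
    def test_flagging_semantics(self, p, suggestive, gws):
        rec = pd.DataFrame({"p": [p]})
        out = mlma.flag_thresholds(rec)
        assert bool(out["suggestive"][0]) is suggestive
        assert bool(out["gws"][0]) is gws
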