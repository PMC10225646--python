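"""Instrument construction: LD thinning, GRS linearity, first-stage strength."""

import numpy as np
import pandas as pd
import pytest

from gestmr.instruments import (
    FirstStage,
    Instrument,
    first_stage,
    genetic_risk_score,
    greedy_ld_thin,
    select_and_thin,
)

from conftest import make_genotypes


def _records(rows):
    return pd.DataFrame(rows, columns=["metabolite", "class_label", "snp_id",
                                       "chrom", "pos", "a1", "beta", "p"])


class TestThinning:
    def test_duplicate_dosage_snps_keep_most_significant(self, rng):
        x = rng.binomial(2, 0.3, size=200)
        geno = make_genotypes(np.column_stack([x, x]))
        recs = _records([
            ("met", "cls", "rs000001", 1, 0, "A", 0.2, 1e-6),
            ("met", "cls", "rs000002", 2, 1000, "A", 0.21, 1e-7),
        ])
        instruments, _ = select_and_thin(recs, geno)
        assert instruments["met"].snp_ids == ["rs000002"]

    def test_independent_snps_all_kept(self, rng):
        X = rng.binomial(2, 0.3, size=(500, 5))
        geno = make_genotypes(X)
        recs = _records([("met", "cls", s, 1, i, "A", 0.2, 1e-6)
                         for i, s in enumerate(geno.snps.index)])
        instruments, _ = select_and_thin(recs, geno)
        assert len(instruments["met"].snp_ids) == 5

    def test_pairwise_bound_holds_and_matches_bruteforce(self):
        from gestmr.experiments import ld_thinning_oracle_check
        res = ld_thinning_oracle_check(5)
        assert res["agrees"]
        assert res["max_pairwise_r2"] < 0.2

    def test_no_suggestive_snp_means_no_instrument(self, rng):
        geno = make_genotypes(rng.binomial(2, 0.3, size=(100, 2)))
        recs = _records([("met", "cls", "rs000001", 1, 0, "A", 0.2, 1e-3)])
        instruments, missing = select_and_thin(recs, geno)
        assert instruments == {}
        assert "met" in missing

    def test_class_pooling_orders_by_best_p(self, rng):
        # one SNP suggestive for two metabolites: pooled once with min p
        x = rng.binomial(2, 0.3, size=300)
        geno = make_genotypes(np.column_stack([x, rng.binomial(2, 0.3, 300)]))
        recs = _records([
            ("m1", "cls", "rs000001", 1, 0, "A", 0.2, 1e-6),
            ("m2", "cls", "rs000001", 1, 0, "A", 0.3, 1e-8),
            ("m2", "cls", "rs000002", 2, 1, "A", 0.1, 1e-6),
        ])
        instruments, _ = select_and_thin(recs, geno)
        assert instruments["m1"].snp_ids == ["rs000001"]
        assert set(instruments["m2"].snp_ids) == {"rs000001", "rs000002"}
        audit = instruments["m1"].audit
        assert audit.loc[audit["snp_id"] == "rs000001", "p"].iloc[0] == 1e-8


class TestGrs:
    def test_zero_weights_give_zero_score(self, rng):
        geno = make_genotypes(rng.binomial(2, 0.3, size=(50, 2)))
        instr = Instrument("met", "cls", [("rs000001", 0.0, "A"), ("rs000002", 0.0, "A")])
        assert np.allclose(genetic_risk_score(instr, geno), 0.0)

    def test_single_snp_linearity(self):
        geno = make_genotypes(np.array([[0], [1], [2]]))
        instr = Instrument("met", "cls", [("rs000001", 0.2, "A")])
        assert np.allclose(genetic_risk_score(instr, geno), [0.0, 0.2, 0.4])

    def test_effect_allele_flip_reflects_score(self, rng):
        X = rng.binomial(2, 0.3, size=(40, 1))
        geno = make_genotypes(X)
        a = genetic_risk_score(Instrument("m", "c", [("rs000001", 0.2, "A")]), geno)
        g = genetic_risk_score(Instrument("m", "c", [("rs000001", 0.2, "G")]), geno)
        assert np.allclose(g, 2 * 0.2 - a)

    def test_absent_snp_fails_naming_it(self, rng):
        geno = make_genotypes(rng.binomial(2, 0.3, size=(10, 1)))
        instr = Instrument("m", "c", [("rs000042", 0.2, "A")])
        with pytest.raises(KeyError, match="rs000042"):
            genetic_risk_score(instr, geno)

    def test_missing_dosages_mean_imputed(self):
        X = np.array([[0.0], [2.0], [np.nan], [2.0]])
        geno = make_genotypes(np.zeros((4, 1)))
        geno.dosages = X  # inject missingness
        instr = Instrument("m", "c", [("rs000001", 1.0, "A")])
        grs = genetic_risk_score(instr, geno)
        assert grs[2] == pytest.approx(np.nanmean(X))


class TestFirstStage:
    @pytest.mark.parametrize("F,weak", [(72.4, False), (9.9, True)])
    def test_weak_flag_rule(self, F, weak):
        fs = FirstStage(r2_first=0.05, F=F, n=1000)
        assert fs.weak is weak

    def test_partial_f_matches_expected_noncentrality(self, rng):
        """GRS explaining 5% of exposure variance at n = 2000:
        E[F] ≈ 1 + n·R²/(1−R²); mean over 50 seeds within ±25%."""
        n, r2 = 2000, 0.05
        expect = 1 + n * r2 / (1 - r2)
        fs_vals = []
        for _ in range(50):
            z = rng.standard_normal(n)
            x = np.sqrt(r2) * z + np.sqrt(1 - r2) * rng.standard_normal(n)
            fs_vals.append(first_stage(x, z).F)
        assert abs(np.mean(fs_vals) - expect) / expect < 0.25

    def test_partial_r2_and_covariate_adjustment(self, rng):
        n = 500
        c = rng.standard_normal(n)
        z = rng.standard_normal(n)
        x = 0.5 * z + 2.0 * c + rng.standard_normal(n)
        fs_raw = first_stage(x, z)
        fs_adj = first_stage(x, z, covariates=c[:, None])
        assert fs_adj.r2_first > fs_raw.r2_first  # covariate removes noise

    def test_zero_variance_grs_rejected(self, rng):
        with pytest.raises(ValueError):
            first_stage(rng.standard_normal(50), np.ones(50))
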