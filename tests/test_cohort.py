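"""Synthetic-cohort generator: reproducibility, allele frequencies,
relatedness structure, phenotype model identities."""

import numpy as np
import pytest

from gestmr.cohort import (
    CohortConfig,
    InvalidConfigError,
    MetaboliteArchitecture,
    Relatedness,
    family_random_effect,
    simulate_cohort,
    simulate_genotypes,
    simulate_phenotypes,
    snp_ids,
)
from gestmr.genetics import compute_grm


def _config(**kw):
    base = dict(n_per_stratum=500, m_snps=60, n_chromosomes=5, strata=("SA",),
                maf_range_per_stratum={"SA": (0.3, 0.3)},
                relatedness=Relatedness(0, 0.0), seed=1)
    base.update(kw)
    return CohortConfig(**base)


def test_seed_reproducibility_is_exact():
    cfg = _config(relatedness=Relatedness(100, 0.25))
    g1 = simulate_genotypes(cfg)["SA"]
    g2 = simulate_genotypes(cfg)["SA"]
    assert np.array_equal(g1.dosages, g2.dosages)
    p1, _ = simulate_phenotypes(g1, cfg)
    p2, _ = simulate_phenotypes(g2, cfg)
    assert p1.equals(p2)


def test_empirical_maf_tracks_target():
    cfg = _config(n_per_stratum=800, maf_range_per_stratum={"SA": (0.1, 0.5)})
    g = simulate_genotypes(cfg)["SA"]
    assert np.all(np.abs(g.maf() - g.snps["maf_target"].to_numpy()) < 0.05)


def test_chromosomes_assigned_round_robin():
    g = simulate_genotypes(_config())["SA"]
    assert np.array_equal(g.snps["chrom"].to_numpy(), (np.arange(60) % 5) + 1)


def test_unrelated_cohort_has_null_grm_offdiagonal():
    cfg = _config(n_per_stratum=500, m_snps=400)
    A = compute_grm(simulate_genotypes(cfg)["SA"]).matrix
    off = A[np.triu_indices(500, 1)]
    assert abs(off.mean()) < 0.02


def test_sibpair_grm_matches_twice_kinship():
    """Within-pair mean GRM entry ≈ 2·kinship = 0.5 (Monte Carlo, 10 seeds)."""
    means = []
    for seed in range(10):
        cfg = _config(n_per_stratum=500, m_snps=300,
                      relatedness=Relatedness(250, 0.25), seed=100 + seed)
        A = compute_grm(simulate_genotypes(cfg)["SA"]).matrix
        means.append(np.mean([A[2 * i, 2 * i + 1] for i in range(250)]))
    assert 0.4 < np.mean(means) < 0.6


@pytest.mark.parametrize("kinship", [0.1, 0.4])
def test_general_kinship_gives_expected_genotype_correlation(kinship):
    cfg = _config(n_per_stratum=1000, m_snps=500,
                  relatedness=Relatedness(500, kinship), seed=5)
    X = simulate_genotypes(cfg)["SA"].dosages.astype(float)
    a, b = X[0::2], X[1::2]
    ac, bc = a - a.mean(0), b - b.mean(0)
    corr = (ac * bc).mean() / np.sqrt((ac**2).mean() * (bc**2).mean())
    assert abs(corr - 2 * kinship) < 0.05


@pytest.mark.parametrize("bad", [
    lambda: _config(m_snps=0),
    lambda: _config(n_per_stratum=1),
    lambda: _config(maf_range_per_stratum={"SA": (0.0, 0.3)}),
    lambda: _config(relatedness=Relatedness(300, 0.25)),  # 2*families > n
    lambda: _config(relatedness=Relatedness(10, 0.6)),
])
def test_degenerate_configs_rejected(bad):
    with pytest.raises(InvalidConfigError):
        bad()


def test_unknown_architecture_snp_fails_naming_it():
    arch = MetaboliteArchitecture(name="met", class_label="c",
                                  causal_snps=(("rs999999", 0.2),))
    cfg = _config(metabolites=(arch,))
    g = simulate_genotypes(cfg)["SA"]
    with pytest.raises(InvalidConfigError, match="rs999999"):
        simulate_phenotypes(g, cfg)


def test_null_architecture_metabolite_independent_of_genotype():
    """No genetic effects, no confounding → per-SNP association t-stats stay
    in the null range across all SNPs."""
    arch = MetaboliteArchitecture(name="met", class_label="c", causal_snps=())
    cfg = _config(n_per_stratum=600, m_snps=200, metabolites=(arch,),
                  confounder_sd=0.0, seed=9)
    g = simulate_genotypes(cfg)["SA"]
    pheno, _ = simulate_phenotypes(g, cfg)
    y = pheno["met"].to_numpy()
    X = g.dosages.astype(float)
    Xc = X - X.mean(0)
    yc = y - y.mean()
    r = (Xc.T @ yc) / np.sqrt((Xc**2).sum(0) * (yc**2).sum())
    t = r * np.sqrt(598 / (1 - r**2))
    # Bonferroni-style bound: max |t| over 200 null SNPs
    assert np.max(np.abs(t)) < 4.5


def test_causal_effect_identified_without_confounding():
    """β_fasting = 0.2, no confounder → OLS of log fasting glucose on the
    metabolite recovers 0.2 within ±0.02 at n=5000."""
    arch = MetaboliteArchitecture(name="met", class_label="c",
                                  causal_snps=tuple((s, 0.2) for s in snp_ids(10)))
    cfg = _config(n_per_stratum=5000, m_snps=10, metabolites=(arch,),
                  causal_effects={"met": (0.2, 0.0)}, confounder_sd=0.0, seed=11)
    out = simulate_cohort(cfg)["SA"]
    _, pheno, _ = out
    x = pheno["met"].to_numpy()
    y = np.log(pheno["fasting_glucose"].to_numpy())
    xc = x - x.mean()
    beta = (xc @ (y - y.mean())) / (xc @ xc)
    assert abs(beta - 0.2) < 0.02


def test_confounding_biases_observational_estimate():
    arch = MetaboliteArchitecture(name="met", class_label="c",
                                  causal_snps=tuple((s, 0.2) for s in snp_ids(10)))
    cfg = _config(n_per_stratum=4000, m_snps=10, metabolites=(arch,),
                  causal_effects={"met": (0.0, 0.0)},
                  confounder_loadings={"metabolites": 0.6, "fasting": 0.15}, seed=13)
    _, pheno, truth = simulate_cohort(cfg)["SA"]
    x = pheno["met"].to_numpy()
    y = np.log(pheno["fasting_glucose"].to_numpy())
    xc = x - x.mean()
    beta = (xc @ (y - y.mean())) / (xc @ xc)
    assert beta > 0.04  # true causal effect is zero


def test_realised_heritability_matches_architecture():
    arch = MetaboliteArchitecture(name="met", class_label="c",
                                  causal_snps=tuple((s, 0.3) for s in snp_ids(8)),
                                  residual_sd=1.0)
    cfg = _config(n_per_stratum=5000, m_snps=8, metabolites=(arch,),
                  maf_range_per_stratum={"SA": (0.3, 0.3)}, confounder_sd=0.0, seed=17)
    _, _, truth = simulate_cohort(cfg)["SA"]
    # expected h2 = 8·0.09·2·0.3·0.7 / (that + 1)
    gv = 8 * 0.09 * 2 * 0.3 * 0.7
    assert abs(truth.heritability["met"] - gv / (gv + 1.0)) < 0.03


def test_strata_generated_independently():
    cfg = _config(strata=("SA", "WE"),
                  maf_range_per_stratum={"SA": (0.3, 0.3), "WE": (0.3, 0.3)})
    genos = simulate_genotypes(cfg)
    assert not np.array_equal(genos["SA"].dosages, genos["WE"].dosages)


def test_family_random_effect_within_family_correlation():
    rng = np.random.default_rng(3)
    fam = np.repeat([f"f{i}" for i in range(4000)], 2)
    u = family_random_effect(fam, 0.25, 1.0, rng)
    a, b = u[0::2], u[1::2]
    corr = np.corrcoef(a, b)[0, 1]
    assert abs(corr - 0.5) < 0.05
    assert abs(u.var() - 1.0) < 0.05


def test_pleiotropic_snp_has_direct_outcome_effect():
    arch = MetaboliteArchitecture(name="met", class_label="c", causal_snps=())
    cfg = _config(n_per_stratum=4000, m_snps=5, metabolites=(arch,),
                  confounder_sd=0.0,
                  pleiotropy=(("rs000001", "two_hour", 0.1),), seed=23)
    g = simulate_genotypes(cfg)["SA"]
    pheno, _ = simulate_phenotypes(g, cfg)
    y = np.log(pheno["two_hour_glucose"].to_numpy())
    dos = g.column("rs000001")
    dc = dos - dos.mean()
    beta = (dc @ (y - y.mean())) / (dc @ dc)
    assert abs(beta - 0.1) < 0.02
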