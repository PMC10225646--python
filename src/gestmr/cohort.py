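"""Synthetic two-stratum pregnancy cohort generator with known ground truth.

The generator emulates the structure a stratified metabolite-GWAS →
one-sample MR analysis needs to be testable end to end without any external
data: two ancestry strata with differing allele frequencies, within-stratum
relatedness (sib pairs drawn from explicit parental genotypes), a sparse
per-metabolite genetic architecture, a single shared confounder U, causal
metabolite → glucose effects on the log scale (so log-normalising the
outcome is the correct transform), and optional horizontally pleiotropic
SNPs with a direct effect on an outcome.

Everything is exactly reproducible from ``(CohortConfig, seed)`` and the
full ground truth is returned as a :class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.special import expit


class InvalidConfigError(ValueError):
    """Raised for degenerate cohort configurations."""


@dataclass(frozen=True)
class MetaboliteArchitecture:
    """Sparse genetic architecture of one metabolite (concentrations in mmol/L).

    ``causal_snps`` maps SNP id → additive effect per allele (mmol/L);
    ``class_correlation`` is the residual correlation shared with other
    members of the same metabolite class (via a class-level latent factor).
    """

    name: str
    class_label: str
    causal_snps: tuple = ()
    residual_sd: float = 1.0
    baseline: float = 3.0
    class_correlation: float = 0.0

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise InvalidConfigError(f"{self.name}: residual_sd must be > 0")
        if not 0 <= self.class_correlation < 1:
            raise InvalidConfigError(f"{self.name}: class_correlation must be in [0, 1)")
        for snp, eff in self.causal_snps:
            if not np.isfinite(eff):
                raise InvalidConfigError(f"{self.name}: non-finite effect for {snp}")


@dataclass(frozen=True)
class Relatedness:
    """Family structure: ``n_families`` sib pairs with the given kinship.

    Pairs are drawn from explicit parental genotypes; the second sib re-uses
    the first sib's parental allele slot with probability 2·kinship, which
    at kinship = 0.25 is exactly Mendelian full-sib transmission.
    """

    n_families: int = 0
    kinship: float = 0.25

    def __post_init__(self):
        if self.n_families < 0:
            raise InvalidConfigError("n_families must be >= 0")
        if not 0 <= self.kinship <= 0.5:
            raise InvalidConfigError("kinship must be in [0, 0.5]")


@dataclass(frozen=True)
class CohortConfig:
    n_per_stratum: int = 1000
    m_snps: int = 1000
    n_chromosomes: int = 10
    strata: tuple = ("SA", "WE")
    maf_range_per_stratum: dict = field(default_factory=lambda: {"SA": (0.05, 0.5), "WE": (0.05, 0.5)})
    relatedness: Relatedness = field(default_factory=Relatedness)
    metabolites: tuple = ()
    # metabolite -> (beta_fasting, beta_2h) or metabolite -> {stratum: (bf, b2h)}
    causal_effects: dict = field(default_factory=dict)
    confounder_sd: float = 1.0
    confounder_loadings: dict = field(default_factory=dict)
    pleiotropy: tuple = ()  # (snp_id, "fasting"|"two_hour", direct effect on log outcome)
    glucose_median: tuple = (4.5, 6.0)  # mmol/L, fasting and 2-hour
    glucose_log_sd: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if self.n_per_stratum < 2:
            raise InvalidConfigError("n_per_stratum must be >= 2")
        if self.m_snps < 1:
            raise InvalidConfigError("m_snps must be >= 1")
        if self.n_chromosomes < 1:
            raise InvalidConfigError("n_chromosomes must be >= 1")
        if self.confounder_sd < 0:
            raise InvalidConfigError("confounder_sd must be >= 0")
        for s in self.strata:
            lo, hi = self.maf_range_per_stratum[s]
            if not (0 < lo <= hi <= 0.5):
                raise InvalidConfigError(f"MAF range for {s} must satisfy 0 < lo <= hi <= 0.5")
        if 2 * self.relatedness.n_families > self.n_per_stratum:
            raise InvalidConfigError("2*n_families exceeds stratum size")
        names = [m.name for m in self.metabolites]
        if len(set(names)) != len(names):
            raise InvalidConfigError("duplicate metabolite names")


def snp_ids(m: int) -> list:
    return [f"rs{j + 1:06d}" for j in range(m)]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (0/1/2) with SNP metadata and sample ids for one stratum."""

    stratum: str
    sample_ids: np.ndarray
    family_ids: np.ndarray
    dosages: np.ndarray  # (n, m) int8
    snps: pd.DataFrame  # index snp_id; columns chrom, pos, a1 (effect/alt), a2, maf_target

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snps.index.get_loc(snp_id)
        return np.asarray(self.dosages[:, j], dtype=float)

    def subset(self, rows) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            stratum=self.stratum,
            sample_ids=self.sample_ids[rows],
            family_ids=self.family_ids[rows],
            dosages=self.dosages[rows],
            snps=self.snps,
        )

    def maf(self) -> np.ndarray:
        from . import genetics

        return genetics.compute_maf(self.dosages)


def _rng(config: CohortConfig, stratum: str, stage: int) -> np.random.Generator:
    idx = list(config.strata).index(stratum)
    return np.random.default_rng([int(config.seed), idx, stage])


def _draw_stratum_genotypes(config: CohortConfig, stratum: str) -> GenotypeMatrix:
    rng = _rng(config, stratum, 1)
    n, m = config.n_per_stratum, config.m_snps
    lo, hi = config.maf_range_per_stratum[stratum]
    maf = rng.uniform(lo, hi, size=m)

    F = config.relatedness.n_families
    share_p = 2.0 * config.relatedness.kinship
    X = np.empty((n, m), dtype=np.int8)

    if F:
        # parental allele pairs, Hardy-Weinberg within stratum
        Ma = (rng.random((F, m)) < maf).astype(np.int8)
        Mb = (rng.random((F, m)) < maf).astype(np.int8)
        Fa = (rng.random((F, m)) < maf).astype(np.int8)
        Fb = (rng.random((F, m)) < maf).astype(np.int8)
        s1m = rng.random((F, m)) < 0.5
        s1f = rng.random((F, m)) < 0.5
        c1m = np.where(s1m, Ma, Mb)
        c1f = np.where(s1f, Fa, Fb)
        # sib 2 re-uses sib 1's parental slot with prob 2k, else the other slot
        tm = rng.random((F, m)) < share_p
        tf = rng.random((F, m)) < share_p
        c2m = np.where(tm, c1m, np.where(s1m, Mb, Ma))
        c2f = np.where(tf, c1f, np.where(s1f, Fb, Fa))
        X[0 : 2 * F : 2] = c1m + c1f
        X[1 : 2 * F : 2] = c2m + c2f
    n_single = n - 2 * F
    if n_single:
        X[2 * F :] = rng.binomial(2, maf, size=(n_single, m)).astype(np.int8)

    sample_ids = np.array([f"{stratum}_{i + 1:05d}" for i in range(n)])
    family_ids = np.array(
        [f"{stratum}_FAM{(i // 2) + 1:05d}" if i < 2 * F else f"{stratum}_FAM{F + (i - 2 * F) + 1:05d}" for i in range(n)]
    )
    chrom = (np.arange(m) % config.n_chromosomes) + 1
    pos = 10_000 * (np.arange(m) // config.n_chromosomes + 1)
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "a1": "A", "a2": "G", "maf_target": maf},
        index=pd.Index(snp_ids(m), name="snp_id"),
    )
    return GenotypeMatrix(stratum, sample_ids, family_ids, X, snps)


def simulate_genotypes(config: CohortConfig) -> dict:
    """Simulate Hardy-Weinberg genotypes per stratum with sib-pair blocks.

    SNPs are assigned round-robin to chromosomes; strata share SNP ids but
    draw independent allele frequencies from their own MAF range.
    """
    return {s: _draw_stratum_genotypes(config, s) for s in config.strata}


@dataclass
class SimTruth:
    """Ground truth of one simulated stratum, for parameter-recovery tests."""

    stratum: str
    seed: int
    snp_effects: dict  # metabolite -> {snp_id: effect}
    causal_betas: dict  # metabolite -> (beta_fasting, beta_2h) on the log-glucose scale
    metabolite_means: dict  # theoretical E[metabolite]
    heritability: dict  # realised var(genetic)/var(metabolite)
    confounder: np.ndarray  # U per individual
    confounder_loadings: dict
    pleiotropy: tuple

    def to_json(self) -> str:
        import json

        d = {
            "stratum": self.stratum,
            "seed": self.seed,
            "snp_effects": self.snp_effects,
            "causal_betas": {k: list(v) for k, v in self.causal_betas.items()},
            "metabolite_means": self.metabolite_means,
            "heritability": self.heritability,
            "confounder": np.asarray(self.confounder).tolist(),
            "confounder_loadings": self.confounder_loadings,
            "pleiotropy": [list(p) for p in self.pleiotropy],
        }
        return json.dumps(d, indent=1)


def _resolve_causal(config: CohortConfig, name: str, stratum: str):
    entry = config.causal_effects.get(name)
    if entry is None:
        return (0.0, 0.0)
    if isinstance(entry, dict):
        return tuple(entry.get(stratum, (0.0, 0.0)))
    return tuple(entry)


def _loading(config: CohortConfig, key: str) -> float:
    if key in config.confounder_loadings:
        return float(config.confounder_loadings[key])
    return 0.0


def _metabolite_loading(config: CohortConfig, name: str) -> float:
    if name in config.confounder_loadings:
        return float(config.confounder_loadings[name])
    return float(config.confounder_loadings.get("metabolites", 0.0))


def simulate_phenotypes(genotypes: GenotypeMatrix, config: CohortConfig):
    """Metabolites, covariates and multiplicative-noise glucose outcomes.

    metabolite_k = baseline + Σ_j effect_jk · dosage_j + λ_k·U + ε_k with the
    residual split between a class-shared latent and an independent part, so
    class members correlate.  Glucose is generated as
    exp(log μ + Σ_k β_k (met_k − E[met_k]) + λ_y·U + pleiotropy + ε): the log
    outcome is exactly linear in the exposures.
    """
    rng = _rng(config, genotypes.stratum, 2)
    n = genotypes.n
    stratum = genotypes.stratum

    U = config.confounder_sd * rng.standard_normal(n)

    class_labels = sorted({m.class_label for m in config.metabolites})
    class_latent = {c: rng.standard_normal(n) for c in class_labels}

    mets = {}
    snp_effects, met_means, herit = {}, {}, {}
    for arch in config.metabolites:
        g = np.zeros(n)
        effects = {}
        for snp, eff in arch.causal_snps:
            if snp not in genotypes.snps.index:
                raise InvalidConfigError(
                    f"metabolite {arch.name}: unknown SNP {snp!r} in architecture"
                )
            g += eff * genotypes.column(snp)
            effects[snp] = float(eff)
        rho = arch.class_correlation
        resid = arch.residual_sd * (
            np.sqrt(rho) * class_latent[arch.class_label] + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        )
        lam = _metabolite_loading(config, arch.name)
        met = arch.baseline + g + lam * U + resid
        mets[arch.name] = met
        snp_effects[arch.name] = effects
        p = genotypes.snps.loc[list(effects), "maf_target"].to_numpy() if effects else np.array([])
        met_means[arch.name] = float(arch.baseline + (2.0 * p * np.fromiter(effects.values(), float)).sum())
        herit[arch.name] = float(np.var(g) / np.var(met)) if np.var(met) > 0 else 0.0

    # covariates
    age = 27.5 + _loading(config, "age") * U + 4.5 * rng.standard_normal(n)
    bmi = np.clip(26.0 + _loading(config, "bmi") * U + 4.0 * rng.standard_normal(n), 15.0, None)
    parity = rng.poisson(np.exp(0.0 + _loading(config, "parity") * U))
    smoking = (rng.random(n) < expit(-1.5 + _loading(config, "smoking") * U)).astype(int)
    multiple_pregnancy = (rng.random(n) < 0.015).astype(int)
    gestational_age = 184.0 + 2.0 * rng.standard_normal(n)

    causal = {m.name: _resolve_causal(config, m.name, stratum) for m in config.metabolites}

    log_f = np.log(config.glucose_median[0]) + _loading(config, "fasting") * U
    log_h = np.log(config.glucose_median[1]) + _loading(config, "two_hour") * U
    for name, (bf, bh) in causal.items():
        centred = mets[name] - met_means[name]
        log_f = log_f + bf * centred
        log_h = log_h + bh * centred
    for snp, outcome, eff in config.pleiotropy:
        if snp not in genotypes.snps.index:
            raise InvalidConfigError(f"pleiotropy: unknown SNP {snp!r}")
        dos = genotypes.column(snp)
        if outcome == "fasting":
            log_f = log_f + eff * dos
        elif outcome == "two_hour":
            log_h = log_h + eff * dos
        else:
            raise InvalidConfigError(f"pleiotropy outcome must be 'fasting' or 'two_hour', got {outcome!r}")
    log_f = log_f + config.glucose_log_sd * rng.standard_normal(n)
    log_h = log_h + config.glucose_log_sd * rng.standard_normal(n)

    table = pd.DataFrame(
        {
            "FID": genotypes.family_ids,
            "IID": genotypes.sample_ids,
            "stratum": stratum,
            "age": age,
            "bmi": bmi,
            "parity": parity,
            "smoking": smoking,
            "multiple_pregnancy": multiple_pregnancy,
            "gestational_age": gestational_age,
            "fasting_glucose": np.exp(log_f),
            "two_hour_glucose": np.exp(log_h),
            **mets,
        }
    )
    truth = SimTruth(
        stratum=stratum,
        seed=config.seed,
        snp_effects=snp_effects,
        causal_betas=causal,
        metabolite_means=met_means,
        heritability=herit,
        confounder=U,
        confounder_loadings=dict(config.confounder_loadings),
        pleiotropy=tuple(config.pleiotropy),
    )
    return table, truth


def simulate_cohort(config: CohortConfig):
    """Genotypes + phenotypes + truth for every stratum.

    Returns ``{stratum: (GenotypeMatrix, phenotype DataFrame, SimTruth)}``;
    strata are generated independently.
    """
    genos = simulate_genotypes(config)
    out = {}
    for s, g in genos.items():
        table, truth = simulate_phenotypes(g, config)
        out[s] = (g, table, truth)
    return out


def family_random_effect(family_ids, kinship: float, sd: float, rng) -> np.ndarray:
    """Polygenic-background random effect with within-family correlation 2·kinship.

    Used to put an h²-controlled family-structured component into a phenotype
    without loading it onto any genotyped SNP (the tested SNPs stay null).
    """
    family_ids = np.asarray(family_ids)
    rho = 2.0 * kinship
    shared = {f: rng.standard_normal() for f in pd.unique(family_ids)}
    common = np.array([shared[f] for f in family_ids])
    own = rng.standard_normal(family_ids.size)
    return sd * (np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own)
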