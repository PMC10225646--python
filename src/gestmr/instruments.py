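"""Genetic-instrument construction: LD thinning, GRS weights, first-stage strength.

Suggestive SNPs (p ≤ 1e-5) are pooled within each metabolite class and
greedily thinned by in-sample LD (keep a SNP iff r² < r2_max against every
already-kept SNP, visiting SNPs by ascending p, ties broken by chromosome
then position).  Each metabolite's instrument is the kept SNPs that were
suggestive for it, weighted by its own GWAS beta.  The weighted genetic
risk score GRS_i = Σ_j w_j · dosage_ij is the single excluded instrument of
the downstream two-stage least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetics
from .mlma import SUGGESTIVE_P


@dataclass
class Instrument:
    exposure: str
    class_label: str
    snps: list  # list of (snp_id, weight = GWAS beta, effect_allele)
    audit: pd.DataFrame | None = None  # thinning trail for the class pool

    @property
    def snp_ids(self) -> list:
        return [s for s, _, _ in self.snps]

    def without(self, snp_ids) -> "Instrument":
        drop = set([snp_ids] if isinstance(snp_ids, str) else snp_ids)
        missing = drop - set(self.snp_ids)
        if missing:
            raise KeyError(f"SNPs not in instrument: {sorted(missing)}")
        kept = [t for t in self.snps if t[0] not in drop]
        if not kept:
            raise ValueError("removal would empty the instrument")
        return Instrument(self.exposure, self.class_label, kept, self.audit)


@dataclass
class FirstStage:
    """Instrument strength of a fitted first stage (exposure ~ GRS [+ covariates])."""

    r2_first: float  # partial R² of the GRS term
    F: float  # partial F statistic for the GRS term
    n: int

    WEAK_F = 10.0

    @property
    def weak(self) -> bool:
        return self.F < self.WEAK_F


def greedy_ld_thin(pool: pd.DataFrame, genotypes, r2_max: float = 0.2) -> pd.DataFrame:
    """Greedy LD thinning of a SNP pool ordered by (p, chrom, pos).

    ``pool`` needs columns snp_id, p, chrom, pos.  Returns the pool with a
    ``kept`` flag and, for dropped SNPs, the kept SNP that excluded them.
    Monomorphic pairs (undefined r²) are treated as r² = 0.
    """
    pool = pool.sort_values(["p", "chrom", "pos"]).reset_index(drop=True)
    cols = {s: np.asarray(genotypes.column(s)) for s in pool["snp_id"]}
    kept: list[str] = []
    kept_flag, excluded_by, max_r2 = [], [], []
    for snp in pool["snp_id"]:
        g = cols[snp]
        worst, blocker = 0.0, None
        for k in kept:
            with np.errstate(invalid="ignore"):
                sd1, sd2 = g.std(), cols[k].std()
                r2 = 0.0 if sd1 == 0 or sd2 == 0 else float(np.corrcoef(g, cols[k])[0, 1] ** 2)
            if r2 > worst:
                worst, blocker = r2, k
            if r2 >= r2_max:
                break
        if worst < r2_max:
            kept.append(snp)
            kept_flag.append(True)
            excluded_by.append(None)
        else:
            kept_flag.append(False)
            excluded_by.append(blocker)
        max_r2.append(worst)
    out = pool.copy()
    out["kept"] = kept_flag
    out["max_r2_vs_kept"] = max_r2
    out["excluded_by"] = excluded_by
    return out


def select_and_thin(records: pd.DataFrame, genotypes, r2_max: float = 0.2,
                    suggestive_p: float = SUGGESTIVE_P) -> dict:
    """Build per-exposure instruments from class-pooled suggestive SNPs.

    ``records`` holds one row per (metabolite, SNP) association with columns
    ``metabolite, class_label, snp_id, chrom, pos, a1, beta, p``.  Thinning
    runs on the pooled suggestive SNPs of each class (a SNP suggestive for
    several metabolites is ordered by its best p).  Metabolites with no
    suggestive SNP get no instrument and are reported in the returned dict's
    ``df.attrs``-style companion (see return).

    Returns ``(instruments, no_instrument)`` where ``instruments`` maps
    metabolite → :class:`Instrument` and ``no_instrument`` maps excluded
    metabolite → reason.
    """
    sugg = records[records["p"] <= suggestive_p]
    instruments: dict[str, Instrument] = {}
    no_instrument: dict[str, str] = {}
    for cls, grp in sugg.groupby("class_label"):
        pool = (
            grp.groupby("snp_id")
            .agg(p=("p", "min"), chrom=("chrom", "first"), pos=("pos", "first"))
            .reset_index()
        )
        audit = greedy_ld_thin(pool, genotypes, r2_max=r2_max)
        kept = set(audit.loc[audit["kept"], "snp_id"])
        for met, mgrp in grp.groupby("metabolite"):
            rows = mgrp[mgrp["snp_id"].isin(kept)].sort_values("p")
            if rows.empty:
                no_instrument[met] = "all suggestive SNPs removed by LD thinning"
                continue
            snps = [(r.snp_id, float(r.beta), str(r.a1)) for r in rows.itertuples()]
            instruments[met] = Instrument(met, cls, snps, audit)
    for met in records["metabolite"].unique():
        if met not in instruments and met not in no_instrument:
            no_instrument[met] = "no SNP at the suggestive threshold"
    return instruments, no_instrument


def genetic_risk_score(instrument: Instrument, genotypes) -> np.ndarray:
    """Weighted allele score; missing dosages are mean-imputed per SNP.

    The effect allele of each weight is aligned to the genotype matrix's
    coding (dosage flipped to 2 − x when the instrument's effect allele is
    the other allele)."""
    n = genotypes.dosages.shape[0]
    grs = np.zeros(n)
    for snp, w, a1 in instrument.snps:
        if snp not in genotypes.snps.index:
            raise KeyError(f"instrument SNP {snp!r} absent from genotype matrix")
        dos = genotypes.column(snp)
        geno_a1 = genotypes.snps.loc[snp, "a1"]
        if a1 != geno_a1:
            if a1 != genotypes.snps.loc[snp, "a2"]:
                raise ValueError(f"effect allele {a1!r} matches neither allele of {snp}")
            dos = 2.0 - dos
        if np.isnan(dos).any():
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        grs += w * dos
    return grs


def first_stage(exposure, grs, covariates=None) -> FirstStage:
    """Partial F and partial R² of the GRS in exposure ~ GRS (+ covariates)."""
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(grs, dtype=float)
    n = x.size
    if np.std(z) == 0:
        raise ValueError("zero-variance GRS: first stage undefined")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    p = C.shape[1]
    if n <= p + 2:
        raise ValueError("too few observations for the first stage")
    Q, _ = np.linalg.qr(C)
    xr = x - Q @ (Q.T @ x)
    zr = z - Q @ (Q.T @ z)
    rss0 = float(xr @ xr)
    zz = float(zr @ zr)
    bz = float(zr @ xr) / zz
    rss1 = max(rss0 - bz**2 * zz, 0.0)
    dof = n - p - 1
    # a perfectly predictive instrument (e.g. GRS ≡ exposure) has F = ∞
    F = np.inf if rss1 <= 1e-12 * rss0 else (rss0 - rss1) / (rss1 / dof)
    r2 = (rss0 - rss1) / rss0 if rss0 > 0 else 0.0
    return FirstStage(r2_first=float(r2), F=float(F), n=n)
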