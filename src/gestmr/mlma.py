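"""Mixed-linear-model association (MLMA) scan with leave-one-out GRM handling.

Model per SNP:  y = C γ + g b + u + e,  u ~ N(0, A σ²_g),  e ~ N(0, I σ²_e),
with A a GRM.  Variance components are estimated once per (phenotype,
left-out chromosome) by REML under the no-SNP null model and re-used for
every SNP on that chromosome (EMMAX-style); the per-SNP effect and SE come
from GLS under V̂ = Â σ̂²_g + I σ̂²_e, with a Wald normal p-value.

``grm_policy``:
  * ``loco_chromosome`` (default): the GRM is rebuilt excluding the tested
    SNP's chromosome, so a SNP is never in both the fixed and random effects.
  * ``loo_snp``: strict per-SNP exclusion via a rank-one GRM downdate and a
    dense solve — O(m) factorisations, only sensible at toy scale.
  * ``global``: one GRM from all SNPs (exhibits proximal contamination).
  * ``none``: plain OLS association scan (no random effect), the naive
    comparator for genomic-inflation diagnostics.

Everything is computed through a one-time eigendecomposition of each GRM and
1-D REML optimisation over the variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import genetics

#: χ²(1 df) null median; divisor for the genomic inflation factor.
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))

SUGGESTIVE_P = 1e-5
GWS_P = 5e-8
LAMBDA_INFLATED = 1.1

MAF_BIN_EDGES = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1)
MAF_BIN_LABELS = (
    "<0.001",
    "[0.001,0.005)",
    "[0.005,0.01)",
    "[0.01,0.05)",
    "[0.05,0.1)",
    ">=0.1",
)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    loglik: float
    converged: bool = True
    boundary: bool = False  # σ²_g pinned at the zero boundary
    identifiable: bool = True  # False when the GRM is (near) identity

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def _design(covariates, n: int) -> np.ndarray:
    """Intercept plus optional covariate columns."""
    if covariates is None:
        return np.ones((n, 1))
    C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate design is rank deficient")
    return C


def _reml_rotated(yt, Ct, d, max_iter: int = 200):
    """REML over the variance ratio h = σ²_g/(σ²_g+σ²_e) on rotated data.

    ``d`` are GRM eigenvalues; rotated V is diag(h d + (1-h)) times a total
    variance that is profiled out.  Log-likelihood is reported up to a
    constant that does not depend on h.
    """
    yt = np.asarray(yt, dtype=float)
    Ct = np.asarray(Ct, dtype=float)
    n, p = Ct.shape

    def neg_restricted_ll(h):
        v = h * d + (1.0 - h)
        v = np.maximum(v, 1e-12)
        Cw = Ct / v[:, None]
        XtVX = Ct.T @ Cw
        gamma = np.linalg.solve(XtVX, Cw.T @ yt)
        r = yt - Ct @ gamma
        rss = float(np.sum(r * r / v))
        sigma2 = rss / (n - p)
        _, logdet = np.linalg.slogdet(XtVX)
        return 0.5 * ((n - p) * np.log(sigma2) + np.log(v).sum() + logdet)

    identifiable = float(np.ptp(d)) > 1e-8
    if not identifiable:
        # GRM ~ identity: h is not identified; report the boundary null fit
        v0 = neg_restricted_ll(0.0)
        sigma2 = _profiled_sigma2(yt, Ct, np.ones_like(d))
        return VarianceComponents(0.0, sigma2, -v0, converged=True, boundary=True, identifiable=False)

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-6, "maxiter": max_iter},
    )
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res}")
    h_candidates = [(neg_restricted_ll(0.0), 0.0), (float(res.fun), float(res.x))]
    nll, h = min(h_candidates, key=lambda t: t[0])
    v = np.maximum(h * d + (1.0 - h), 1e-12)
    sigma2 = _profiled_sigma2(yt, Ct, v)
    return VarianceComponents(
        sigma2_g=h * sigma2,
        sigma2_e=(1.0 - h) * sigma2,
        loglik=-nll,
        converged=True,
        boundary=h < 1e-4,
    )


def _profiled_sigma2(yt, Ct, v):
    n, p = Ct.shape
    Cw = Ct / v[:, None]
    gamma = np.linalg.solve(Ct.T @ Cw, Cw.T @ yt)
    r = yt - Ct @ gamma
    return float(np.sum(r * r / v)) / (n - p)


def reml_variance_components(phenotype, covariates, grm) -> VarianceComponents:
    """REML (σ²_g, σ²_e) for y = Cγ + u + e with u ~ N(0, A σ²_g)."""
    y = np.asarray(phenotype, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")
    A = grm.matrix if isinstance(grm, genetics.GRM) else np.asarray(grm, dtype=float)
    if A.shape[0] != y.size:
        raise ValueError("GRM not aligned with samples")
    C = _design(covariates, y.size)
    d, U = np.linalg.eigh(A)
    d = np.maximum(d, 0.0)
    return _reml_rotated(U.T @ y, U.T @ C, d)


class LocoWorkspace:
    """Pre-computed eigendecompositions + rotated dosages for an MLMA scan.

    Building the workspace is the expensive part (per-chromosome GRM
    eigendecompositions); it can be re-used across phenotypes measured on
    the same individuals.
    """

    def __init__(self, genotypes, maf_min: float = 0.05, grm_policy: str = "loco_chromosome",
                 test_snps=None):
        """``test_snps`` (boolean mask over SNP columns) restricts which SNPs
        are scanned; the GRM always uses every MAF-passing SNP.  This mirrors
        GWAS practice where the relatedness matrix comes from the full
        genotyping panel while a filtered subset is tested."""
        if grm_policy not in ("loco_chromosome", "global"):
            raise ValueError(f"unsupported workspace policy {grm_policy!r}")
        X = np.asarray(getattr(genotypes, "dosages", genotypes), dtype=float)
        snps = getattr(genotypes, "snps", None)
        if snps is None:
            raise ValueError("genotypes must carry SNP metadata (chrom/pos)")
        self.snps = snps
        self.maf = genetics.compute_maf(X)
        self.keep = (self.maf > 0) & (self.maf >= maf_min)
        if self.keep.sum() < 2:
            raise ValueError("fewer than 2 SNPs pass the MAF filter")
        if test_snps is None:
            test_mask = self.keep
        else:
            test_mask = self.keep & np.asarray(test_snps, dtype=bool)
        self.maf_min = maf_min
        self.policy = grm_policy
        self.n = X.shape[0]

        Z, _ = genetics._standardise(X[:, self.keep])
        chrom_all = snps["chrom"].to_numpy()
        self.chrom_kept = chrom_all[self.keep]
        kept_idx = np.nonzero(self.keep)[0]
        S = Z @ Z.T  # m_all * A_global
        m_all = Z.shape[1]
        test_chroms = pd.unique(chrom_all[test_mask])
        self.chromosomes = [int(c) for c in pd.unique(self.chrom_kept) if c in set(test_chroms)]
        self._per_chrom = {}
        if grm_policy == "global":
            A = S / m_all
            d, U = np.linalg.eigh(A)
            d = np.maximum(d, 0.0)
            shared = (d, U)
        for c in self.chromosomes:
            on_c = self.chrom_kept == c
            m_c = int(on_c.sum())
            if grm_policy == "loco_chromosome":
                if m_all - m_c < 1:
                    raise ValueError(
                        f"leave-one-chromosome-out GRM for chromosome {c} would be empty"
                    )
                Zc = Z[:, on_c]
                A = (S - Zc @ Zc.T) / (m_all - m_c)
                d, U = np.linalg.eigh(A)
                d = np.maximum(d, 0.0)
            else:
                d, U = shared
            cols = np.nonzero(test_mask & (chrom_all == c))[0]
            G_rot = U.T @ X[:, cols]
            self._per_chrom[c] = {"d": d, "U": U, "G_rot": G_rot, "cols": cols}
        self._X = X

    def chrom_data(self, c: int) -> dict:
        return self._per_chrom[c]


def mlma_scan(
    phenotype,
    covariates,
    genotypes,
    grm_policy: str = "loco_chromosome",
    maf_min: float = 0.05,
    workspace: LocoWorkspace | None = None,
    test_snps=None,
) -> pd.DataFrame:
    """Per-SNP mixed-model (or OLS) association scan.

    Returns a GCTA-style table with columns
    ``snp_id, chrom, pos, a1, a2, freq, maf, n, beta, se, p``; per-chromosome
    variance components are attached in ``df.attrs['variance_components']``.
    ``freq`` is the in-sample effect-allele (a1) frequency.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    C = _design(covariates, n)

    if grm_policy == "none":
        return _ols_scan(y, C, genotypes, maf_min, test_snps)
    if grm_policy == "loo_snp":
        return _loo_snp_scan(y, C, genotypes, maf_min)

    if workspace is None:
        workspace = LocoWorkspace(genotypes, maf_min=maf_min, grm_policy=grm_policy,
                                  test_snps=test_snps)
    if workspace.n != n:
        raise ValueError("workspace sample size does not match phenotype")
    snps = workspace.snps

    rows = []
    vcs = {}
    for c in workspace.chromosomes:
        data = workspace.chrom_data(c)
        d, U, G_rot, cols = data["d"], data["U"], data["G_rot"], data["cols"]
        yt = U.T @ y
        Ct = U.T @ C
        vc = _reml_rotated(yt, Ct, d)
        vcs[c] = vc
        w = 1.0 / np.maximum(vc.sigma2_g * d + vc.sigma2_e, 1e-12)
        sw = np.sqrt(w)
        ys = sw * yt
        Cs = sw[:, None] * Ct
        Gs = sw[:, None] * G_rot
        Q, _ = np.linalg.qr(Cs)
        yr = ys - Q @ (Q.T @ ys)
        Gr = Gs - Q @ (Q.T @ Gs)
        denom = np.einsum("ij,ij->j", Gr, Gr)
        ok = denom > 1e-10
        beta = np.full(denom.size, np.nan)
        beta[ok] = (Gr.T @ yr)[ok] / denom[ok]
        se = np.full(denom.size, np.nan)
        se[ok] = np.sqrt(1.0 / denom[ok])
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        freq = workspace._X[:, cols].mean(axis=0) / 2.0
        meta = snps.iloc[cols]
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": meta.index,
                    "chrom": meta["chrom"].to_numpy(),
                    "pos": meta["pos"].to_numpy(),
                    "a1": meta["a1"].to_numpy(),
                    "a2": meta["a2"].to_numpy(),
                    "freq": freq,
                    "maf": workspace.maf[cols],
                    "n": n,
                    "beta": beta,
                    "se": se,
                    "p": np.clip(p, np.nextafter(0, 1), 1.0),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out = out[np.isfinite(out["beta"])].reset_index(drop=True)
    out = out.sort_values(["chrom", "pos"]).reset_index(drop=True)
    out.attrs["variance_components"] = vcs
    out.attrs["grm_policy"] = grm_policy
    return out


def _ols_scan(y, C, genotypes, maf_min, test_snps=None) -> pd.DataFrame:
    X = np.asarray(getattr(genotypes, "dosages", genotypes), dtype=float)
    snps = getattr(genotypes, "snps", None)
    maf = genetics.compute_maf(X)
    keep_mask = (maf > 0) & (maf >= maf_min)
    if test_snps is not None:
        keep_mask &= np.asarray(test_snps, dtype=bool)
    keep = np.nonzero(keep_mask)[0]
    n, p = C.shape
    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    G = X[:, keep]
    Gr = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    ok = gg > 1e-10
    beta = np.full(gg.size, np.nan)
    beta[ok] = (Gr.T @ yr)[ok] / gg[ok]
    rss = float(yr @ yr) - beta**2 * gg
    dof = n - p - 1
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / gg)
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    meta = snps.iloc[keep]
    out = pd.DataFrame(
        {
            "snp_id": meta.index,
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "a1": meta["a1"].to_numpy(),
            "a2": meta["a2"].to_numpy(),
            "freq": G.mean(axis=0) / 2.0,
            "maf": maf[keep],
            "n": n,
            "beta": beta,
            "se": se,
            "p": np.clip(pvals, np.nextafter(0, 1), 1.0),
        }
    )
    out = out[np.isfinite(out["beta"])].reset_index(drop=True)
    out.attrs["grm_policy"] = "none"
    return out


def _loo_snp_scan(y, C, genotypes, maf_min) -> pd.DataFrame:
    """Strict per-SNP GRM exclusion via rank-one downdate + dense GLS.

    Variance components are estimated once on the all-SNP GRM and re-used
    (per-SNP REML would be O(m) eigendecompositions).  Toy scale only.
    """
    X = np.asarray(getattr(genotypes, "dosages", genotypes), dtype=float)
    snps = getattr(genotypes, "snps", None)
    maf = genetics.compute_maf(X)
    keep = np.nonzero((maf > 0) & (maf >= maf_min))[0]
    Z, _ = genetics._standardise(X[:, keep])
    m = Z.shape[1]
    if m < 2:
        raise ValueError("need >= 2 SNPs for leave-one-SNP-out")
    S = Z @ Z.T
    vc = reml_variance_components(y, C[:, 1:] if C.shape[1] > 1 else None, genetics.GRM(S / m, m))
    n = y.size
    rows = []
    for local_j, j in enumerate(keep):
        A_j = (S - np.outer(Z[:, local_j], Z[:, local_j])) / (m - 1)
        V = vc.sigma2_g * A_j + vc.sigma2_e * np.eye(n)
        b, s = dense_gls_effect(y, C, X[:, j], V)
        rows.append((j, b, s))
    idx = [r[0] for r in rows]
    beta = np.array([r[1] for r in rows])
    se = np.array([r[2] for r in rows])
    z = beta / se
    meta = snps.iloc[idx]
    out = pd.DataFrame(
        {
            "snp_id": meta.index,
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "a1": meta["a1"].to_numpy(),
            "a2": meta["a2"].to_numpy(),
            "freq": X[:, idx].mean(axis=0) / 2.0,
            "maf": maf[idx],
            "n": n,
            "beta": beta,
            "se": se,
            "p": np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0),
        }
    )
    out.attrs["variance_components"] = {"global": vc}
    out.attrs["grm_policy"] = "loo_snp"
    return out


def dense_gls_effect(y, C, g, V):
    """Reference GLS effect/SE via an explicit V⁻¹ solve (oracle path)."""
    n = y.size
    Vi = np.linalg.inv(V)
    D = np.column_stack([C, g])
    XtVi = D.T @ Vi
    cov = np.linalg.inv(XtVi @ D)
    coef = cov @ (XtVi @ y)
    return float(coef[-1]), float(np.sqrt(cov[-1, -1]))


@dataclass
class GwasDiagnostics:
    """Genomic inflation factors λ = median(χ²)/χ²₀.₅ overall and per MAF bin."""

    lambda_overall: float
    n_snps: int
    lambda_by_maf_bin: dict = field(default_factory=dict)
    inflated: dict = field(default_factory=dict)
    reliable: dict = field(default_factory=dict)
    n_by_bin: dict = field(default_factory=dict)

    @property
    def inflated_overall(self) -> bool:
        return bool(self.lambda_overall >= LAMBDA_INFLATED - 1e-12)


def genomic_inflation(records: pd.DataFrame, min_bin_count: int = 20) -> GwasDiagnostics:
    """λ per fixed MAF bin; bins with < ``min_bin_count`` SNPs are flagged
    unreliable, empty bins are omitted."""
    def _inflated(lam):
        # tolerance keeps the λ ≥ 1.1 rule exact under float round-off
        return bool(lam >= LAMBDA_INFLATED - 1e-12)

    chi2 = (records["beta"] / records["se"]) ** 2
    chi2 = chi2[np.isfinite(chi2)]
    lam_all = float(np.median(chi2) / CHI2_NULL_MEDIAN)
    diag = GwasDiagnostics(lambda_overall=lam_all, n_snps=int(chi2.size))
    maf = records["maf"].to_numpy()
    edges = list(MAF_BIN_EDGES) + [0.5 + 1e-9]
    for i, label in enumerate(MAF_BIN_LABELS):
        sel = (maf >= edges[i]) & (maf < edges[i + 1])
        if not sel.any():
            continue
        c = (records.loc[sel, "beta"] / records.loc[sel, "se"]) ** 2
        lam = float(np.median(c) / CHI2_NULL_MEDIAN)
        diag.lambda_by_maf_bin[label] = lam
        diag.inflated[label] = _inflated(lam)
        diag.reliable[label] = bool(sel.sum() >= min_bin_count)
        diag.n_by_bin[label] = int(sel.sum())
    return diag


def flag_thresholds(records: pd.DataFrame) -> pd.DataFrame:
    """Annotate suggestive (p ≤ 1e-5, inclusive) and genome-wide significant
    (p < 5e-8, strict) hits."""
    out = records.copy()
    out["suggestive"] = out["p"] <= SUGGESTIVE_P
    out["gws"] = out["p"] < GWS_P
    return out
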