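"""Shared genetic computations: allele frequency, GRM, genotype PCA, LD r².

All functions accept either a plain ``(n_samples, m_snps)`` dosage array with
values in ``[0, 2]`` (``NaN`` = missing) or any object exposing a ``dosages``
attribute (e.g. :class:`gestmr.cohort.GenotypeMatrix`).

Allele frequencies are always computed in-sample: the analysis is fully
stratified by ancestry, so no pooled frequency is ever used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _dosage_array(genotypes) -> np.ndarray:
    d = getattr(genotypes, "dosages", genotypes)
    return np.asarray(d, dtype=float)


def compute_maf(genotypes) -> np.ndarray:
    """Per-SNP minor allele frequency, missing dosages excluded.

    MAF = min(p, 1 - p) with p = mean(dosage) / 2.  A monomorphic SNP has
    MAF 0; this is valid output and is filtered downstream.
    """
    X = _dosage_array(genotypes)
    if X.size and (np.nanmin(X) < 0 or np.nanmax(X) > 2):
        raise ValueError("dosages must lie in [0, 2]")
    p = np.nanmean(X, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages and scale each SNP to unit HWE variance.

    Returns (Z, p) where Z[:, j] = (x_j - 2 p_j) / sqrt(2 p_j (1 - p_j)).
    """
    X = X.copy()
    p = np.nanmean(X, axis=0) / 2.0
    # mean imputation per SNP
    nan_r, nan_c = np.nonzero(np.isnan(X))
    if nan_r.size:
        X[nan_r, nan_c] = 2.0 * p[nan_c]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - 2.0 * p) / denom
    Z[:, denom == 0] = 0.0
    return Z, p


@dataclass
class GRM:
    """Genetic relationship matrix A_jk = (1/m) Σ_i z_ij z_ik.

    ``matrix`` is symmetric n×n; ``m_snps`` is the number of SNPs that passed
    the MAF filter and entered the sum.
    """

    matrix: np.ndarray
    m_snps: int
    sample_ids: np.ndarray | None = None


def compute_grm(genotypes, maf_min: float = 0.0, sample_ids=None) -> GRM:
    """GCTA-style GRM from MAF-filtered, standardised dosages."""
    X = _dosage_array(genotypes)
    maf = compute_maf(X)
    keep = (maf > 0) & (maf >= maf_min)
    if not keep.any():
        raise ValueError("no polymorphic SNP passes the MAF filter; GRM undefined")
    Z, _ = _standardise(X[:, keep])
    m = int(keep.sum())
    A = (Z @ Z.T) / m
    if sample_ids is None:
        sample_ids = getattr(genotypes, "sample_ids", None)
    return GRM(matrix=A, m_snps=m, sample_ids=np.asarray(sample_ids) if sample_ids is not None else None)


def genotype_pca(genotypes, n_components: int = 2, maf_min: float = 0.0):
    """PCA of the standardised dosage matrix.

    Returns ``(scores, variance_fractions)``; scores are orthogonal and the
    variance fractions non-increasing.  The component sign is fixed so that
    the largest-magnitude loading of each component is positive, making the
    output deterministic across linear-algebra backends.
    """
    from sklearn.decomposition import PCA

    X = _dosage_array(genotypes)
    n = X.shape[0]
    if n < n_components:
        raise ValueError("n_components exceeds sample size")
    maf = compute_maf(X)
    keep = (maf > 0) & (maf >= maf_min) & (np.nanstd(X, axis=0) > 0)
    if not keep.any():
        raise ValueError("zero-variance genotype matrix: PCA undefined")
    Z, _ = _standardise(X[:, keep])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    # deterministic orientation
    for j in range(scores.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores, pca.explained_variance_ratio_


def ld_r2(genotypes, snp_a: int, snp_b: int) -> float:
    """Composite (genotype-correlation) LD: squared Pearson r of dosages.

    Monomorphic SNPs have undefined LD; ``NaN`` is returned and treated as
    r² = 0 by the instrument-thinning step.
    """
    X = _dosage_array(genotypes)
    a, b = X[:, snp_a], X[:, snp_b]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(genotypes) -> np.ndarray:
    """Pairwise r² matrix (NaN rows/cols for monomorphic SNPs)."""
    X = _dosage_array(genotypes)
    sd = np.nanstd(X, axis=0)
    Xc = X.copy()
    mu = np.nanmean(Xc, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(Xc))
    if nan_r.size:
        Xc[nan_r, nan_c] = mu[nan_c]
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(Xc.T)
    R2 = np.asarray(R, dtype=float) ** 2
    mono = sd == 0
    R2[mono, :] = np.nan
    R2[:, mono] = np.nan
    np.fill_diagonal(R2, 1.0)
    R2[np.ix_(mono, mono)] = np.nan
    return R2
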