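"""One-sample Mendelian randomization by two-stage least squares.

The GRS is the single excluded instrument: stage 1 regresses the exposure
on the GRS (plus any covariates), stage 2 regresses the log-glucose outcome
on the fitted exposure.  Standard errors use the conventional 2SLS variance
with residuals computed from the *observed* exposure (ivreg's default,
homoskedastic).  Endogeneity is tested with the Wu-Hausman statistic in its
control-function form (outcome regressed on exposure plus the first-stage
residual; t-test on the residual coefficient), numerically identical to the
classical Durbin-Wu-Hausman contrast here but better conditioned.

By default no covariates enter the MR stages beyond the implicit
stratification; pass ``covariates`` to adjust both stages symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import FirstStage, Instrument, first_stage, genetic_risk_score


@dataclass
class MrEstimate:
    exposure: str
    outcome: str
    n: int
    beta_iv: float
    se: float
    ci95: tuple
    first_stage: FirstStage
    wu_hausman_stat: float
    wu_hausman_p: float
    ols_beta: float
    covariates_used: bool = False
    note: str = ""

    @property
    def significant(self) -> bool:
        """95% CI excludes zero."""
        lo, hi = self.ci95
        return bool(lo > 0 or hi < 0)


def _residualise(arrs, C):
    Q, _ = np.linalg.qr(C)
    return [a - Q @ (Q.T @ a) for a in arrs]


def tsls(outcome, exposure, grs, covariates=None, exposure_name="exposure",
         outcome_name="outcome") -> MrEstimate:
    """2SLS causal estimate of exposure → outcome with the GRS as instrument.

    Implemented through the explicit two-stage linear algebra (fitted
    exposure from the first stage, second-stage OLS on the fitted values);
    with one instrument this equals the covariate-projected ratio estimator
    cov(y, GRS)/cov(x, GRS), an identity asserted in the test suite.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(grs, dtype=float)
    n = y.size
    if covariates is None:
        C = np.ones((n, 1))
        covs_used = False
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        covs_used = True
    p = C.shape[1]
    if np.linalg.matrix_rank(C) < p:
        raise ValueError("collinear covariates in the MR design")

    fs = first_stage(x, z, covariates)

    # two-stage algebra on covariate-residualised data
    yr, xr, zr = _residualise([y, x, z], C)
    zz = float(zr @ zr)
    xhat = zr * (float(zr @ xr) / zz)  # first-stage fitted (residualised) exposure
    denom = float(xhat @ xhat)
    if denom <= 0:
        raise ValueError("first stage explains no exposure variance")
    beta_iv = float(xhat @ yr) / denom

    # 2SLS SE convention: residuals from the observed exposure
    u = yr - beta_iv * xr
    dof = n - p - 1
    sigma2_u = float(u @ u) / dof
    se = float(np.sqrt(sigma2_u / denom))
    ci = (beta_iv - 1.96 * se, beta_iv + 1.96 * se)

    ols_beta = float(xr @ yr) / float(xr @ xr)

    wstat, wp = _wu_hausman_from_parts(yr, xr, zr, n_minus_p=n - p)

    return MrEstimate(
        exposure=exposure_name,
        outcome=outcome_name,
        n=n,
        beta_iv=beta_iv,
        se=se,
        ci95=ci,
        first_stage=fs,
        wu_hausman_stat=wstat,
        wu_hausman_p=wp,
        ols_beta=ols_beta,
        covariates_used=covs_used,
    )


def _wu_hausman_from_parts(yr, xr, zr, n_minus_p):
    """Control-function Wu-Hausman on residualised data.

    Augment y ~ x with the first-stage residual v̂ = x − x̂; two-sided t-test
    on the v̂ coefficient.  Degenerate when the GRS equals the exposure
    (zero residual): statistic 0, p = 1.
    """
    zz = float(zr @ zr)
    v = xr - zr * (float(zr @ xr) / zz)
    vv = float(v @ v)
    if vv <= 1e-12 * max(1.0, float(xr @ xr)):
        return 0.0, 1.0
    D = np.column_stack([xr, v])
    coef, _, _, _ = np.linalg.lstsq(D, yr, rcond=None)
    resid = yr - D @ coef
    dof = n_minus_p - 2
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(D.T @ D)
    t = coef[1] / np.sqrt(cov[1, 1])
    p = float(2 * stats.t.sf(abs(t), dof))
    return float(t), p


def wu_hausman(outcome, exposure, grs, covariates=None):
    """Standalone Wu-Hausman endogeneity test (statistic, two-sided p)."""
    est = tsls(outcome, exposure, grs, covariates)
    return est.wu_hausman_stat, est.wu_hausman_p


def leave_one_out(instrument: Instrument, genotypes, outcome, exposure,
                  covariates=None, outcome_name="outcome") -> pd.DataFrame:
    """Sequential single-SNP exclusion refits, forest-plot ready.

    The reduced GRS keeps the original GWAS weights (no re-estimation).
    Single-SNP instruments return an empty table with the reason recorded in
    ``df.attrs['reason']``.
    """
    if len(instrument.snps) < 2:
        out = pd.DataFrame(columns=["excluded_snp", "beta_iv", "ci_lo", "ci_hi", "F"])
        out.attrs["reason"] = "single-SNP instrument: leave-one-out not possible"
        return out
    rows = []
    for snp, _, _ in instrument.snps:
        reduced = instrument.without(snp)
        grs = genetic_risk_score(reduced, genotypes)
        est = tsls(outcome, exposure, grs, covariates,
                   exposure_name=instrument.exposure, outcome_name=outcome_name)
        rows.append(
            {
                "excluded_snp": snp,
                "beta_iv": est.beta_iv,
                "ci_lo": est.ci95[0],
                "ci_hi": est.ci95[1],
                "F": est.first_stage.F,
                "wu_hausman_p": est.wu_hausman_p,
            }
        )
    return pd.DataFrame(rows)


def refit_excluding(instrument: Instrument, snp_ids, genotypes, outcome, exposure,
                    covariates=None, outcome_name="outcome"):
    """Refit without named (e.g. potentially pleiotropic) SNPs.

    Returns ``(estimate, report)`` where the report states whether the 95%
    CI excluded zero before and after the removal.
    """
    full_grs = genetic_risk_score(instrument, genotypes)
    before = tsls(outcome, exposure, full_grs, covariates,
                  exposure_name=instrument.exposure, outcome_name=outcome_name)
    reduced = instrument.without(snp_ids)
    grs = genetic_risk_score(reduced, genotypes)
    after = tsls(outcome, exposure, grs, covariates,
                 exposure_name=instrument.exposure, outcome_name=outcome_name)
    report = {
        "removed": list([snp_ids] if isinstance(snp_ids, str) else snp_ids),
        "significant_before": before.significant,
        "significant_after": after.significant,
        "beta_before": before.beta_iv,
        "beta_after": after.beta_iv,
    }
    return after, report


def mr_table(estimates) -> pd.DataFrame:
    """Flatten MrEstimates into the results layout used by the study tables."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "exposure": est.exposure,
                "outcome": est.outcome,
                "n": est.n,
                "F": est.first_stage.F,
                "beta": est.beta_iv,
                "ci_lo": est.ci95[0],
                "ci_hi": est.ci95[1],
                "wu_hausman_p": est.wu_hausman_p,
                "ols_beta": est.ols_beta,
                "significant": est.significant,
                "weak_instrument": est.first_stage.weak,
            }
        )
    return pd.DataFrame(rows)
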