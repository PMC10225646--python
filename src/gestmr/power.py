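"""Post-hoc MR power for continuous outcomes (non-centrality calculation).

Asymptotic power of the two-sided Wald test of the single-instrument TSLS
estimator: with instrument-on-exposure variance fraction R²_xz, true causal
effect β, exposure variance σ²_x and residual outcome variance σ²_res,

    NCP = n · R²_xz · β² · σ²_x / σ²_res,
    power = P( χ²₁(NCP) > χ²₁ critical at α ).

The residual outcome variance is derived from the *observational* estimate:
σ²_res = var_y − β_obs² · var_x (the continuous-outcome bookkeeping of the
standard MR power calculators).  Published variants of this formula family
differ in the residual-variance bookkeeping, so the implementation is
anchored to a Monte-Carlo oracle (simulate, run TSLS, count rejections) in
the acceptance suite.

Convention: β_true defaults to the MR estimate (post-hoc second pass); the
observational estimate is accepted as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

POWER_ADEQUATE = 0.80


@dataclass
class PowerInput:
    n: int
    alpha: float
    r2_xz: float  # instrument-on-exposure variance fraction
    beta_true: float  # causal effect, outcome units per exposure unit
    beta_obs: float  # observational (OLS) estimate, same units
    var_x: float = 1.0
    var_y: float = 1.0

    def __post_init__(self):
        if not 0 < self.r2_xz < 1:
            raise ValueError("r2_xz must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n < 2 or self.var_x <= 0 or self.var_y <= 0:
            raise ValueError("n must be >= 2 and variances positive")


@dataclass
class PowerResult:
    ncp: float
    power: float
    adequate: bool  # power >= 0.80
    alpha: float
    power_alpha01: float | None = None  # evaluated when adequate at alpha = 0.05


def mr_power(inp: PowerInput) -> PowerResult:
    """Analytic MR power; triggers the α = 0.01 evaluation when adequate at 5%."""
    var_res = inp.var_y - inp.beta_obs**2 * inp.var_x
    if var_res <= 0:
        raise ValueError(
            "inconsistent inputs: beta_obs^2 * var_x >= var_y implies non-positive residual variance"
        )
    ncp = inp.n * inp.r2_xz * inp.beta_true**2 * inp.var_x / var_res
    crit = stats.chi2.ppf(1.0 - inp.alpha, 1)
    power = float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(inp.alpha)
    adequate = power >= POWER_ADEQUATE
    power01 = None
    if adequate and inp.alpha == 0.05:
        crit01 = stats.chi2.ppf(0.99, 1)
        power01 = float(stats.ncx2.sf(crit01, 1, ncp)) if ncp > 0 else 0.01
    return PowerResult(ncp=float(ncp), power=power, adequate=bool(adequate),
                       alpha=inp.alpha, power_alpha01=power01)


def monte_carlo_power(n: int, r2_xz: float, beta_true: float, alpha: float,
                      n_reps: int, rng, var_res_y: float = 1.0) -> float:
    """Monte-Carlo oracle: simulate, run the package's TSLS, count rejections.

    Exposure x = γ z + e_x with var(x) = 1 and the instrument explaining
    R²_xz; outcome y = β x + e_y with var(e_y) = var_res_y.  No confounding,
    so β_obs = β_true and the analytic residual-variance bookkeeping matches
    the simulation exactly.
    """
    from .mr import tsls

    gamma = np.sqrt(r2_xz)
    sd_ex = np.sqrt(1.0 - r2_xz)
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    rejections = 0
    for _ in range(n_reps):
        z = rng.standard_normal(n)
        x = gamma * z + sd_ex * rng.standard_normal(n)
        y = beta_true * x + np.sqrt(var_res_y) * rng.standard_normal(n)
        est = tsls(y, x, z)
        if abs(est.beta_iv / est.se) > crit:
            rejections += 1
    return rejections / n_reps


def observational_estimates(table: pd.DataFrame, outcome_col: str, metabolite_col: str,
                            adjust_cols=("age", "bmi", "smoking", "multiple_pregnancy",
                                         "parity", "gestational_age")):
    """Unadjusted and covariate-adjusted OLS coefficients of the metabolite.

    The adjusted fit controls for maternal age, BMI, smoking status,
    multiple pregnancy, parity and gestational age.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    import statsmodels.api as sm

    cols = [outcome_col, metabolite_col, *adjust_cols]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    df = table[cols].dropna()
    y = df[outcome_col].to_numpy(dtype=float)
    X_un = sm.add_constant(df[[metabolite_col]].to_numpy(dtype=float))
    beta_unadj = float(sm.OLS(y, X_un).fit().params[1])

    X_adj = df[[metabolite_col, *adjust_cols]].to_numpy(dtype=float)
    Xc = sm.add_constant(X_adj)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        corr = np.corrcoef(X_adj.T)
        bad = [adjust_cols[i - 1] for i in range(1, len(adjust_cols) + 1)
               if np.any(np.abs(corr[i][np.arange(corr.shape[0]) != i]) > 0.999)]
        raise ValueError(f"rank-deficient adjusted design; collinear columns: {bad or 'unknown'}")
    beta_adj = float(sm.OLS(y, Xc).fit().params[1])
    return beta_unadj, beta_adj
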