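"""Metabolite and glucose-outcome preparation.

Per-stratum interquartile-range outlier masking, distribution-normalising
transforms (log / square root / rank-based normal scores), natural-log
normalisation of the oral-glucose-tolerance-test outcomes, and flagging of
gestational diabetes (fasting glucose > 6.1 mmol/L or 2-hour post-load
glucose > 7.8 mmol/L, strict inequalities).

Every statistic here is computed within a single stratum; nothing is pooled
across strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GDM_FASTING_MMOL = 6.1
GDM_TWO_HOUR_MMOL = 7.8

_TRANSFORMS = ("log", "sqrt", "nst", "none", "auto")


@dataclass
class PrepConfig:
    """Preparation knobs: 1.5×IQR is the standard fence multiplier, 3 the
    stringent one used for the composite-class stage."""

    iqr_multiplier: float = 1.5
    transform_policy: str = "auto"
    outcome_log: bool = True

    def __post_init__(self):
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be positive")
        if self.transform_policy not in _TRANSFORMS:
            raise ValueError(f"unknown transform policy {self.transform_policy!r}")


def remove_outliers_iqr(values, multiplier: float = 1.5, anchor: str = "quartile"):
    """Mask values outside the IQR fences; returns ``(masked, n_masked)``.

    ``anchor='quartile'`` uses Tukey fences [Q1 - k·IQR, Q3 + k·IQR];
    ``anchor='median'`` anchors both fences at the median (median ± k·IQR),
    the literal reading used for the stringent composite-class stage.
    Quartiles use linear interpolation (type 7).  The interval is closed, so
    a constant series (IQR = 0) masks nothing.  Single pass: fences are
    computed once on the input, never re-quantiled.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    is_series = isinstance(values, pd.Series)
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise ValueError("need at least 4 non-missing values for IQR fences")
    q1, med, q3 = np.quantile(x[finite], [0.25, 0.5, 0.75])
    iqr = q3 - q1
    if anchor == "quartile":
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    elif anchor == "median":
        lo, hi = med - multiplier * iqr, med + multiplier * iqr
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    out = finite & ((x < lo) | (x > hi))
    masked = x.copy()
    masked[out] = np.nan
    n_masked = int(out.sum())
    if is_series:
        masked = pd.Series(masked, index=values.index, name=values.name)
    return masked, n_masked


def normal_scores(values) -> np.ndarray:
    """Blom normal-score transform: rank r (ties → average rank) mapped to
    Φ⁻¹((r − 3/8) / (n + 1/4)), computed on non-missing values."""
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    n = ok.sum()
    if n:
        r = stats.rankdata(x[ok], method="average")
        out[ok] = stats.norm.ppf((r - 3.0 / 8.0) / (n + 0.25))
    return out


def _apply_single(x: np.ndarray, name: str) -> np.ndarray:
    ok = np.isfinite(x)
    if name == "log":
        if np.any(x[ok] <= 0):
            raise ValueError("log transform requires strictly positive values")
        out = np.full_like(x, np.nan)
        out[ok] = np.log(x[ok])
        return out
    if name == "sqrt":
        if np.any(x[ok] < 0):
            raise ValueError("sqrt transform requires non-negative values")
        out = np.full_like(x, np.nan)
        out[ok] = np.sqrt(x[ok])
        return out
    if name == "nst":
        return normal_scores(x)
    if name == "none":
        return x.copy()
    raise ValueError(f"unknown transform {name!r}")


def transform(values, policy: str = "auto"):
    """Apply (or select) a normalising transform.

    ``auto`` keeps the applicable transform among log and sqrt with the
    smallest absolute sample skewness — an automatable stand-in for choosing
    by histogram / QQ-plot inspection.  The rank-based normal-score
    transform has zero skewness by construction, so it would trivially win
    any skewness comparison; it is therefore the fallback, used when the
    best analytic transform still leaves |skewness| above ``nst_tol``.
    Returns ``(transformed, label)``.
    """
    if policy not in _TRANSFORMS:
        raise ValueError(f"unknown transform policy {policy!r}")
    nst_tol = 0.2
    is_series = isinstance(values, pd.Series)
    x = np.asarray(values, dtype=float)
    if policy != "auto":
        out, label = _apply_single(x, policy), policy
    else:
        ok = np.isfinite(x)
        candidates = []
        if not np.any(x[ok] < 0):
            candidates.append("sqrt")
        if not np.any(x[ok] <= 0):
            candidates.append("log")
        best, best_skew, label = None, np.inf, None
        for name in candidates:
            cand = _apply_single(x, name)
            sk = abs(stats.skew(cand[np.isfinite(cand)]))
            if sk < best_skew:
                best, best_skew, label = cand, sk, name
        if best is None or best_skew > nst_tol:
            best, label = _apply_single(x, "nst"), "nst"
        out = best
    if is_series:
        out = pd.Series(out, index=values.index, name=values.name)
    return out, label


def prepare_outcomes(fasting, two_hour) -> pd.DataFrame:
    """Natural-log glucose outcomes plus the dysglycemia (GDM) flag.

    GDM is flagged when fasting glucose *exceeds* 6.1 mmol/L or the 2-hour
    post-load value *exceeds* 7.8 mmol/L (strict: values exactly at a
    threshold are not flagged).
    """
    f = np.asarray(fasting, dtype=float)
    h = np.asarray(two_hour, dtype=float)
    for arr, name in ((f, "fasting"), (h, "two_hour")):
        ok = np.isfinite(arr)
        if np.any(arr[ok] <= 0):
            raise ValueError(f"non-positive {name} glucose value")
    index = fasting.index if isinstance(fasting, pd.Series) else None
    return pd.DataFrame(
        {
            "log_fasting": np.log(f),
            "log_two_hour": np.log(h),
            "gdm": (f > GDM_FASTING_MMOL) | (h > GDM_TWO_HOUR_MMOL),
        },
        index=index,
    )


def prepare_metabolites(
    table: pd.DataFrame,
    metabolite_cols,
    config: PrepConfig | None = None,
    anchor: str = "quartile",
):
    """Outlier-mask then transform each metabolite column of one stratum.

    Outliers are removed before transformation.  Returns the prepared table
    plus a per-metabolite report (n before/after, transform chosen) for
    audit.  Rows with missing values are dropped per metabolite only, never
    listwise.
    """
    config = config or PrepConfig()
    out = table.copy()
    rows = []
    for col in metabolite_cols:
        before = int(np.isfinite(out[col].to_numpy(dtype=float)).sum())
        masked, n_masked = remove_outliers_iqr(out[col], config.iqr_multiplier, anchor=anchor)
        transformed, label = transform(masked, config.transform_policy)
        out[col] = transformed
        rows.append(
            {
                "metabolite": col,
                "n_before": before,
                "n_masked": n_masked,
                "n_after": before - n_masked,
                "transform": label,
            }
        )
    report = pd.DataFrame(rows)
    return out, report
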