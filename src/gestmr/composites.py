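"""Composite metabolite-class exposures via PCA.

Highly correlated metabolites within a class share instruments, which risks
violating the exclusion restriction at the level of individual exposures.
A class composite sidesteps this: mask stringent outliers (median ± 3·IQR
by default) per member metabolite, keep complete rows, standardise, run PCA
and take PC1 as a collective exposure — eligible only when PC1 explains at
least 70% of the class variance.  The PC1 direction is arbitrary, so the
effect sign of a composite MR is flagged as not interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import remove_outliers_iqr

PC1_VARIANCE_THRESHOLD = 0.70


@dataclass
class CompositeClass:
    class_label: str
    members: list
    pc1_variance_fraction: float
    pc1: pd.Series  # unitless scores, NaN where a member was missing/masked
    loadings: np.ndarray  # unit norm, sign-fixed so the loading sum is positive
    eligible: bool
    reason: str = ""
    n_complete: int = 0


def build_composite(
    class_table: pd.DataFrame,
    iqr_multiplier: float = 3.0,
    anchor: str = "median",
    min_members: int = 2,
    pc1_threshold: float = PC1_VARIANCE_THRESHOLD,
    class_label: str = "",
) -> CompositeClass:
    """PC1 composite of one class's metabolite columns.

    Outliers are masked per metabolite (default: stringent median ± 3·IQR),
    PCA runs on standardised complete rows.  The PC1 sign is oriented so the
    loading sum is positive, making scores deterministic across backends.
    """
    members = list(class_table.columns)
    label = class_label or "+".join(members)
    index = class_table.index

    def ineligible(reason):
        return CompositeClass(label, members, float("nan"),
                              pd.Series(np.nan, index=index), np.array([]),
                              eligible=False, reason=reason)

    if len(members) < max(2, min_members):
        return ineligible(f"fewer than {max(2, min_members)} member metabolites")
    masked = {}
    for col in members:
        vals = class_table[col].to_numpy(dtype=float)
        if np.isfinite(vals).sum() <= 2:
            return ineligible(f"member {col} has <= 2 non-missing values")
        masked[col], _ = remove_outliers_iqr(vals, iqr_multiplier, anchor=anchor)
    M = np.column_stack([masked[c] for c in members])
    complete = np.all(np.isfinite(M), axis=1)
    if complete.sum() <= 2:
        return ineligible("fewer than 3 complete rows after outlier masking")
    Xc = M[complete]
    mu, sd = Xc.mean(axis=0), Xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        return ineligible("constant member metabolite")
    Z = (Xc - mu) / sd
    # PCA via SVD of the standardised complete-case matrix
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    frac = float(s[0] ** 2 / np.sum(s**2))
    load = Vt[0]
    if load.sum() < 0 or (load.sum() == 0 and load[np.argmax(np.abs(load))] < 0):
        load = -load
    scores = np.full(len(index), np.nan)
    scores[complete] = Z @ load
    eligible = frac >= pc1_threshold
    return CompositeClass(
        class_label=label,
        members=members,
        pc1_variance_fraction=frac,
        pc1=pd.Series(scores, index=index, name=f"PC1_{label}"),
        loadings=load,
        eligible=bool(eligible),
        reason="" if eligible else f"PC1 explains {frac:.2f} < {pc1_threshold:.2f} of class variance",
        n_complete=int(complete.sum()),
    )


def composite_report(composites) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": c.class_label,
                "n_members": len(c.members),
                "pc1_var": c.pc1_variance_fraction,
                "eligible": c.eligible,
                "reason": c.reason,
            }
            for c in composites
        ]
    )
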