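"""Fixed-effect inverse-variance meta-analysis across strata with I².

Per-stratum GWAS records for the same SNP are first allele-harmonised
(sign-flip when effect/other alleles are swapped, strand complements
resolved, strand-ambiguous A/T and C/G SNPs flagged), then pooled with
weights w_i = 1/se_i².  Heterogeneity is summarised by Cochran's Q and
I² = max(0, (Q − (k−1))/Q)·100 (floored at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele.upper())


def is_palindromic(a1: str, a2: str) -> bool:
    return _complement(a1) == a2.upper()


@dataclass
class HarmonisationResult:
    record_a: dict
    record_b: dict
    status: str  # identical | flipped | strand | strand_flipped | incompatible
    ambiguous: bool = False  # A/T or C/G SNP: strand cannot be resolved from alleles

    @property
    def usable(self) -> bool:
        return self.status != "incompatible"


def harmonise_alleles(record_a, record_b) -> HarmonisationResult:
    """Align record_b's effect allele to record_a's.

    Records are mappings with keys ``snp_id, a1, a2, beta`` and optionally
    ``freq``.  If the effect alleles are swapped the sign of beta_b is
    flipped and its frequency complemented; strand complements are renamed.
    Incompatible allele pairs are excluded with status ``incompatible``.
    """
    a = dict(record_a)
    b = dict(record_b)
    if a["snp_id"] != b["snp_id"]:
        raise ValueError("harmonise_alleles requires matching snp_id")
    a1a, a2a = a["a1"].upper(), a["a2"].upper()
    a1b, a2b = b["a1"].upper(), b["a2"].upper()
    ambiguous = is_palindromic(a1a, a2a)

    def flip(rec):
        rec["a1"], rec["a2"] = a1a, a2a
        rec["beta"] = -rec["beta"]
        if "freq" in rec and rec["freq"] is not None:
            rec["freq"] = 1.0 - rec["freq"]

    if (a1b, a2b) == (a1a, a2a):
        status = "identical"
    elif (a1b, a2b) == (a2a, a1a):
        flip(b)
        status = "flipped"
    elif (_complement(a1b), _complement(a2b)) == (a1a, a2a):
        b["a1"], b["a2"] = a1a, a2a
        status = "strand"
    elif (_complement(a1b), _complement(a2b)) == (a2a, a1a):
        flip(b)
        status = "strand_flipped"
    else:
        status = "incompatible"
    return HarmonisationResult(a, b, status, ambiguous=ambiguous)


@dataclass
class MetaRecord:
    snp_id: str
    beta_meta: float
    se_meta: float
    p_meta: float
    Q: float
    df: int
    I2: float  # percent; NaN when k = 1
    direction: str
    inputs: list = field(default_factory=list)


def ivw_meta(records) -> MetaRecord:
    """Fixed-effect IVW pooling of harmonised records (one per stratum).

    With a single input the pooled estimate equals the input and I² is
    reported missing.  Two-sided p from the normal approximation of
    β_meta/se_meta (METAL's convention).
    """
    records = [dict(r) for r in records]
    if not records:
        raise ValueError("no records to meta-analyse")
    snp = records[0]["snp_id"]
    if any(r["snp_id"] != snp for r in records):
        raise ValueError("records must share snp_id")
    beta = np.array([r["beta"] for r in records], dtype=float)
    se = np.array([r["se"] for r in records], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    direction = "".join("+" if b >= 0 else "-" for b in beta)
    k = beta.size
    if k == 1:
        b, s = float(beta[0]), float(se[0])
        p = float(2 * stats.norm.sf(abs(b / s)))
        return MetaRecord(snp, b, s, p, 0.0, 0, float("nan"), direction, records)
    w = 1.0 / se**2
    b = float(np.sum(w * beta) / np.sum(w))
    s = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (beta - b) ** 2))
    I2 = float(max(0.0, (Q - (k - 1)) / Q) * 100.0) if Q > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(b / s)))
    return MetaRecord(snp, b, s, p, Q, k - 1, I2, direction, records)


def meta_analyse_strata(records_by_stratum: dict, snp_ids=None) -> pd.DataFrame:
    """IVW-meta every requested SNP across per-stratum GWAS tables.

    ``records_by_stratum`` maps stratum → DataFrame with snp_id, a1, a2,
    beta, se, freq columns.  SNPs missing from any stratum, or with
    incompatible alleles, are skipped with a reason column in
    ``df.attrs['excluded']``.
    """
    strata = list(records_by_stratum)
    frames = {s: df.set_index("snp_id") for s, df in records_by_stratum.items()}
    if snp_ids is None:
        snp_ids = sorted(set.intersection(*(set(f.index) for f in frames.values())))
    rows, excluded = [], []
    for snp in snp_ids:
        recs = []
        missing = [s for s in strata if snp not in frames[s].index]
        if missing:
            excluded.append({"snp_id": snp, "reason": f"absent in {','.join(missing)}"})
            continue
        base = frames[strata[0]].loc[snp]
        rec0 = {"snp_id": snp, "a1": base["a1"], "a2": base["a2"], "beta": base["beta"],
                "se": base["se"], "freq": base.get("freq")}
        recs.append(rec0)
        ok = True
        ambiguous = False
        for s in strata[1:]:
            r = frames[s].loc[snp]
            h = harmonise_alleles(rec0, {"snp_id": snp, "a1": r["a1"], "a2": r["a2"],
                                         "beta": r["beta"], "se": r["se"], "freq": r.get("freq")})
            ambiguous = ambiguous or h.ambiguous
            if not h.usable:
                excluded.append({"snp_id": snp, "reason": "incompatible alleles"})
                ok = False
                break
            rec = h.record_b
            rec["se"] = r["se"]
            recs.append(rec)
        if not ok:
            continue
        m = ivw_meta(recs)
        rows.append(
            {
                "snp_id": snp,
                "beta_meta": m.beta_meta,
                "se_meta": m.se_meta,
                "p_meta": m.p_meta,
                "Q": m.Q,
                "df": m.df,
                "I2": m.I2,
                "direction": m.direction,
                "ambiguous": ambiguous,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded  # list of {snp_id, reason} records
    return out
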