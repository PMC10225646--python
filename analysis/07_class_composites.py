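"""Composite metabolite-class exposures: stringent (median ± 3·IQR) outlier
masking per member, PCA, PC1-variance eligibility (≥ 70%), then the same
GWAS → instrument → TSLS machinery on PC1 scores.

Effect directions for composites are not interpretable (PC1 orientation is
a convention)."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import _common

from gestmr import pipeline
from gestmr.composites import build_composite, composite_report
from gestmr.instruments import select_and_thin


def main():
    out = _common.outdir("composites")
    for stratum, (geno, prepared, _, _) in _common.prepared_tables().items():
        comps = []
        comp_cols = []
        for cls in sorted(set(_common.CLASS_MAP.values())):
            members = [m for m in _common.METABOLITES if _common.CLASS_MAP[m] == cls]
            comp = build_composite(prepared[members], iqr_multiplier=3.0,
                                   anchor="median", min_members=3, class_label=cls)
            comps.append(comp)
            if comp.eligible:
                prepared[comp.pc1.name] = comp.pc1.to_numpy()
                comp_cols.append(comp.pc1.name)
        rep = composite_report(comps)
        rep.insert(0, "stratum", stratum)
        rep.to_csv(out / f"{stratum}.composite_report.tsv", sep="\t", index=False)
        print(f"{stratum}: eligible classes "
              f"{[c.class_label for c in comps if c.eligible]} "
              f"(PC1 fractions {[round(c.pc1_variance_fraction, 2) for c in comps]})")
        if not comp_cols:
            continue
        gwas, diags, _ = pipeline.gwas_exposures(geno, prepared, comp_cols)
        records = pipeline.assemble_association_records(gwas, {c: c for c in comp_cols})
        instruments, _ = select_and_thin(records, geno, r2_max=0.2)
        tab, _ = pipeline.mr_exposures(instruments, geno, prepared,
                                       direction_uninterpretable=set(comp_cols))
        tab.to_csv(out / f"{stratum}.composite_mr.tsv", sep="\t", index=False)
        for _, r in tab.iterrows():
            mark = "significant" if r["significant"] else "null"
            print(f"  {stratum} {r['exposure']} × {r['outcome']}: "
                  f"|β| {abs(r['beta']):.3f} (F {r['F']:.0f}) — {mark}; "
                  f"direction not interpretable")
    print(f"composite tables in {out}")


if __name__ == "__main__":
    main()
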