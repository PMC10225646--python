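"""Build genetic instruments: pool suggestive SNPs within metabolite class,
thin by in-sample LD (r² < 0.2, most significant kept), weight by GWAS beta.

Writes the instrument tables (EXPOSURE, SNP, A1, WEIGHT) and first-stage
strength per exposure."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import _common

from gestmr import io
from gestmr.instruments import first_stage, genetic_risk_score, select_and_thin


def main():
    gwas_dir = _common.outdir("gwas")
    out = _common.outdir("instruments")
    for stratum, (geno, prepared, _, _) in _common.prepared_tables().items():
        rows = []
        for met in _common.METABOLITES:
            rec = io.read_gwas(gwas_dir / f"{stratum}.{met}.mlma.tsv")
            sub = rec[rec["p"] <= 1e-5]
            rows.append(pd.DataFrame({
                "metabolite": met, "class_label": _common.CLASS_MAP[met],
                "snp_id": sub["snp_id"], "chrom": sub["chrom"], "pos": sub["pos"],
                "a1": sub["a1"], "beta": sub["beta"], "p": sub["p"],
            }))
        records = pd.concat(rows, ignore_index=True)
        instruments, missing = select_and_thin(records, geno, r2_max=0.2)

        instr_rows, fs_rows = [], []
        for met, instr in sorted(instruments.items()):
            for snp, w, a1 in instr.snps:
                instr_rows.append({"EXPOSURE": met, "SNP": snp, "A1": a1, "WEIGHT": w})
            x = prepared[met].to_numpy(dtype=float)
            ok = np.isfinite(x)
            grs = genetic_risk_score(instr, geno.subset(ok))
            fs = first_stage(x[ok], grs)
            fs_rows.append({"exposure": met, "n_snps": len(instr.snps),
                            "F": fs.F, "r2_first": fs.r2_first, "weak": fs.weak})
        pd.DataFrame(instr_rows).to_csv(out / f"{stratum}.instruments.tsv",
                                        sep="\t", index=False)
        fs_tab = pd.DataFrame(fs_rows)
        fs_tab.to_csv(out / f"{stratum}.first_stage.tsv", sep="\t", index=False)
        no_instr = sorted(set(_common.METABOLITES) - set(instruments))
        print(f"{stratum}: instruments for {len(instruments)}/{len(_common.METABOLITES)} "
              f"metabolites (mean F {fs_tab['F'].mean():.1f}, "
              f"{int(fs_tab['weak'].sum())} weak); none for {no_instr or '—'}")
    print(f"instrument files in {out}")


if __name__ == "__main__":
    main()
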