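"""Simulate the two-stratum pregnancy cohort and export it.

Writes, per stratum: genotypes as VCF and PLINK-.raw-style dosage TSV, the
phenotype/covariate table, and the simulation ground truth (JSON).  Prints
a cohort summary including the dysglycemia (GDM) rate implied by the
fasting > 6.1 / 2-hour > 7.8 mmol/L rule.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import _common

from gestmr import io, prep


def main():
    out = _common.outdir("cohort")
    for stratum, (geno, pheno, truth) in _common.cohort().items():
        io.write_vcf(geno, out / f"{stratum}.vcf")
        io.write_raw(geno, out / f"{stratum}.raw.tsv")
        io.write_phenotypes(pheno, out / f"{stratum}.pheno.tsv")
        io.write_sim_truth(truth, out / f"{stratum}.truth.json")
        outcomes = prep.prepare_outcomes(pheno["fasting_glucose"], pheno["two_hour_glucose"])
        print(f"{stratum}: n={len(pheno)}, m={geno.m} SNPs, "
              f"median fasting {pheno['fasting_glucose'].median():.2f} mmol/L, "
              f"median 2-h {pheno['two_hour_glucose'].median():.2f} mmol/L, "
              f"GDM rate {outcomes['gdm'].mean():.1%}")
    print(f"cohort written to {out}")


if __name__ == "__main__":
    main()
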