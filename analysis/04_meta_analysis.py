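"""Fixed-effect inverse-variance meta-analysis across strata for SNPs that
reached the suggestive level in exactly one stratum, with I² heterogeneity.

Reads the per-stratum summary statistics written by 03_gwas_metabolites.py."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import _common

from gestmr import io, meta
from gestmr.mlma import SUGGESTIVE_P

STRATA = ("SA", "WE")


def main():
    gwas_dir = _common.outdir("gwas")
    out = _common.outdir("meta")
    frames = []
    for met in _common.METABOLITES:
        recs = {s: io.read_gwas(gwas_dir / f"{s}.{met}.mlma.tsv") for s in STRATA}
        sugg = {s: set(r.loc[r["p"] <= SUGGESTIVE_P, "snp_id"]) for s, r in recs.items()}
        one_stratum = sorted(set.union(*sugg.values()) - set.intersection(*sugg.values()))
        if not one_stratum:
            continue
        tab = meta.meta_analyse_strata(recs, one_stratum)
        tab.insert(0, "metabolite", met)
        frames.append(tab)
    result = pd.concat(frames, ignore_index=True)
    result.to_csv(out / "ivw_meta_single_stratum_hits.tsv", sep="\t", index=False)
    retained = result[result["p_meta"] <= SUGGESTIVE_P]
    print(f"meta-analysed {len(result)} single-stratum suggestive SNPs across "
          f"{result['metabolite'].nunique()} metabolites; "
          f"{len(retained)} stay suggestive after pooling; "
          f"median I² {result['I2'].median():.0f}%")
    print(f"table in {out}")


if __name__ == "__main__":
    main()
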