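"""Post-hoc MR power: for every exposure–outcome pair significant in exactly
one stratum, evaluate in the *other* stratum whether the absence of an
association is plausibly a power problem, using the detected stratum's MR
estimate as the true effect and the other stratum's observational
(unadjusted and covariate-adjusted) estimates for the residual-variance
bookkeeping.  When power is adequate (≥ 80%) at α = 0.05 it is also
evaluated at α = 0.01."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import _common

from gestmr.power import PowerInput, mr_power, observational_estimates

STRATA = ("SA", "WE")


def main():
    mr_dir = _common.outdir("mr")
    instr_dir = _common.outdir("instruments")
    out = _common.outdir("power")
    tables = _common.prepared_tables()
    mr = {s: pd.read_csv(mr_dir / f"{s}.mr_results.tsv", sep="\t") for s in STRATA}
    fs = {s: pd.read_csv(instr_dir / f"{s}.first_stage.tsv", sep="\t").set_index("exposure")
          for s in STRATA}
    rows = []
    for s in STRATA:
        other = [t for t in STRATA if t != s][0]
        sig = mr[s][mr[s]["significant"]]
        for _, hit in sig.iterrows():
            met, out_col = hit["exposure"], hit["outcome"]
            o = mr[other]
            omatch = o[(o.exposure == met) & (o.outcome == out_col)]
            if len(omatch) and bool(omatch["significant"].iloc[0]):
                continue  # significant in both strata: no power question
            _, prepared, _, _ = tables[other]
            if met not in prepared.columns or met not in fs[other].index:
                rows.append({"metabolite": met, "outcome": out_col, "detected_in": s,
                             "evaluated_in": other, "power": np.nan,
                             "note": "no instrument in other stratum"})
                continue
            beta_un, beta_adj = observational_estimates(prepared, out_col, met)
            x = prepared[met].to_numpy(dtype=float)
            y = prepared[out_col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            inp = PowerInput(n=int(ok.sum()), alpha=0.05,
                             r2_xz=float(fs[other].loc[met, "r2_first"]),
                             beta_true=float(hit["beta"]), beta_obs=beta_adj,
                             var_x=float(np.var(x[ok])), var_y=float(np.var(y[ok])))
            res = mr_power(inp)
            rows.append({"metabolite": met, "outcome": out_col, "detected_in": s,
                         "evaluated_in": other, "beta_true": hit["beta"],
                         "beta_obs_unadjusted": beta_un, "beta_obs_adjusted": beta_adj,
                         "r2_xz": inp.r2_xz, "ncp": res.ncp, "power": res.power,
                         "adequate": res.adequate,
                         "power_alpha01": res.power_alpha01, "note": ""})
    tab = pd.DataFrame(rows)
    tab.to_csv(out / "posthoc_power.tsv", sep="\t", index=False)
    for _, r in tab.iterrows():
        if np.isfinite(r.get("power", np.nan)):
            extra = (f", at 1% {r['power_alpha01']:.2f}" if pd.notna(r["power_alpha01"])
                     else "")
            print(f"{r['metabolite']} × {r['outcome']} (found in {r['detected_in']}): "
                  f"power in {r['evaluated_in']} {r['power']:.2f}"
                  f"{' (adequate)' if r['adequate'] else ''}{extra}")
        else:
            print(f"{r['metabolite']} × {r['outcome']}: {r['note']}")
    print(f"power table in {out}")


if __name__ == "__main__":
    main()
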