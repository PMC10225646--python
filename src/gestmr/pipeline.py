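"""Stratified end-to-end orchestration: prep → GWAS → instruments → MR.

One code path serves both individual metabolites and PC1 class composites —
a composite's scores are simply handed to the same GWAS/instrument/MR
machinery as another exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import composites as composites_mod
from . import genetics, mlma, prep
from .cohort import GenotypeMatrix
from .instruments import first_stage, genetic_risk_score, select_and_thin
from .mr import MrEstimate, leave_one_out, mr_table, tsls


@dataclass
class StratumAnalysis:
    """All per-stratum intermediate products of one pipeline run."""

    stratum: str
    prepared: pd.DataFrame
    prep_report: pd.DataFrame
    pcs: np.ndarray
    gwas: dict = field(default_factory=dict)  # exposure -> records DataFrame
    diagnostics: dict = field(default_factory=dict)
    instruments: dict = field(default_factory=dict)
    no_instrument: dict = field(default_factory=dict)
    mr: pd.DataFrame | None = None
    mr_estimates: dict = field(default_factory=dict)
    composites: list = field(default_factory=list)


def prepare_stratum(
    pheno: pd.DataFrame,
    metabolite_cols,
    iqr_multiplier: float = 1.5,
    transform_policy: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outlier-mask/transform metabolites and append log outcomes + GDM flag."""
    cfg = prep.PrepConfig(iqr_multiplier=iqr_multiplier, transform_policy=transform_policy)
    prepared, report = prep.prepare_metabolites(pheno, metabolite_cols, cfg)
    outcomes = prep.prepare_outcomes(prepared["fasting_glucose"], prepared["two_hour_glucose"])
    prepared = pd.concat([prepared.reset_index(drop=True), outcomes.reset_index(drop=True)], axis=1)
    return prepared, report


def gwas_exposures(
    geno: GenotypeMatrix,
    prepared: pd.DataFrame,
    exposure_cols,
    maf_min: float = 0.05,
    grm_policy: str = "loco_chromosome",
    n_pcs: int = 2,
    pcs: np.ndarray | None = None,
) -> tuple[dict, dict, np.ndarray]:
    """Mixed-model scan of each exposure with parity + PC1 + PC2 covariates.

    PCs are computed once per stratum on all rows; each exposure is scanned
    on its own non-missing rows (rows masked as outliers for that exposure
    are dropped for that exposure only).
    """
    if pcs is None:
        pcs, _ = genetics.genotype_pca(geno.dosages, n_components=n_pcs, maf_min=maf_min)
    gwas, diags = {}, {}
    for col in exposure_cols:
        y = prepared[col].to_numpy(dtype=float)
        rows = np.isfinite(y)
        sub = geno.subset(rows)
        covar = np.column_stack([prepared.loc[rows, "parity"].to_numpy(dtype=float), pcs[rows]])
        records = mlma.mlma_scan(y[rows], covar, sub, grm_policy=grm_policy, maf_min=maf_min)
        records = mlma.flag_thresholds(records)
        gwas[col] = records
        diags[col] = mlma.genomic_inflation(records)
    return gwas, diags, pcs


def assemble_association_records(gwas: dict, class_map: dict) -> pd.DataFrame:
    """Stack per-exposure suggestive GWAS rows into the instrument-selection
    layout (metabolite, class_label, snp_id, chrom, pos, a1, beta, p)."""
    frames = []
    for met, records in gwas.items():
        sub = records[records["suggestive"]]
        if sub.empty:
            frames.append(pd.DataFrame({"metabolite": [met], "class_label": [class_map.get(met, met)],
                                        "snp_id": [None], "chrom": [0], "pos": [0],
                                        "a1": [None], "beta": [np.nan], "p": [np.nan]}).iloc[:0])
            continue
        frames.append(pd.DataFrame({
            "metabolite": met,
            "class_label": class_map.get(met, met),
            "snp_id": sub["snp_id"].to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "a1": sub["a1"].to_numpy(),
            "beta": sub["beta"].to_numpy(),
            "p": sub["p"].to_numpy(),
        }))
    if not frames:
        return pd.DataFrame(columns=["metabolite", "class_label", "snp_id", "chrom",
                                     "pos", "a1", "beta", "p"])
    out = pd.concat(frames, ignore_index=True)
    # keep every metabolite name visible to select_and_thin even if no hits
    missing = [m for m in gwas if m not in set(out["metabolite"])]
    for m in missing:
        out = pd.concat([out, pd.DataFrame({"metabolite": [m], "class_label": [class_map.get(m, m)],
                                            "snp_id": ["__none__"], "chrom": [0], "pos": [0],
                                            "a1": ["A"], "beta": [0.0], "p": [1.0]})],
                        ignore_index=True)
    return out


def mr_exposures(
    instruments: dict,
    geno: GenotypeMatrix,
    prepared: pd.DataFrame,
    outcome_cols=("log_fasting", "log_two_hour"),
    covariate_cols=None,
    direction_uninterpretable=(),
) -> tuple[pd.DataFrame, dict]:
    """TSLS of every instrumented exposure against every log-glucose outcome."""
    estimates: dict[tuple, MrEstimate] = {}
    for met, instr in instruments.items():
        x_all = prepared[met].to_numpy(dtype=float)
        for out_col in outcome_cols:
            y_all = prepared[out_col].to_numpy(dtype=float)
            rows = np.isfinite(x_all) & np.isfinite(y_all)
            sub = geno.subset(rows)
            grs = genetic_risk_score(instr, sub)
            covar = (prepared.loc[rows, list(covariate_cols)].to_numpy(dtype=float)
                     if covariate_cols else None)
            est = tsls(y_all[rows], x_all[rows], grs, covar,
                       exposure_name=met, outcome_name=out_col)
            if met in direction_uninterpretable:
                est.note = "composite PC1 exposure: direction of effect not interpretable"
            estimates[(met, out_col)] = est
    table = mr_table(estimates.values())
    return table, estimates


def run_stratum_pipeline(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    metabolite_cols,
    class_map: dict,
    maf_min: float = 0.05,
    r2_max: float = 0.2,
    iqr_multiplier: float = 1.5,
    transform_policy: str = "none",
    grm_policy: str = "loco_chromosome",
    composite_min_members: int = 3,
) -> StratumAnalysis:
    """Full per-stratum analysis including eligible class composites."""
    prepared, report = prepare_stratum(pheno, metabolite_cols, iqr_multiplier, transform_policy)
    gwas, diags, pcs = gwas_exposures(geno, prepared, metabolite_cols, maf_min, grm_policy)
    records = assemble_association_records(gwas, class_map)
    instruments, no_instr = select_and_thin(records, geno, r2_max=r2_max)
    mr_tab, estimates = mr_exposures(instruments, geno, prepared)

    # composite stage: stringent (median ± 3·IQR) outliers on the *raw*
    # metabolite values, then the identical GWAS→instrument→MR path on PC1
    comps = []
    comp_names = []
    for cls in sorted(set(class_map.values())):
        members = [m for m in metabolite_cols if class_map.get(m) == cls]
        comp = composites_mod.build_composite(
            pheno[members], iqr_multiplier=3.0, anchor="median",
            min_members=composite_min_members, class_label=cls,
        )
        comps.append(comp)
        if comp.eligible:
            prepared[comp.pc1.name] = comp.pc1.to_numpy()
            comp_names.append(comp.pc1.name)
    if comp_names:
        cg, cdiag, _ = gwas_exposures(geno, prepared, comp_names, maf_min, grm_policy, pcs=pcs)
        gwas.update(cg)
        diags.update(cdiag)
        comp_records = assemble_association_records(cg, {c: c for c in comp_names})
        comp_instr, comp_no = select_and_thin(comp_records, geno, r2_max=r2_max)
        instruments.update(comp_instr)
        no_instr.update(comp_no)
        comp_tab, comp_est = mr_exposures(comp_instr, geno, prepared,
                                          direction_uninterpretable=set(comp_names))
        mr_tab = pd.concat([mr_tab, comp_tab], ignore_index=True)
        estimates.update(comp_est)

    analysis = StratumAnalysis(
        stratum=geno.stratum, prepared=prepared, prep_report=report, pcs=pcs,
        gwas=gwas, diagnostics=diags, instruments=instruments,
        no_instrument=no_instr, mr=mr_tab, mr_estimates=estimates, composites=comps,
    )
    return analysis


def sensitivity_for_significant(analysis: StratumAnalysis, geno: GenotypeMatrix,
                                covariate_cols=None) -> dict:
    """Leave-one-out tables for every significant MR association."""
    out = {}
    for (met, out_col), est in analysis.mr_estimates.items():
        if not est.significant or met not in analysis.instruments:
            continue
        x_all = analysis.prepared[met].to_numpy(dtype=float)
        y_all = analysis.prepared[out_col].to_numpy(dtype=float)
        rows = np.isfinite(x_all) & np.isfinite(y_all)
        sub = geno.subset(rows)
        out[(met, out_col)] = leave_one_out(
            analysis.instruments[met], sub, y_all[rows], x_all[rows],
            outcome_name=out_col,
        )
    return out
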