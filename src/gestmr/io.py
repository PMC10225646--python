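"""Readers and writers for the standard interchange formats.

Genotypes go out as plain-text VCF (GT field, one ALT) and as a PLINK
``.raw``-style tab-delimited dosage table; phenotype/covariate tables as TSV
with header; the GRM in a GCTA-like plain-text lower-triangle layout with a
companion ``.grm.id`` file; GWAS summary statistics in the ``.mlma`` column
convention (SNP CHR BP A1 A2 FREQ BETA SE P N).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix
from .genetics import GRM

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path):
    """Minimal VCF 4.2 with one ALT per site; REF = other allele (a2), ALT =
    effect allele (a1), so the ALT dosage equals the stored dosage."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##source=gestmr;stratum={geno.stratum}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.sample_ids) + "\n")
        order = geno.snps.sort_values(["chrom", "pos"]).index
        for snp in order:
            j = geno.snps.index.get_loc(snp)
            row = geno.snps.loc[snp]
            gts = "\t".join(_GT[int(d)] for d in geno.dosages[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{snp}\t{row['a2']}\t{row['a1']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, stratum: str = "") -> GenotypeMatrix:
    """Load a (plain or bgzipped) VCF into a GenotypeMatrix (ALT dosages)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    ids, chroms, poss, a1s, a2s, rows = [], [], [], [], [], []
    for v in vcf:
        g = np.array(v.genotypes)[:, :2].sum(axis=1)
        rows.append(g.astype(np.int8))
        ids.append(v.ID)
        chroms.append(int(v.CHROM))
        poss.append(v.POS)
        a1s.append(v.ALT[0])
        a2s.append(v.REF)
    X = np.column_stack(rows) if rows else np.empty((samples.size, 0), dtype=np.int8)
    snps = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s,
         "maf_target": np.nan},
        index=pd.Index(ids, name="snp_id"),
    )
    fam = np.array([s.rsplit("_", 1)[0] for s in samples])
    return GenotypeMatrix(stratum, samples, fam, X, snps)


def write_raw(geno: GenotypeMatrix, path):
    """PLINK ``--recode A``-style dosage table: FID IID then SNP_EFFECTALLELE."""
    cols = {f"{snp}_{geno.snps.loc[snp, 'a1']}": geno.dosages[:, j]
            for j, snp in enumerate(geno.snps.index)}
    df = pd.DataFrame({"FID": geno.family_ids, "IID": geno.sample_ids, **cols})
    df.to_csv(path, sep="\t", index=False)


def read_raw(path, stratum: str = "") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    snp_cols = [c for c in df.columns if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
    ids, a1s = zip(*[c.rsplit("_", 1) for c in snp_cols])
    X = df[list(snp_cols)].to_numpy()
    snps = pd.DataFrame(
        {"chrom": 0, "pos": 0, "a1": list(a1s), "a2": "N", "maf_target": np.nan},
        index=pd.Index(ids, name="snp_id"),
    )
    return GenotypeMatrix(stratum, df["IID"].to_numpy(dtype=str), df["FID"].to_numpy(dtype=str),
                          X.astype(np.int8), snps)


def write_phenotypes(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sim_truth(truth, path):
    Path(path).write_text(truth.to_json())


def read_sim_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_grm(grm: GRM, prefix):
    """GCTA-like text layout: ``<prefix>.grm.txt`` rows ``i j m A_ij`` over the
    lower triangle (1-based), plus ``<prefix>.grm.id``."""
    prefix = Path(prefix)
    n = grm.matrix.shape[0]
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m_snps}\t{grm.matrix[i, j]:.6g}\n")
    ids = grm.sample_ids if grm.sample_ids is not None else np.arange(1, n + 1).astype(str)
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in ids:
            fh.write(f"{s}\t{s}\n")


def read_grm(prefix) -> GRM:
    prefix = Path(prefix)
    ids = [line.split("\t")[1].strip() for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    A = np.zeros((n, n))
    m = 0
    for line in open(f"{prefix}.grm.txt"):
        i, j, m_s, a = line.split("\t")
        i, j = int(i) - 1, int(j) - 1
        A[i, j] = A[j, i] = float(a)
        m = int(m_s)
    return GRM(A, m, np.array(ids))


GWAS_COLUMNS = {"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2",
                "freq": "FREQ", "beta": "BETA", "se": "SE", "p": "P", "n": "N"}


def write_gwas(records: pd.DataFrame, path):
    out = records[list(GWAS_COLUMNS)].rename(columns=GWAS_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    inv = {v: k for k, v in GWAS_COLUMNS.items()}
    return df.rename(columns=inv)


def qq_data(records: pd.DataFrame) -> pd.DataFrame:
    """Expected vs observed −log10 p for QQ plotting, smallest p first."""
    p = np.sort(records["p"].to_numpy())
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"expected": expected, "observed": -np.log10(p)})
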