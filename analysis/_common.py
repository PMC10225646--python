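"""Shared setup for the numbered analysis scripts.

The study cohort is exactly reproducible from STUDY_SEED, so later stages
re-derive genotypes/phenotypes deterministically instead of re-reading the
(large) exported genotype files; the files written by 01_simulate_cohort.py
are the portable record of the same data.
"""

from pathlib import Path

from gestmr import experiments, pipeline

STUDY_SEED = 13
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "study"

METABOLITES = [f"M{i + 1:02d}" for i in range(experiments.N_METABOLITES)]
CLASS_MAP = experiments.STUDY_CLASSES


def config():
    return experiments.study_config(STUDY_SEED)


def cohort():
    from gestmr.cohort import simulate_cohort

    return simulate_cohort(config())


def prepared_tables():
    """Outlier-masked metabolites + log outcomes per stratum."""
    out = {}
    for stratum, (geno, pheno, truth) in cohort().items():
        prepared, report = pipeline.prepare_stratum(pheno, METABOLITES,
                                                    iqr_multiplier=1.5,
                                                    transform_policy="none")
        out[stratum] = (geno, prepared, report, truth)
    return out


def outdir(sub=""):
    d = RESULTS / sub if sub else RESULTS
    d.mkdir(parents=True, exist_ok=True)
    return d
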