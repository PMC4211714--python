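"""Plain-TSV readers and writers for the per-cohort schemas.

All interchange is tab-separated text: a genotype table (one row per
individual, one 0/1/2/NA column per SNP), a phenotype/diet/covariate table,
and a bare estimates table (label, beta, lo, hi[, n, outcome, replaced])
for meta-analysis of pre-fitted cohort results.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .longitudinal import annualize

PHENO_COLUMNS = [
    "protein_e", "carbohydrate_e", "fat_e", "alcohol_e", "energy_mj",
    "sex", "age_y", "height_cm", "bw0_kg", "bw1_kg", "wc0_cm", "wc1_cm",
    "smoking", "pa", "education", "menopause", "fu_years",
]


def read_genotypes(path) -> pd.DataFrame:
    g = pd.read_csv(path, sep="\t", index_col="individual_id")
    return g.astype(float)


def read_pheno(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="individual_id")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns and not c.startswith("wc")]
    if missing:
        raise ValueError(f"{path}: phenotype table lacks columns {missing}")
    return df


def read_cohort(name: str, pheno_path, genotype_path=None) -> Cohort:
    """Load one cohort and attach annualized changes."""
    pheno = annualize(read_pheno(pheno_path))
    geno = read_genotypes(genotype_path) if genotype_path else None
    if geno is not None:
        geno = geno.reindex(pheno.index)
    return Cohort(name=name, pheno=pheno, genotypes=geno)


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    pheno = cohort.pheno.drop(columns=[c for c in ("d_bw", "d_wc") if c in cohort.pheno.columns])
    paths["pheno"] = outdir / f"{cohort.name}_pheno.tsv"
    pheno.to_csv(paths["pheno"], sep="\t", float_format="%.10g")
    if cohort.genotypes is not None:
        paths["genotypes"] = outdir / f"{cohort.name}_genotypes.tsv"
        cohort.genotypes.to_csv(paths["genotypes"], sep="\t", float_format="%g")
    return paths


def read_estimates(path=None) -> pd.DataFrame:
    """Read a bare estimates table for meta-only pooling.

    With no ``path``, returns the bundled cohort-level estimates of annual
    body-weight (gram/y per 5 E%) and waist (mm/y per 5 E%) change per
    protein substitution reported for the three Danish cohorts, usable to
    reproduce the pooled results without individual-level data.
    """
    if path is None:
        path = resources.files("genediet.data") / "cohort_estimates.tsv"
    df = pd.read_csv(path, sep="\t")
    if not {"label", "beta"}.issubset(df.columns):
        raise ValueError("estimates table needs at least columns label, beta and lo/hi or se")
    if "se" not in df.columns:
        if not {"lo", "hi"}.issubset(df.columns):
            raise ValueError("estimates table needs either se or lo/hi columns")
    return df
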