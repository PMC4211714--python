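"""The joined per-cohort container the analysis operates on."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class Cohort:
    """One cohort: phenotypes/diet/covariates plus an optional dosage matrix.

    ``pheno`` is indexed by individual id and carries the diet E% columns,
    covariates, anthropometry and annualized changes; ``genotypes`` holds
    risk-allele dosages (0/1/2/NaN), one column per SNP, aligned on the same
    index.
    """

    name: str
    pheno: pd.DataFrame
    genotypes: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.pheno)

    def has_waist(self) -> bool:
        return "wc0_cm" in self.pheno.columns and self.pheno["wc0_cm"].notna().any()
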