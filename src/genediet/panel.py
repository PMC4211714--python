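"""SNP panel definitions and genetic predisposition scores.

A predisposition score is the unweighted count of adiposity-associated risk
alleles over a defined SNP subset.  Four scores are supported: ``complete``
(every SNP on the panel) and three trait-specific subsets tagged ``BMI``,
``WC`` and ``WHR_BMI`` (waist-hip ratio adjusted for BMI).  Trait tags need
not partition the panel: a SNP associated with two traits carries both tags,
so the complete score is computed directly over all panel SNPs and is not in
general the sum of the three subset scores.

Scores are complete-case: an individual missing any dosage among the
selected SNPs receives a missing score.  This mirrors the attrition pattern
of real cohort data, where per-score N shrinks with subset size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

TRAITS = ("BMI", "WC", "WHR_BMI")
SCORE_TYPES = ("complete", "BMI", "WC", "WHR_BMI")

_IUPAC_BASES = set("ACGT")


class PanelError(ValueError):
    """Configuration problem in the SNP panel or score request."""


@dataclass(frozen=True)
class SnpDefinition:
    """One panel SNP: its risk allele, trait tag(s) and allele frequency.

    ``risk_allele_freq`` is used only by the synthetic genotype generator;
    it plays no role in score building.
    """

    snp_id: str
    risk_allele: str
    traits: frozenset[str] = field(default_factory=frozenset)
    risk_allele_freq: float | None = None

    def __post_init__(self) -> None:
        if self.risk_allele not in _IUPAC_BASES:
            raise PanelError(f"{self.snp_id}: risk allele {self.risk_allele!r} is not a single base")
        unknown = self.traits - set(TRAITS)
        if unknown or not self.traits:
            raise PanelError(f"{self.snp_id}: trait tags {sorted(self.traits)} must be drawn from {TRAITS}")
        if self.risk_allele_freq is not None and not 0.0 < self.risk_allele_freq < 1.0:
            raise PanelError(f"{self.snp_id}: risk allele frequency {self.risk_allele_freq} outside (0, 1)")


def load_panel(path=None) -> list[SnpDefinition]:
    """Read a SNP panel TSV (columns: snp_id, risk_allele, trait, risk_allele_freq).

    The trait column may hold several comma-separated tags.  With no ``path``
    the bundled 50-SNP panel (33 BMI / 6 WC / 14 WHR_BMI tags) is returned.
    """
    if path is None:
        path = resources.files("genediet.data") / "snp_panel.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "risk_allele": str, "trait": str})
    defs = []
    for row in df.itertuples(index=False):
        freq = getattr(row, "risk_allele_freq", None)
        defs.append(
            SnpDefinition(
                snp_id=row.snp_id,
                risk_allele=row.risk_allele,
                traits=frozenset(t.strip() for t in row.trait.split(",")),
                risk_allele_freq=None if freq is None or pd.isna(freq) else float(freq),
            )
        )
    ids = [d.snp_id for d in defs]
    if len(set(ids)) != len(ids):
        raise PanelError("duplicate snp_id in panel")
    return defs


def snps_for_score(defs: list[SnpDefinition], score_type: str) -> list[str]:
    """SNP ids entering a given score, in panel order."""
    if score_type == "complete":
        return [d.snp_id for d in defs]
    if score_type not in TRAITS:
        raise PanelError(f"unknown score type {score_type!r}; expected one of {SCORE_TYPES}")
    subset = [d.snp_id for d in defs if score_type in d.traits]
    if not subset:
        raise PanelError(f"no panel SNP carries trait tag {score_type!r}")
    return subset


def build_score(
    dosages: pd.DataFrame, defs: list[SnpDefinition], score_type: str = "complete"
) -> pd.Series:
    """Sum risk-allele dosages over the selected SNP subset per individual.

    Parameters
    ----------
    dosages
        Individuals in rows (index = individual id), SNPs in columns; values
        0/1/2 or NaN for a failed genotype.
    defs
        Panel definitions; the dosage columns must cover the selected subset.
    score_type
        ``complete``, ``BMI``, ``WC`` or ``WHR_BMI``.

    Returns a float Series named after the score; individuals missing any
    dosage in the subset get NaN (complete-case policy).
    """
    subset = snps_for_score(defs, score_type)
    missing_cols = [s for s in subset if s not in dosages.columns]
    if missing_cols:
        raise PanelError(f"dosage matrix lacks panel SNPs: {missing_cols[:5]}...")
    sub = dosages[subset]
    bad = sub.stack().dropna()
    if not bad.isin([0, 1, 2]).all():
        raise PanelError("dosages must be 0, 1, 2 or missing")
    score = sub.sum(axis=1, skipna=False).astype(float)
    score.name = f"score_{score_type}"
    return score


def split_at_mean(scores: pd.Series) -> pd.Series:
    """Label each individual ``high`` or ``low`` against the within-cohort mean.

    ``high`` means strictly above the mean of non-missing scores; a score
    exactly equal to the mean is labelled ``low`` (tie rule documented in the
    methods note).  Missing scores stay missing.
    """
    valid = scores.dropna()
    out = pd.Series(pd.NA, index=scores.index, dtype="object", name="score_group")
    if valid.empty:
        warnings.warn("all scores missing; empty mean-split", stacklevel=2)
        return out
    mean = valid.mean()
    out.loc[valid.index] = np.where(valid > mean, "high", "low")
    return out
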