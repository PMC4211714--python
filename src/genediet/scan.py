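"""Per-SNP substitution-interaction scan with Bonferroni correction.

Each panel SNP's dosage takes the place of the predisposition score in the
substitution-interaction model; one fit per SNP yields the interaction
estimate on the reporting scale and a Bonferroni-corrected p-value.  The
correction multiplier stays at the full panel size even when some SNPs are
skipped in a given cohort (monomorphic or unusable), because the family of
tests is defined by the panel, not by what happened to converge.
"""

from __future__ import annotations

import logging
from dataclasses import replace as dc_replace

import pandas as pd

from .cohort import Cohort
from .diet import DesignSpec, assemble_design, interaction_column_name
from .inference import FitError, fit_linear, rescale_effect
from .panel import SnpDefinition

log = logging.getLogger(__name__)


def bonferroni(p_raw: float, m_tests: int) -> float:
    """min(1, m × p)."""
    return min(1.0, m_tests * p_raw)


def scan_snps(cohort: Cohort, defs: list[SnpDefinition], spec: DesignSpec,
              m_tests: int | None = None) -> pd.DataFrame:
    """Interaction fit per SNP; returns one row per SNP attempted.

    ``spec.score_type`` is ignored — the scanned dosage is the interacting
    variable.  ``m_tests`` defaults to the panel size.
    """
    if cohort.genotypes is None:
        raise ValueError(f"cohort {cohort.name} carries no genotypes")
    m = m_tests if m_tests is not None else len(defs)
    unit = "g/y" if spec.outcome == "dBW" else "mm/y"
    int_col = interaction_column_name(spec.replaced)
    rows = []
    for d in defs:
        dosage = cohort.genotypes[d.snp_id]
        snp_spec = dc_replace(spec, parameterization="substitution", score_type="complete")
        try:
            X, y, _ = assemble_design(cohort.pheno, snp_spec, score=dosage)
            fits = fit_linear(X, y)
        except (FitError, ValueError) as exc:
            log.warning("%s: SNP %s skipped (%s)", cohort.name, d.snp_id, exc)
            continue
        if int_col not in fits:   # interaction dropped as constant (monomorphic SNP)
            log.warning("%s: SNP %s skipped (no estimable interaction)", cohort.name, d.snp_id)
            continue
        f = rescale_effect(fits[int_col], outcome_unit=unit)
        rows.append({
            "snp_id": d.snp_id, "cohort": cohort.name, "outcome": spec.outcome,
            "replaced": spec.replaced, "beta_int": f.beta, "se": f.se,
            "p_raw": f.p, "p_corrected": bonferroni(f.p, m), "m_tests": m, "n": f.n,
        })
    return pd.DataFrame(rows)
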