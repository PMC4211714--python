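"""Linear model fitting and reporting-scale conversion.

Models are ordinary least squares with classical (homoskedastic) standard
errors.  Confidence intervals and p-values use normal quantiles by default
— cohort sizes run to the thousands, where t and z are indistinguishable —
with a switch to t quantiles for small samples.

Effects are estimated in natural units (outcome kg/y or cm/y, diet terms
per 1 E%) and converted for reporting: per 5 E% substitution, body weight
in gram/y (×1000), waist in mm/y (×10); interaction terms additionally per
single risk allele (score units are already alleles, so no extra factor).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

OUTCOME_UNIT_FACTOR = {"g/y": 1000.0, "mm/y": 10.0}


class FitError(ValueError):
    """Design unusable for OLS (rank deficiency, too few rows)."""


@dataclass(frozen=True)
class FitResult:
    """One regression term on a stated reporting scale."""

    term: str
    beta: float
    se: float
    lo: float
    hi: float
    p: float
    n: int
    scale: str = "natural"

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.lo, self.hi)


def fit_linear(X: pd.DataFrame, y: pd.Series, use_t: bool = False) -> dict[str, FitResult]:
    """OLS fit returning a FitResult per design column, in natural units.

    Raises on rank deficiency (naming the offending columns) and when the
    row count does not exceed the column count.
    """
    Xa = np.asarray(X, dtype=float)
    n, p = Xa.shape
    if n <= p:
        raise FitError(f"n={n} rows do not exceed p={p} columns")
    rank = np.linalg.matrix_rank(Xa)
    if rank < p:
        from .diet import _collinear_columns
        raise FitError(f"rank-deficient design; collinear columns: {_collinear_columns(Xa, list(X.columns))}")
    res = sm.OLS(np.asarray(y, dtype=float), Xa).fit(use_t=use_t)
    q = stats.t.ppf(0.975, res.df_resid) if use_t else stats.norm.ppf(0.975)
    out = {}
    for j, term in enumerate(X.columns):
        b, se = res.params[j], res.bse[j]
        out[term] = FitResult(term=term, beta=float(b), se=float(se),
                              lo=float(b - q * se), hi=float(b + q * se),
                              p=float(res.pvalues[j]), n=n)
    return out


def rescale_effect(f: FitResult, per_e_pct: float = 5.0, outcome_unit: str = "g/y",
                   label: str | None = None) -> FitResult:
    """Convert a natural-scale effect to the reporting scale.

    Multiplies beta, SE and CI by ``per_e_pct`` (effect per 5 E% rather than
    per 1 E%) and by the outcome factor (kg/y → g/y is ×1000, cm/y → mm/y is
    ×10).  z = beta/se, and hence p, are unchanged.  Interaction terms stay
    per single risk allele.
    """
    if outcome_unit not in OUTCOME_UNIT_FACTOR:
        raise FitError(f"unknown outcome unit {outcome_unit!r}; expected one of {sorted(OUTCOME_UNIT_FACTOR)}")
    c = per_e_pct * OUTCOME_UNIT_FACTOR[outcome_unit]
    return replace(f, beta=f.beta * c, se=f.se * c, lo=f.lo * c, hi=f.hi * c,
                   scale=label or f"per {per_e_pct:g} E% [{outcome_unit}]")


def project_effect(beta_int: float, extra_e_pct: float, n_alleles: float) -> float:
    """Scale a per-(5 E%, per-allele) interaction coefficient to a scenario.

    Given beta_int in g/y per 5 E% per risk allele, the projected annual
    weight-change contribution of substituting ``extra_e_pct`` energy percent
    in a carrier of ``n_alleles`` risk alleles is
    beta_int × (extra_e_pct / 5) × n_alleles.
    """
    return beta_int * (extra_e_pct / 5.0) * n_alleles
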