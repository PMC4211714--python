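"""Macronutrient substitution design matrices.

Total energy intake is split into four parts — protein, carbohydrate, fat
and alcohol — expressed as percent of energy (E%) summing to 100.  Because
of that closure, a regression containing three of the four E% terms is a
*substitution model*: the protein coefficient is the effect of 1 E% protein
replacing 1 E% of the omitted macronutrient, holding the two included ones
fixed.  Two equivalent parameterizations are provided:

* leave-one-out — covariates (protein, alcohol, kept), omitting the
  replaced macronutrient;
* substitution — a single substitution variable s = (protein − replaced)/2
  plus (kept, alcohol).  The coefficient of s equals the leave-one-out
  protein coefficient, and the product s × score is a *true* substitution
  interaction: it is specific to which macronutrient protein replaces,
  unlike a plain protein × score product.

Total energy is deliberately not a covariate: raising relative protein
intake may itself change total energy, and the models are interpreted as
changing the E% composition with total intake free to move.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MACRONUTRIENTS = ("protein", "carbohydrate", "fat", "alcohol")
_E_COLS = {m: f"{m}_e" for m in MACRONUTRIENTS}
REPLACEABLE = ("carbohydrate", "fat")
OUTCOMES = ("dBW", "dWC")

#: covariate schema: column -> (kind, levels or None); reference level first
CATEGORICAL = {
    "smoking": ("never", "former", "current"),
    "pa": (1, 2, 3, 4),
    "education": ("low", "high"),
}
MENOPAUSE_LEVELS = ("male", "pre", "post")
CONTINUOUS_COVARIATES = ("height_cm",)
BASELINE_COLUMN = {"dBW": "bw0_kg", "dWC": "wc0_cm"}


class DesignError(ValueError):
    """Invalid design request or unusable cohort data."""


@dataclass(frozen=True)
class DesignSpec:
    """What to fit: which substitution, parameterization, interaction and outcome.

    ``score_type=None`` fits the diet-only model; otherwise the named
    predisposition score and its substitution interaction enter the design.
    ``adjust_age`` and ``adjust_followup`` add age and follow-up time, both
    off by default (the published adjustment set omits them).
    """

    replaced: str = "carbohydrate"
    parameterization: str = "substitution"
    score_type: str | None = None
    outcome: str = "dBW"
    adjust_age: bool = False
    adjust_followup: bool = False

    def __post_init__(self) -> None:
        if self.replaced not in REPLACEABLE:
            raise DesignError(f"replaced must be one of {REPLACEABLE}, got {self.replaced!r}")
        if self.parameterization not in ("leave_one_out", "substitution"):
            raise DesignError(f"unknown parameterization {self.parameterization!r}")
        if self.outcome not in OUTCOMES:
            raise DesignError(f"outcome must be one of {OUTCOMES}")
        if self.score_type is not None and self.parameterization != "substitution":
            raise DesignError("score interaction requires the substitution parameterization")


def check_composition(df: pd.DataFrame, tol: float = 0.5, renormalize: bool = True) -> pd.DataFrame:
    """Validate the four-part E% closure; renormalize rows off by more than ``tol``.

    Real diet-record E% rarely sums to exactly 100; rows within ``tol`` E%
    are left untouched, rows further out are rescaled to 100 with a warning.
    Negative components are always an error.
    """
    cols = list(_E_COLS.values())
    comp = df[cols]
    if (comp.dropna() < 0).any().any():
        raise DesignError("negative macronutrient E% values")
    total = comp.sum(axis=1)
    off = (total - 100.0).abs() > tol
    if off.any():
        if not renormalize:
            raise DesignError(f"{int(off.sum())} rows violate the 100 E% closure by more than {tol}")
        warnings.warn(f"renormalizing {int(off.sum())} rows whose E% sum deviates from 100 by more than {tol}", stacklevel=2)
        df = df.copy()
        df.loc[off, cols] = comp.loc[off].div(total[off], axis=0) * 100.0
    return df


def leave_one_out_terms(df: pd.DataFrame, replaced: str) -> pd.DataFrame:
    """Diet covariates (protein, alcohol, kept) omitting the replaced macronutrient."""
    if replaced not in REPLACEABLE:
        raise DesignError(f"cannot replace {replaced!r}; only {REPLACEABLE} may be replaced by protein")
    kept = "fat" if replaced == "carbohydrate" else "carbohydrate"
    return df[[_E_COLS["protein"], _E_COLS["alcohol"], _E_COLS[kept]]].copy()


def substitution_terms(df: pd.DataFrame, replaced: str) -> pd.DataFrame:
    """Substitution variable s = (protein − replaced)/2 plus (kept, alcohol) covariates."""
    if replaced not in REPLACEABLE:
        raise DesignError(f"cannot replace {replaced!r}; only {REPLACEABLE} may be replaced by protein")
    kept = "fat" if replaced == "carbohydrate" else "carbohydrate"
    s = (df[_E_COLS["protein"]] - df[_E_COLS[replaced]]) / 2.0
    out = pd.DataFrame({f"sub_protein_{replaced}": s})
    out[_E_COLS[kept]] = df[_E_COLS[kept]]
    out[_E_COLS["alcohol"]] = df[_E_COLS["alcohol"]]
    return out


def interaction_column(s: pd.Series, score: pd.Series) -> pd.Series:
    """Product of the substitution variable and a predisposition score."""
    prod = s * score
    prod.name = f"{s.name}:score"
    return prod


def substitution_column_name(replaced: str) -> str:
    return f"sub_protein_{replaced}"


def interaction_column_name(replaced: str) -> str:
    return f"sub_protein_{replaced}:score"


def _encode_categoricals(df: pd.DataFrame) -> pd.DataFrame:
    """Indicator-encode the fixed categorical covariates, reference level first."""
    out = {}
    for col, levels in CATEGORICAL.items():
        vals = df[col]
        bad = ~vals.isin(levels) & vals.notna()
        if bad.any():
            raise DesignError(f"column {col!r} has levels outside {levels}: {sorted(vals[bad].unique())}")
        for lev in levels[1:]:
            out[f"{col}_{lev}"] = (vals == lev).astype(float).where(vals.notna())
    out["sex_female"] = df["sex"].map({"male": 0.0, "female": 1.0})
    # menopause is a 3-level factor (male / pre / post); together with the sex
    # indicator a single post-menopause column spans it without collinearity
    meno = df["menopause"]
    bad = ~meno.isin(MENOPAUSE_LEVELS) & meno.notna()
    if bad.any():
        raise DesignError(f"column 'menopause' has levels outside {MENOPAUSE_LEVELS}: {sorted(meno[bad].unique())}")
    out["menopause_post"] = (meno == "post").astype(float).where(meno.notna())
    return pd.DataFrame(out, index=df.index)


def _collinear_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    """Name the columns involved in a rank deficiency via pivoted QR."""
    _, r, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(X, pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > thresh).sum())
    return [labels[i] for i in sorted(piv[rank:])]


def assemble_design(
    cohort: pd.DataFrame,
    spec: DesignSpec,
    score: pd.Series | None = None,
    composition_tol: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Build the full-rank design matrix and outcome vector for one model fit.

    ``cohort`` is a per-individual phenotype frame carrying the diet E%
    columns, covariates and annualized outcomes (``d_bw`` kg/y, ``d_wc``
    cm/y).  Columns: intercept, diet terms per the parameterization, score
    and substitution interaction when requested, baseline level of the
    outcome, height, sex, smoking/physical-activity/education/menopause
    indicators, and concurrent d_bw when the outcome is dWC.  Rows are
    complete cases only; the attrition count is logged and returned in the
    info dict.  Constant indicator columns (a level absent from the cohort)
    are dropped with a warning; any remaining rank deficiency is an error
    naming the collinear columns.
    """
    cohort = check_composition(cohort, tol=composition_tol)
    if spec.parameterization == "leave_one_out":
        diet = leave_one_out_terms(cohort, spec.replaced)
    else:
        diet = substitution_terms(cohort, spec.replaced)
    parts = [diet]

    if spec.score_type is not None:
        if score is None:
            raise DesignError("spec requests a score interaction but no score was supplied")
        s = diet[substitution_column_name(spec.replaced)]
        sc = score.reindex(cohort.index).astype(float)
        parts.append(pd.DataFrame({"score": sc, interaction_column_name(spec.replaced): s * sc}))

    base_col = BASELINE_COLUMN[spec.outcome]
    adj = pd.DataFrame({base_col: cohort[base_col], "height_cm": cohort["height_cm"]})
    parts.append(adj)
    parts.append(_encode_categoricals(cohort))
    if spec.outcome == "dWC":
        parts.append(cohort[["d_bw"]])
    if spec.adjust_age:
        parts.append(cohort[["age_y"]])
    if spec.adjust_followup:
        parts.append(cohort[["fu_years"]])

    X = pd.concat(parts, axis=1)
    y = cohort["d_bw"] if spec.outcome == "dBW" else cohort["d_wc"]
    keep = X.notna().all(axis=1) & y.notna()
    n_total, n_used = len(X), int(keep.sum())
    log.info("design %s/%s/%s: %d rows read, %d dropped incomplete, %d used",
             spec.outcome, spec.replaced, spec.score_type, n_total, n_total - n_used, n_used)
    if n_used == 0:
        raise DesignError("no complete-case rows left for this design")
    X, y = X.loc[keep], y.loc[keep]

    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant design columns: {const}", stacklevel=2)
        X = X.drop(columns=const)
    X.insert(0, "const", 1.0)

    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError(f"design is rank deficient; collinear columns: {_collinear_columns(X.to_numpy(), list(X.columns))}")
    info = {"n_total": n_total, "n_used": n_used, "n_dropped": n_total - n_used,
            "dropped_constant": const}
    return X, y, info
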