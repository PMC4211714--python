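"""Annualized anthropometric change, energy balance and weight-gainer selection.

Follow-up time varies between and within cohorts, so body-weight and waist
changes are annualized: (follow-up − baseline) / follow-up years, in kg/y
and cm/y.  Observed annual weight change also serves as a crude proxy for
cumulative net energy balance, trichotomized at ±0.5 kg/y.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

ENERGY_BALANCE_CLASSES = ("negative", "neutral", "positive")

#: kJ of metabolizable energy per gram of protein (Atwater-style factor)
KJ_PER_G_PROTEIN = 17.0


def annualize(df: pd.DataFrame) -> pd.DataFrame:
    """Add annualized change columns ``d_bw`` (kg/y) and ``d_wc`` (cm/y).

    Expects columns bw0_kg, bw1_kg, fu_years and optionally wc0_cm, wc1_cm.
    Rows with non-positive follow-up time get missing changes (and a logged
    count); a missing waist measure at either visit leaves only d_wc missing.
    """
    out = df.copy()
    fu = out["fu_years"]
    bad = fu.notna() & (fu <= 0)
    if bad.any():
        log.warning("rejecting %d rows with non-positive follow-up time", int(bad.sum()))
    fu = fu.where(~bad)
    out["d_bw"] = (out["bw1_kg"] - out["bw0_kg"]) / fu
    if "wc0_cm" in out.columns and "wc1_cm" in out.columns:
        out["d_wc"] = (out["wc1_cm"] - out["wc0_cm"]) / fu
    else:
        out["d_wc"] = np.nan
    return out


def classify_energy_balance(d_bw) -> pd.Series | str:
    """Trichotomize annual weight change at ±0.5 kg/y.

    negative < −0.5; neutral within the closed interval [−0.5, 0.5];
    positive > 0.5.  Accepts a scalar or a Series.
    """
    scalar = np.isscalar(d_bw)
    x = pd.Series([d_bw]) if scalar else pd.Series(d_bw)
    lab = pd.Series(pd.NA, index=x.index, dtype="object")
    lab[x < -0.5] = "negative"
    lab[(x >= -0.5) & (x <= 0.5)] = "neutral"
    lab[x > 0.5] = "positive"
    return lab.iloc[0] if scalar else lab


def protein_g_per_kg(df: pd.DataFrame) -> pd.Series:
    """Protein intake in g per kg baseline body weight per day.

    g/kg/d = (protein E%/100) × (energy MJ/d × 1000 kJ/MJ) / 17 kJ/g / bw0.
    The 17 kJ/g protein energy factor is configurable at module level.
    """
    kj_per_day = df["energy_mj"] * 1000.0
    grams = df["protein_e"] / 100.0 * kj_per_day / KJ_PER_G_PROTEIN
    return grams / df["bw0_kg"]


def protein_by_subgroup(cohort: pd.DataFrame, score_group: pd.Series) -> pd.DataFrame:
    """Mean protein intake in six (energy balance × score high/low) cells.

    For each cell and each intake scale (E% and g/kg/day): n, mean,
    SEM = sd/√n and a normal 95% CI.  Empty cells appear with n = 0 and
    missing statistics.
    """
    d = cohort.copy()
    d["balance"] = classify_energy_balance(d["d_bw"])
    d["score_group"] = score_group.reindex(d.index)
    d["protein_g_kg_d"] = protein_g_per_kg(d)
    rows = []
    for bal in ENERGY_BALANCE_CLASSES:
        for grp in ("low", "high"):
            cell = d[(d["balance"] == bal) & (d["score_group"] == grp)]
            row = {"balance": bal, "score_group": grp, "n": len(cell)}
            for scale, col in (("e_pct", "protein_e"), ("g_kg_d", "protein_g_kg_d")):
                vals = cell[col].dropna()
                if len(vals) == 0:
                    row.update({f"mean_{scale}": np.nan, f"sem_{scale}": np.nan,
                                f"lo_{scale}": np.nan, f"hi_{scale}": np.nan})
                    continue
                mean = vals.mean()
                sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                z = stats.norm.ppf(0.975)
                row.update({f"mean_{scale}": mean, f"sem_{scale}": sem,
                            f"lo_{scale}": mean - z * sem, f"hi_{scale}": mean + z * sem})
            rows.append(row)
    return pd.DataFrame(rows)


def select_weight_gainers(cohort: pd.DataFrame, k_per_sex: int) -> pd.Index:
    """Pick the top-k weight gainers per sex, net of baseline covariates.

    Within each sex a linear regression of annual weight change on baseline
    age, body weight, height, smoking status and follow-up time is fitted;
    individuals are ranked by descending residual and the top ``k_per_sex``
    returned.  Residual ties break on individual id for determinism.
    """
    needed = ["d_bw", "age_y", "bw0_kg", "height_cm", "smoking", "fu_years", "sex"]
    d = cohort[needed].dropna()
    selected = []
    for sex, grp in d.groupby("sex", sort=True):
        X = pd.DataFrame({
            "age_y": grp["age_y"], "bw0_kg": grp["bw0_kg"], "height_cm": grp["height_cm"],
            "smoking_former": (grp["smoking"] == "former").astype(float),
            "smoking_current": (grp["smoking"] == "current").astype(float),
            "fu_years": grp["fu_years"],
        })
        X = X.loc[:, X.nunique() > 1]
        X = sm.add_constant(X, has_constant="add")
        resid = sm.OLS(grp["d_bw"], X).fit().resid
        if k_per_sex > len(grp):
            warnings.warn(f"k_per_sex={k_per_sex} exceeds {sex} group size {len(grp)}; returning all", stacklevel=2)
        order = pd.Series(resid).to_frame("resid")
        order["_id"] = order.index.astype(str)
        order = order.sort_values(["resid", "_id"], ascending=[False, True], kind="mergesort")
        selected.append(order.index[:k_per_sex])
    return selected[0].append(selected[1:]) if len(selected) > 1 else selected[0]
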