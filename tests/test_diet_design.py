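import numpy as np
import pandas as pd
import pytest

import genediet as gd
from genediet.diet import (DesignError, DesignSpec, check_composition,
                           interaction_column_name, substitution_column_name)

from conftest import toy_pheno


def comp_row(p, c, f, a):
    return pd.DataFrame({"protein_e": [p], "carbohydrate_e": [c],
                         "fat_e": [f], "alcohol_e": [a]})


def test_leave_one_out_selects_kept_macronutrient():
    d = comp_row(15, 45, 35, 5)
    fat_repl = gd.leave_one_out_terms(d, "fat")
    assert list(fat_repl.columns) == ["protein_e", "alcohol_e", "carbohydrate_e"]
    assert fat_repl.iloc[0].tolist() == [15, 5, 45]
    carb_repl = gd.leave_one_out_terms(d, "carbohydrate")
    assert list(carb_repl.columns) == ["protein_e", "alcohol_e", "fat_e"]
    assert carb_repl.iloc[0].tolist() == [15, 5, 35]


def test_substitution_variable_is_half_difference():
    d = comp_row(15, 45, 35, 5)
    s = gd.substitution_terms(d, "fat")
    assert s["sub_protein_fat"].iloc[0] == (15 - 35) / 2 == -10
    even = gd.substitution_terms(comp_row(20, 40, 20, 20), "fat")
    assert even["sub_protein_fat"].iloc[0] == 0


@pytest.mark.parametrize("bad", ["protein", "alcohol"])
def test_only_carbohydrate_or_fat_replaceable(bad):
    d = comp_row(15, 45, 35, 5)
    with pytest.raises(DesignError):
        gd.leave_one_out_terms(d, bad)
    with pytest.raises(DesignError):
        gd.substitution_terms(d, bad)


def test_interaction_column_arithmetic():
    s = pd.Series([-10.0, 3.0], name="sub_protein_fat")
    g = pd.Series([44.0, 0.0])
    prod = gd.interaction_column(s, g)
    assert prod.tolist() == [-440.0, 0.0]


@pytest.mark.parametrize("replaced", ["carbohydrate", "fat"])
def test_reparameterization_equivalence(replaced):
    """Substitution and leave-one-out models span the same space.

    Under the 100 E% closure: beta_s = beta_P, beta_kept(sub) =
    beta_kept(loo) - beta_P/2, beta_A(sub) = beta_A(loo) - beta_P/2, and
    fitted values coincide to numerical precision.
    """
    ph = toy_pheno(n=120, seed=9)
    y = ph["d_bw"]
    kept = "fat_e" if replaced == "carbohydrate" else "carbohydrate_e"

    loo = gd.leave_one_out_terms(ph, replaced)
    loo.insert(0, "const", 1.0)
    sub = gd.substitution_terms(ph, replaced)
    sub.insert(0, "const", 1.0)
    f_loo = gd.fit_linear(loo, y)
    f_sub = gd.fit_linear(sub, y)

    bP = f_loo["protein_e"].beta
    assert f_sub[substitution_column_name(replaced)].beta == pytest.approx(bP, rel=1e-8)
    assert f_sub[kept].beta == pytest.approx(f_loo[kept].beta - bP / 2, rel=1e-8)
    assert f_sub["alcohol_e"].beta == pytest.approx(f_loo["alcohol_e"].beta - bP / 2, rel=1e-8)

    import statsmodels.api as sm
    yhat_loo = sm.OLS(y, loo).fit().fittedvalues
    yhat_sub = sm.OLS(y, sub).fit().fittedvalues
    assert np.allclose(yhat_loo, yhat_sub, atol=1e-10)


def test_substitution_symmetry_negates_coefficient():
    ph = toy_pheno(n=80, seed=13)
    y = ph["d_bw"]
    swapped = ph.copy()
    swapped["protein_e"], swapped["fat_e"] = ph["fat_e"], ph["protein_e"]
    X1 = gd.substitution_terms(ph, "fat")
    X2 = gd.substitution_terms(swapped, "fat")
    assert np.allclose(X2["sub_protein_fat"], -X1["sub_protein_fat"])
    X1.insert(0, "const", 1.0)
    X2.insert(0, "const", 1.0)
    b1 = gd.fit_linear(X1, y)["sub_protein_fat"].beta
    b2 = gd.fit_linear(X2, y)["sub_protein_fat"].beta
    assert b2 == pytest.approx(-b1, rel=1e-8)


def test_total_energy_never_enters_design():
    ph = toy_pheno(n=40, seed=3)
    spec = DesignSpec(replaced="carbohydrate", outcome="dBW")
    X1, y1, _ = gd.assemble_design(ph, spec)
    ph2 = ph.assign(energy_mj=ph["energy_mj"] + 7.5)
    X2, y2, _ = gd.assemble_design(ph2, spec)
    pd.testing.assert_frame_equal(X1, X2)
    pd.testing.assert_series_equal(y1, y2)


def test_design_column_bookkeeping(cohort_clean, defs):
    score = gd.build_score(cohort_clean.genotypes, defs, "complete")
    spec = DesignSpec(replaced="carbohydrate", score_type="complete", outcome="dBW")
    X, y, info = gd.assemble_design(cohort_clean.pheno, spec, score=score)
    assert list(X.columns) == [
        "const", "sub_protein_carbohydrate", "fat_e", "alcohol_e",
        "score", "sub_protein_carbohydrate:score",
        "bw0_kg", "height_cm",
        "smoking_former", "smoking_current", "pa_2", "pa_3", "pa_4",
        "education_high", "sex_female", "menopause_post",
    ]
    assert not X.isna().any().any()
    assert info["n_used"] + info["n_dropped"] == info["n_total"]

    spec_wc = DesignSpec(replaced="carbohydrate", score_type="complete", outcome="dWC")
    Xw, _, _ = gd.assemble_design(cohort_clean.pheno, spec_wc, score=score)
    extra = set(Xw.columns) - set(X.columns) - {"wc0_cm"}
    assert extra == {"d_bw"}  # dWC additionally adjusts for concurrent dBW
    assert "wc0_cm" in Xw.columns and "bw0_kg" not in Xw.columns


def test_single_smoking_level_dropped_with_warning():
    ph = toy_pheno(n=60, seed=21)
    ph["smoking"] = "never"
    with pytest.warns(UserWarning, match="constant design columns"):
        X, y, info = gd.assemble_design(ph, DesignSpec(outcome="dBW"))
    assert "smoking_former" not in X.columns and "smoking_current" not in X.columns
    gd.fit_linear(X, y)  # full rank restored


def test_composition_closure_renormalized_with_warning():
    ph = toy_pheno(n=10, seed=2)
    ph.loc[ph.index[0], "protein_e"] += 4.0  # closure now off by 4 E%
    with pytest.warns(UserWarning, match="renormalizing"):
        fixed = check_composition(ph)
    sums = fixed[["protein_e", "carbohydrate_e", "fat_e", "alcohol_e"]].sum(axis=1)
    assert np.allclose(sums, 100.0, atol=1e-9)
    with pytest.raises(DesignError):
        check_composition(ph.assign(fat_e=-1.0))


def test_rank_deficiency_names_collinear_columns():
    ph = toy_pheno(n=50, seed=7)
    # a unit score is dropped as constant, leaving its interaction column an
    # exact copy of the substitution variable
    score = pd.Series(1.0, index=ph.index)
    spec = DesignSpec(replaced="fat", score_type="complete", outcome="dBW")
    with pytest.warns(UserWarning, match="constant design columns"):
        with pytest.raises(DesignError, match="collinear"):
            gd.assemble_design(ph, spec, score=score)


def test_duplicated_continuous_covariate_is_rank_error():
    ph = toy_pheno(n=50, seed=7)
    ph["height_cm"] = 2.0 * ph["bw0_kg"]
    with pytest.raises(DesignError) as err:
        gd.assemble_design(ph, DesignSpec(outcome="dBW"))
    assert "bw0_kg" in str(err.value) or "height_cm" in str(err.value)
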