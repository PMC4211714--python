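from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import genediet as gd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def defs():
    return gd.load_panel()


@pytest.fixture(scope="session")
def cohort_small(defs):
    """One modest synthetic cohort with waist data and a little missingness."""
    return gd.simulate_cohort(gd.SimConfig(n=600, name="SMALL"), defs, seed=424242)


@pytest.fixture(scope="session")
def cohort_clean(defs):
    """Cohort without genotype missingness, for complete-case-free checks."""
    return gd.simulate_cohort(gd.SimConfig(n=500, name="CLEAN", missing_rate=0.0), defs, seed=31337)


def toy_pheno(n=8, seed=5):
    """Small handmade phenotype frame with every required column."""
    rng = np.random.default_rng(seed)
    comp = rng.dirichlet([14, 45, 33, 4], size=n) * 100.0
    df = pd.DataFrame({
        "protein_e": comp[:, 0], "carbohydrate_e": comp[:, 1],
        "fat_e": comp[:, 2], "alcohol_e": comp[:, 3],
        "energy_mj": rng.uniform(6, 12, n),
        "sex": rng.choice(["male", "female"], n),
        "age_y": rng.uniform(30, 60, n),
        "height_cm": rng.uniform(155, 190, n),
        "bw0_kg": rng.uniform(55, 95, n),
        "bw1_kg": rng.uniform(55, 95, n),
        "wc0_cm": rng.uniform(70, 110, n),
        "wc1_cm": rng.uniform(70, 110, n),
        "smoking": rng.choice(["never", "former", "current"], n),
        "pa": rng.choice([1, 2, 3, 4], n),
        "education": rng.choice(["low", "high"], n),
        "fu_years": rng.uniform(4.5, 6.0, n),
    }, index=pd.Index([f"p{i}" for i in range(n)], name="individual_id"))
    df["menopause"] = np.where(df["sex"] == "male", "male",
                               np.where(df["age_y"] > 50, "post", "pre"))
    return gd.annualize(df)
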