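import numpy as np
import pytest

import genediet as gd
from genediet.meta import MetaError, Z95, forest_table

# cohort-level body-weight rows (beta g/y per 5 E%, 95% CI) for the two
# substitutions, as printed for the three Danish cohorts
CARB_ROWS = [("MONICA", 123.4, 30.4, 216.4),
             ("DCH", -11.6, -102.6, 79.5),
             ("INTER99", 19.0, -47.6, 85.6)]
FAT_ROWS = [("MONICA", 56.3, -31.9, 144.4),
            ("DCH", 54.5, -45.1, 154.1),
            ("INTER99", 15.2, -54.1, 84.5)]


def studies(rows):
    return [gd.StudyEstimate.from_ci(l, b, lo, hi) for l, b, lo, hi in rows]


def test_se_from_ci_values():
    assert gd.se_from_ci(30.4, 216.4) == pytest.approx((216.4 - 30.4) / (2 * 1.959964))
    assert gd.se_from_ci(30.4, 216.4) == pytest.approx(47.45, abs=0.005)
    assert gd.se_from_ci(-1.96, 1.96) == pytest.approx(1.0, rel=1e-4)
    assert gd.se_from_ci(-1.6449, 1.6449, level=0.90) == pytest.approx(1.0, rel=1e-4)
    with pytest.raises(MetaError):
        gd.se_from_ci(2.0, 2.0)


def test_single_study_passes_through():
    s = gd.StudyEstimate("only", 1.5, 0.5)
    for pool in (gd.pool_fixed, gd.pool_random_dl):
        r = pool([s])
        assert r.beta == pytest.approx(1.5)
        assert r.se == pytest.approx(0.5)
        assert r.Q == 0.0 and r.tau2 == 0.0
        assert r.weights_pct["only"] == pytest.approx(100.0)


def test_two_identical_studies_halve_variance():
    s = gd.StudyEstimate("a", 2.0, 1.0), gd.StudyEstimate("b", 2.0, 1.0)
    r = gd.pool_fixed(list(s))
    assert r.beta == pytest.approx(2.0)
    assert r.se == pytest.approx(1.0 / np.sqrt(2))
    assert r.Q == pytest.approx(0.0)
    rr = gd.pool_random_dl(list(s))
    assert rr.beta == pytest.approx(2.0) and rr.tau2 == 0.0


def test_pooled_carbohydrate_row_reproduces_printed_overall():
    r = gd.pool_random_dl(studies(CARB_ROWS))
    assert r.beta == pytest.approx(41.0, abs=0.1)
    assert r.lo == pytest.approx(-32.3, abs=0.1)
    assert r.hi == pytest.approx(114.3, abs=0.1)
    w = r.weights_pct
    assert w["MONICA"] == pytest.approx(30.04, abs=0.05)
    assert w["DCH"] == pytest.approx(30.65, abs=0.05)
    assert w["INTER99"] == pytest.approx(39.31, abs=0.05)
    assert r.tau2 > 0
    # I2 from Q=4.69 on 2 df lands in the "significant" band
    assert r.i2_pct == pytest.approx(57.4, abs=0.5)
    assert r.band == "significant"


def test_pooled_fat_row_truncates_tau2_to_zero():
    st = studies(FAT_ROWS)
    r = gd.pool_random_dl(st)
    f = gd.pool_fixed(st)
    assert r.tau2 == 0.0
    assert r.beta == pytest.approx(36.3, abs=0.1)
    assert r.lo == pytest.approx(-11.5, abs=0.1)
    assert r.hi == pytest.approx(84.1, abs=0.1)
    assert r.weights_pct["MONICA"] == pytest.approx(29.41, abs=0.05)
    assert r.weights_pct["DCH"] == pytest.approx(23.01, abs=0.05)
    assert r.weights_pct["INTER99"] == pytest.approx(47.58, abs=0.05)
    # tau2 = 0 -> random equals fixed
    assert r.beta == pytest.approx(f.beta) and r.se == pytest.approx(f.se)


@pytest.mark.parametrize("i2,band", [
    (10, "no"), (57.4, "significant"), (25, "moderate"),
    (0, "no"), (50, "significant"), (75, "extreme"), (100, "extreme"),
])
def test_heterogeneity_bands(i2, band):
    assert gd.heterogeneity_band(i2) == band


def test_band_out_of_range_errors():
    with pytest.raises(MetaError):
        gd.heterogeneity_band(-1)
    with pytest.raises(MetaError):
        gd.heterogeneity_band(101)


def test_weights_sum_convexity_and_scale_equivariance():
    st = studies(CARB_ROWS)
    for pool in (gd.pool_fixed, gd.pool_random_dl):
        r = pool(st)
        assert sum(r.weights_pct.values()) == pytest.approx(100.0, abs=1e-6)
        betas = [s.beta for s in st]
        assert min(betas) <= r.beta <= max(betas)
    c = 3.7
    scaled = [gd.StudyEstimate(s.label, s.beta * c, s.se * c) for s in st]
    r1, r2 = gd.pool_random_dl(st), gd.pool_random_dl(scaled)
    assert r2.beta == pytest.approx(r1.beta * c, rel=1e-10)
    assert r2.se == pytest.approx(r1.se * c, rel=1e-10)
    assert r2.i2_pct == pytest.approx(r1.i2_pct, rel=1e-10)
    assert r2.weights_pct["DCH"] == pytest.approx(r1.weights_pct["DCH"], rel=1e-10)
    assert r2.band == r1.band


def test_infinite_heterogeneity_limit_equalizes_weights():
    st = [gd.StudyEstimate("a", -100.0, 0.1), gd.StudyEstimate("b", 0.0, 0.2),
          gd.StudyEstimate("c", 100.0, 0.15)]
    r = gd.pool_random_dl(st)   # tau2 >> se^2, so weights -> 1/k
    for w in r.weights_pct.values():
        assert w == pytest.approx(100 / 3, abs=0.5)


def test_against_statsmodels_dl_oracle():
    """Independent cross-check of the DL pooling against statsmodels."""
    from statsmodels.stats.meta_analysis import combine_effects
    rng = np.random.default_rng(17)
    betas = rng.normal(0, 2, size=5)
    ses = rng.uniform(0.5, 2.0, size=5)
    st = [gd.StudyEstimate(f"s{i}", b, s) for i, (b, s) in enumerate(zip(betas, ses))]
    ours = gd.pool_random_dl(st)
    ref = combine_effects(betas, ses**2, method_re="dl")
    assert ours.tau2 == pytest.approx(ref.tau2, rel=1e-10)
    frame = ref.summary_frame()
    assert ours.beta == pytest.approx(frame.loc["random effect", "eff"], rel=1e-8)
    assert gd.pool_fixed(st).beta == pytest.approx(frame.loc["fixed effect", "eff"], rel=1e-8)
    assert ours.Q == pytest.approx(float(ref.q), rel=1e-10)


def test_forest_table_mentions_every_study():
    st = studies(CARB_ROWS)
    txt = forest_table(st, gd.pool_random_dl(st))
    for name in ("MONICA", "DCH", "INTER99", "pooled", "tau^2"):
        assert name in txt
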