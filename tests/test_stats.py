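"""Cohort statistics: closed forms, degrees of freedom, and operating
characteristics under the generator."""

import numpy as np
import pandas as pd
import pytest

from beemorph import (
    PhantomParams,
    allometric_slope,
    asymmetry_quadrants,
    cohort_to_table,
    colony_effect_test,
    lateralization_test,
    pearson,
    percent_variation,
    sample_cohort,
    simulate_operating_characteristics,
)
from beemorph.core import ConfigError, DegenerateInputError, InvalidParameterError
from beemorph.phantom import HONEYBEE_HIVE_PLAN, HONEYBEE_POPULATIONS


# percent variation ----------------------------------------------------------


def test_percent_variation_closed_forms():
    assert percent_variation([1.0, 1.0, 1.0]) == 0.0
    assert percent_variation([0.5, 1.0]) == 50.0
    # total-brain min/max of the honey-bee cohort: (0.628-0.425)*100/0.628
    assert percent_variation([0.425, 0.5, 0.628]) == pytest.approx(32.32, abs=0.01)


def test_percent_variation_scale_invariant(rng):
    v = rng.uniform(0.5, 2.0, size=30)
    a = percent_variation(v)
    assert 0 <= a < 100
    assert percent_variation(17.3 * v) == pytest.approx(a)
    with pytest.raises(InvalidParameterError):
        percent_variation([1.0])


# correlation and allometry --------------------------------------------------


def test_pearson_closed_forms(rng):
    x = rng.normal(size=20)
    assert pearson(x, x).value == pytest.approx(1.0)
    assert pearson(x, -x).value == pytest.approx(-1.0)
    res = pearson([1, 2, 3, 4], [2, 1, 4, 3])
    assert res.value == pytest.approx(0.6)
    assert res.df == (2,)
    with pytest.raises(DegenerateInputError):
        pearson([1, 1, 1], [1, 2, 3])
    with pytest.raises(InvalidParameterError):
        pearson([1, 2], [3, 4])


def test_pearson_matches_sum_formula(rng):
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    sx, sy = x - x.mean(), y - y.mean()
    r_manual = (sx * sy).sum() / np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
    assert pearson(x, y).value == pytest.approx(r_manual, abs=1e-12)


def test_allometric_slope_closed_forms(rng):
    total = rng.uniform(0.4, 0.7, size=40)
    iso = allometric_slope(total, 0.25 * total)
    assert iso.value == pytest.approx(1.0, abs=1e-9)
    assert iso.extra["isometric"]
    quad = allometric_slope(total, total ** 2)
    assert quad.value == pytest.approx(2.0, abs=1e-9)
    assert not quad.extra["isometric"]
    with pytest.raises(InvalidParameterError):
        allometric_slope([1.0, -1.0, 2.0], [1.0, 1.0, 1.0])


def test_allometric_ci_covers_isometry():
    """Isometric lognormal draws: the CI contains slope 1 in >= 90% of seeds."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        total = np.exp(rng.normal(0, 0.2, size=500))
        part = 0.3 * total * np.exp(rng.normal(0, 0.05, size=500))
        res = allometric_slope(total, part)
        hits += res.extra["isometric"]
    assert hits >= 18


# colony effects -------------------------------------------------------------


def test_colony_df_matches_honeybee_design():
    """110 specimens in 9 hives across 2 populations: F(8, 101)."""
    p = PhantomParams(seed=1)
    cohort = sample_cohort(p, 110, HONEYBEE_HIVE_PLAN, HONEYBEE_POPULATIONS)
    res = colony_effect_test(cohort_to_table(cohort), "total_mm3")
    assert res.df == (8, 101)
    assert res.n == 110
    assert 0 <= res.p_value <= 1


def test_colony_single_population_is_anova():
    p = PhantomParams(seed=2)
    cohort = sample_cohort(p, 40, {"H1": 20, "H2": 20})
    res = colony_effect_test(cohort_to_table(cohort), "total_mm3")
    assert res.df == (1, 38)
    assert "ANOVA" in res.grouping


def test_colony_requires_two_hives():
    p = PhantomParams(seed=2)
    cohort = sample_cohort(p, 10, {"H1": 10})
    with pytest.raises(ConfigError):
        colony_effect_test(cohort_to_table(cohort), "total_mm3")


def test_colony_null_and_alternative_behaviour():
    """No hive effect: F near 1 on average; huge offsets: p < 0.001."""
    fs = []
    for seed in range(8):
        p = PhantomParams(seed=seed, hive_cv=0.0)
        cohort = sample_cohort(p, 60, {"H1": 20, "H2": 20, "H3": 20})
        fs.append(colony_effect_test(cohort_to_table(cohort), "total_mm3").value)
    assert 0.3 < np.mean(fs) < 2.0
    p = PhantomParams(seed=3, hive_cv=0.5)
    cohort = sample_cohort(p, 60, {"H1": 20, "H2": 20, "H3": 20})
    res = colony_effect_test(cohort_to_table(cohort), "total_mm3")
    assert res.p_value < 0.001


# lateralization -------------------------------------------------------------


def _table(left, right):
    return pd.DataFrame({
        "OL_left_mm3": left,
        "OL_right_mm3": right,
    })


def test_lateralization_ties_give_null():
    t = _table([1.0] * 5, [1.0] * 5)
    res = lateralization_test(t, "OL")
    assert res.value == 0.0 and res.p_value == 1.0
    assert res.extra["pct_smaller_left"] == 0.0
    assert res.extra["n_ties"] == 5


def test_lateralization_systematic_deficit():
    right = np.linspace(0.9, 1.1, 12)
    res = lateralization_test(_table(0.95 * right, right), "OL")
    assert res.p_value < 1e-6
    assert res.extra["pct_smaller_left"] == 100.0


def test_lateralization_needs_three_pairs():
    with pytest.raises(InvalidParameterError):
        lateralization_test(_table([1.0, 1.1], [1.0, 1.2]), "OL")


def test_lateralization_excludes_merged_rows():
    t = pd.DataFrame({
        "MB_left_mm3": [1.0, np.nan, 1.2, 0.9, np.nan],
        "MB_right_mm3": [1.1, 2.0, 1.1, 1.0, 2.1],
    })
    res = lateralization_test(t, "MB")
    assert res.n == 3
    assert "2 non-separable" in res.grouping


# asymmetry quadrants --------------------------------------------------------


def test_quadrants_all_ties():
    t = pd.DataFrame({
        "AL_left_mm3": [1.0, 1.0], "AL_right_mm3": [1.0, 1.0],
        "OL_left_mm3": [2.0, 2.0], "OL_right_mm3": [2.0, 2.0],
    })
    q = asymmetry_quadrants(t)
    assert q["n_classified"] == 0 and q["n_ties_excluded"] == 2


def test_quadrants_uniform_right_dominance():
    t = pd.DataFrame({
        "AL_left_mm3": [1.0, 0.9], "AL_right_mm3": [1.1, 1.0],
        "OL_left_mm3": [2.0, 1.9], "OL_right_mm3": [2.2, 2.0],
    })
    q = asymmetry_quadrants(t)
    assert q["larger_right_AL_larger_right_OL"] == 100.0


def test_quadrants_converge_to_quarter_each(rng):
    n = 4000
    da = rng.choice([-0.1, 0.1], size=n)
    db = rng.choice([-0.1, 0.1], size=n)
    t = pd.DataFrame({
        "AL_left_mm3": 1.0 - da / 2, "AL_right_mm3": 1.0 + da / 2,
        "OL_left_mm3": 2.0 - db / 2, "OL_right_mm3": 2.0 + db / 2,
    })
    q = asymmetry_quadrants(t)
    values = [v for k, v in q.items() if k.startswith(("larger", "smaller"))]
    assert sum(values) == pytest.approx(100.0)
    for v in values:
        assert abs(v - 25.0) < 3.0


# operating characteristics --------------------------------------------------


def test_type_one_error_near_alpha():
    p = PhantomParams(seed=0)    # no lateral deficit
    oc = simulate_operating_characteristics(p, 77, 200, seed=42)
    assert 0.02 <= oc["lateralization_rejection_rate"] <= 0.08


def test_power_at_bumblebee_effect_size():
    p = PhantomParams.bumblebee(
        lateral_delta={"ME": 0.05, "LO": 0.05}, lateral_noise_cv=0.03, seed=0
    )
    oc = simulate_operating_characteristics(p, 77, 100, seed=7)
    assert oc["lateralization_rejection_rate"] >= 0.90


def test_oc_rejects_bad_config():
    p = PhantomParams(seed=0)
    with pytest.raises(ConfigError):
        simulate_operating_characteristics(p, 10, 1, seed=0)
    with pytest.raises(ConfigError):
        simulate_operating_characteristics(p, 10, 100, alpha=1.5, seed=0)
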