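"""Morphometric statistics on per-specimen volume tables.

Implements the analyses run on bee-brain cohort tables: percent volume
variation, Pearson correlations, log–log allometric slopes (isometry =
slope 1), colony-effect F-tests from linear mixed models (hive as fixed
categorical effect, population as random intercept), paired left/right
t-tests for lateralization, asymmetry-quadrant classification across two
neuropil pairs, and Monte-Carlo operating characteristics of those tests
against the synthetic cohort generator.

F-test degrees of freedom follow the between/within (containment)
convention: for n specimens in k hives the hive term has (k - 1, n - k)
degrees of freedom — the honey-bee design (110 specimens, 9 hives in two
populations) gives (8, 101).  With a single population the model reduces to
one-way ANOVA with identical degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ConfigError, DegenerateInputError, InvalidParameterError, logger


@dataclass
class StatResult:
    name: str
    value: float
    df: tuple | None
    p_value: float
    n: int
    grouping: str = ""
    extra: dict | None = None


def _frame(t) -> pd.DataFrame:
    return t.frame if hasattr(t, "frame") else t


# simple descriptive / correlation statistics --------------------------------


def percent_variation(values) -> float:
    """(Max - Min) x 100 / Max of a set of volumes."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise InvalidParameterError("need at least 2 values")
    if v.max() <= 0:
        raise InvalidParameterError("maximum must be positive")
    return float((v.max() - v.min()) * 100.0 / v.max())


def pearson(x, y) -> StatResult:
    """Product-moment correlation with two-sided p from the t distribution
    with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InvalidParameterError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector in correlation")
    r, p = sps.pearsonr(x, y)
    return StatResult("pearson_r", float(r), (x.size - 2,), float(p), int(x.size))


def allometric_slope(total, part, conf: float = 0.95) -> StatResult:
    """Least-squares slope of log(part) on log(total) with confidence
    interval; the relation is isometric when the CI contains 1."""
    total = np.asarray(total, dtype=float)
    part = np.asarray(part, dtype=float)
    keep = ~(np.isnan(total) | np.isnan(part))
    total, part = total[keep], part[keep]
    if np.any(total <= 0) or np.any(part <= 0):
        raise InvalidParameterError("volumes must be positive for log-log fit")
    if total.size < 3:
        raise InvalidParameterError("need at least 3 observations")
    res = sps.linregress(np.log(total), np.log(part))
    n = total.size
    tcrit = sps.t.ppf(0.5 + conf / 2.0, n - 2)
    lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    return StatResult(
        "allometric_slope", float(res.slope), (n - 2,), float(res.pvalue), n,
        extra={"ci": (float(lo), float(hi)),
               # epsilon absorbs the degenerate zero-residual (exact-fit) case
               "isometric": bool(lo - 1e-9 <= 1.0 <= hi + 1e-9),
               "intercept": float(res.intercept)},
    )


# colony effects -------------------------------------------------------------


def colony_effect_test(t, response: str) -> StatResult:
    """F-test of the hive effect on ``response``.

    With more than one population, a linear mixed model with hive as fixed
    categorical effect and population as random intercept is fitted and the
    hive term is Wald-tested; with a single population this reduces to
    one-way ANOVA.  Denominator degrees of freedom are n - k (containment).
    """
    df = _frame(t)
    for col in ("hive", "population", response):
        if col not in df.columns:
            raise InvalidParameterError(f"column {col!r} missing from table")
    data = df[["hive", "population", response]].dropna()
    hives = sorted(data["hive"].unique())
    k = len(hives)
    if k < 2:
        raise ConfigError("colony effect requires at least 2 hives")
    n = len(data)
    df1, df2 = k - 1, n - k
    n_pops = data["population"].nunique()

    y = data[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(n)] + [(data["hive"] == h).to_numpy(float) for h in hives[1:]]
    )
    if n_pops > 1:
        import statsmodels.formula.api as smf

        d = data.rename(columns={response: "_y"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = smf.mixedlm("_y ~ C(hive)", d, groups=d["population"]).fit(reml=True)
                names = [nm for nm in fit.fe_params.index if nm != "Intercept"]
                beta = fit.fe_params[names].to_numpy()
                cov = fit.cov_params().loc[names, names].to_numpy()
                fstat = float(beta @ np.linalg.solve(cov, beta)) / df1
            except Exception as exc:  # singular fits on degenerate designs
                logger.warning("mixed model failed (%s); falling back to ANOVA", exc)
                fstat = _anova_f(y, X, df1, df2)
        grouping = f"{k} hives, {n_pops} populations (random)"
    else:
        fstat = _anova_f(y, X, df1, df2)
        grouping = f"{k} hives, 1 population (one-way ANOVA)"
    p = float(sps.f.sf(fstat, df1, df2))
    return StatResult("hive_F", float(fstat), (df1, df2), p, n, grouping)


def _anova_f(y, X, df1, df2) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    tss0 = float(np.sum((y - y.mean()) ** 2))
    if rss <= 0:
        return np.inf
    return ((tss0 - rss) / df1) / (rss / df2)


# lateralization -------------------------------------------------------------


def lateralization_test(t, neuropil: str) -> StatResult:
    """Paired two-sided t-test of left vs right volumes of a paired neuropil,
    plus the percentage of specimens with a strictly smaller left side.

    Rows with missing left/right values (e.g. midline-merged MB) are
    excluded; their count is reported.
    """
    df = _frame(t)
    lcol, rcol = f"{neuropil}_left_mm3", f"{neuropil}_right_mm3"
    for col in (lcol, rcol):
        if col not in df.columns:
            raise InvalidParameterError(f"column {col!r} missing from table")
    sub = df[[lcol, rcol]].dropna()
    n_excluded = len(df) - len(sub)
    left = sub[lcol].to_numpy(dtype=float)
    right = sub[rcol].to_numpy(dtype=float)
    n = left.size
    if n < 3:
        raise InvalidParameterError(f"fewer than 3 usable left/right pairs ({n})")
    if np.allclose(left, right):
        tstat, p = 0.0, 1.0
    else:
        tstat, p = sps.ttest_rel(left, right)
    smaller_left = int((left < right).sum())
    ties = int((left == right).sum())
    return StatResult(
        f"paired_t_{neuropil}", float(tstat), (n - 1,), float(p), n,
        grouping=f"{n_excluded} non-separable rows excluded",
        extra={
            "pct_smaller_left": smaller_left / n * 100.0,
            "n_ties": ties,
            "mean_diff_mm3": float((left - right).mean()),
        },
    )


def asymmetry_quadrants(t, pair_a: str = "AL", pair_b: str = "OL") -> dict:
    """Classify specimens by the signs of right-minus-left for two pairs.

    Categories (strict inequalities): larger right in both; larger right A,
    smaller right B; smaller right A, larger right B; smaller right in both.
    Rows with a tie in either pair are excluded and counted.
    """
    df = _frame(t)
    cols = [f"{pair_a}_left_mm3", f"{pair_a}_right_mm3",
            f"{pair_b}_left_mm3", f"{pair_b}_right_mm3"]
    for col in cols:
        if col not in df.columns:
            raise InvalidParameterError(f"column {col!r} missing from table")
    sub = df[cols].dropna()
    da = sub[cols[1]].to_numpy(float) - sub[cols[0]].to_numpy(float)  # right - left
    db = sub[cols[3]].to_numpy(float) - sub[cols[2]].to_numpy(float)
    keep = (da != 0) & (db != 0)
    n_ties = int((~keep).sum())
    da, db = da[keep], db[keep]
    n = int(keep.sum())
    if n == 0:
        logger.warning("asymmetry_quadrants: all specimens tied; nothing classified")
    def pct(mask):
        return float(mask.sum()) / n * 100.0 if n else float("nan")
    return {
        f"larger_right_{pair_a}_larger_right_{pair_b}": pct((da > 0) & (db > 0)),
        f"larger_right_{pair_a}_smaller_right_{pair_b}": pct((da > 0) & (db < 0)),
        f"smaller_right_{pair_a}_larger_right_{pair_b}": pct((da < 0) & (db > 0)),
        f"smaller_right_{pair_a}_smaller_right_{pair_b}": pct((da < 0) & (db < 0)),
        "n_classified": n,
        "n_ties_excluded": n_ties,
    }


# operating characteristics --------------------------------------------------


def simulate_operating_characteristics(
    params,
    n_specimens: int,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
    hive_plan: dict[str, int] | None = None,
    populations: dict[str, str] | None = None,
    neuropil: str = "OL",
    include_colony_test: bool = False,
    colony_response: str = "total_mm3",
) -> dict:
    """Monte-Carlo rejection rates of the cohort tests under the generator.

    Draws ``n_reps`` cohorts (volumes only, no rendering), runs the
    lateralization test on ``neuropil`` (and optionally the colony-effect
    test), and returns rejection frequencies with binomial standard errors.
    """
    from dataclasses import replace as dc_replace

    from .phantom import cohort_to_table, sample_cohort

    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    if n_reps < 50:
        raise ConfigError("n_reps must be >= 50 for stable rates")
    hive_plan = hive_plan or {"H1": n_specimens}
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rej_lat = 0
    rej_col = 0
    for i in range(n_reps):
        p_i = dc_replace(params, seed=int(seeds[i]))
        cohort = sample_cohort(p_i, n_specimens, hive_plan, populations)
        table = cohort_to_table(cohort)
        res = lateralization_test(table, neuropil)
        rej_lat += res.p_value < alpha
        if include_colony_test:
            resc = colony_effect_test(table, colony_response)
            rej_col += resc.p_value < alpha
    out = {
        "n_reps": n_reps,
        "alpha": alpha,
        "lateralization_rejection_rate": rej_lat / n_reps,
        "lateralization_se": float(
            np.sqrt(max(rej_lat / n_reps * (1 - rej_lat / n_reps), 1e-12) / n_reps)
        ),
    }
    if include_colony_test:
        out["colony_rejection_rate"] = rej_col / n_reps
        out["colony_se"] = float(
            np.sqrt(max(rej_col / n_reps * (1 - rej_col / n_reps), 1e-12) / n_reps)
        )
    return out
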