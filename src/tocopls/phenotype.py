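"""Phenotype processing and descriptive/dispersion statistics.

Replicate adipose-tissue alpha-tocopherol concentrations (nmol/g protein)
are measured per participant on a meal x time grid (three test meals,
fasting and 8 h post-meal; 2-6 replicates present). Because neither meal
nor sampling time shifts the concentration, the replicates are treated as
technical replicates: each participant's set is screened with a single-pass
two-tailed Grubbs test and then averaged into one phenotype value.

The module also implements the cohort-level statistics used around that
aggregation: paired t contrasts of the meal/time design, percent
coefficient of variation, Forkman's F-type test for equality of CVs (based
on McKay's approximation), Fisher-z confidence intervals for Pearson
correlations, and the CI-based covariate screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TestResult

__all__ = [
    "grubbs_critical",
    "grubbs_test",
    "aggregate_replicates",
    "cohort_phenotype",
    "paired_meal_tests",
    "percent_cv",
    "cv_from_summary",
    "forkman_cv_test",
    "pearson_ci",
    "pearson_ci_from_r",
    "covariate_screen",
]

MEALS = ("control", "alpha_toc", "tomato")
TIMES = ("fasting", "8h")


# ---------------------------------------------------------------------------
# Grubbs outlier screening and replicate aggregation
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 df.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[int | None, TestResult]:
    """Single-pass two-sided Grubbs test for one outlier.

    Returns the index of the flagged observation (or ``None``) plus the test
    result. G = max|x_i - mean| / sd; the approximate p-value inverts the
    critical-value identity (capped at 1). Constant data never flag
    (``"zero_variance"``).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return None, TestResult(0.0, 1.0, df=n - 2, method="grubbs",
                                flags=("zero_variance",))
    deviations = np.abs(x - mean)
    idx = int(np.argmax(deviations))
    g = float(deviations[idx] / sd)
    # invert G = ((n-1)/sqrt(n)) sqrt(t^2/(n-2+t^2)) for the equivalent t
    u = g * g * n / (n - 1) ** 2
    if u >= 1.0:
        p = 0.0
    else:
        t_equiv = math.sqrt(u * (n - 2) / (1 - u))
        p = min(1.0, 2 * n * stats.t.sf(t_equiv, n - 2))
    outlier = idx if g > grubbs_critical(n, alpha) else None
    return outlier, TestResult(g, p, df=n - 2, method="grubbs")


@dataclass(frozen=True)
class AggregateResult:
    mean: float
    n_used: int
    outlier_index: int | None = None
    flags: tuple[str, ...] = ()


def aggregate_replicates(
    values: np.ndarray, alpha: float = 0.05
) -> AggregateResult:
    """Grubbs-screen a replicate set (at most one removal) and average it.

    Sets with fewer than 3 values skip the outlier screen; fewer than 2
    surviving values is flagged ``"low_confidence"`` but still averaged.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no replicate values")
    outlier = None
    if x.size >= 3:
        outlier, _ = grubbs_test(x, alpha)
        if outlier is not None:
            x = np.delete(x, outlier)
    flags = ("low_confidence",) if x.size < 2 else ()
    return AggregateResult(float(x.mean()), int(x.size), outlier, flags)


def cohort_phenotype(
    measurements: pd.DataFrame, grubbs_alpha: float = 0.05
) -> pd.DataFrame:
    """Aggregate a long replicate table into one phenotype row per participant.

    ``measurements`` columns: participant_id, meal, time, adipose_atoc.
    Returns a DataFrame indexed by participant_id with columns
    ``atoc`` (replicate mean after Grubbs screening), ``n_replicates`` and
    ``outlier_removed``.
    """
    required = {"participant_id", "adipose_atoc"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements table needs columns {sorted(required)}")
    rows = []
    for pid, group in measurements.groupby("participant_id", sort=False):
        agg = aggregate_replicates(group["adipose_atoc"].to_numpy(), grubbs_alpha)
        rows.append(
            {
                "participant_id": pid,
                "atoc": agg.mean,
                "n_replicates": agg.n_used,
                "outlier_removed": agg.outlier_index is not None,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


# ---------------------------------------------------------------------------
# Meal / time design checks
# ---------------------------------------------------------------------------

def _paired_t(x: np.ndarray, y: np.ndarray, label: str) -> TestResult:
    diff = x - y
    n = diff.size
    if n < 3:
        raise ValueError("paired t-test needs >= 3 complete pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() == 0:
            return TestResult(0.0, 1.0, df=n - 1, method=label, flags=("degenerate",))
        return TestResult(math.inf, 0.0, df=n - 1, method=label, flags=("degenerate",))
    t = diff.mean() / (sd / math.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return TestResult(float(t), p, df=n - 1, method=label)


def paired_meal_tests(measurements: pd.DataFrame) -> dict[str, TestResult]:
    """Two-sided paired t-tests over the meal x time replicate design.

    One contrast per meal (fasting vs 8 h) and one per meal pair at each
    time point, each computed on participants with both members present.
    """
    table = measurements.pivot_table(
        index="participant_id", columns=["meal", "time"], values="adipose_atoc",
        aggfunc="mean",
    )
    results: dict[str, TestResult] = {}
    for meal in MEALS:
        if (meal, TIMES[0]) in table.columns and (meal, TIMES[1]) in table.columns:
            pair = table[[(meal, TIMES[0]), (meal, TIMES[1])]].dropna()
            if len(pair) >= 3:
                label = f"{meal}:fasting_vs_8h"
                results[label] = _paired_t(
                    pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy(), label
                )
    for time in TIMES:
        for i, meal_a in enumerate(MEALS):
            for meal_b in MEALS[i + 1:]:
                cols = [(meal_a, time), (meal_b, time)]
                if all(c in table.columns for c in cols):
                    pair = table[cols].dropna()
                    if len(pair) >= 3:
                        label = f"{meal_a}_vs_{meal_b}:{time}"
                        results[label] = _paired_t(
                            pair.iloc[:, 0].to_numpy(),
                            pair.iloc[:, 1].to_numpy(),
                            label,
                        )
    return results


# ---------------------------------------------------------------------------
# Dispersion statistics
# ---------------------------------------------------------------------------

def percent_cv(values: np.ndarray) -> float:
    """Percent coefficient of variation, 100 * sample SD / mean (mean > 0)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs n >= 2")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / mean)


def cv_from_summary(mean: float, sd: float) -> float:
    """Percent CV recomputed from a printed mean/SD summary pair."""
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * sd / mean


def forkman_cv_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Forkman's test of equality of two coefficients of variation.

    With sample CVs c1, c2 from independent samples of sizes n1, n2, the
    statistic F = [c1^2 / (1 + c1^2 (n1-1)/n1)] / [c2^2 / (1 + c2^2 (n2-1)/n2)]
    is referred to F(n1-1, n2-1); the p-value is two-sided. Based on
    McKay's chi-square approximation, accurate for CVs below about 0.7.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 3 or n2 < 3:
        raise ValueError("Forkman test needs n >= 3 in both samples")
    if x.mean() <= 0 or y.mean() <= 0:
        raise ValueError("Forkman test needs positive sample means")
    c1 = x.std(ddof=1) / x.mean()
    c2 = y.std(ddof=1) / y.mean()
    if c2 == 0 and c1 == 0:
        return TestResult(1.0, 1.0, df=(n1 - 1, n2 - 1), method="forkman",
                          flags=("degenerate",))
    if c2 == 0 or c1 == 0:
        return TestResult(math.inf, 0.0, df=(n1 - 1, n2 - 1), method="forkman",
                          flags=("degenerate",))
    num = c1**2 / (1 + c1**2 * (n1 - 1) / n1)
    den = c2**2 / (1 + c2**2 * (n2 - 1) / n2)
    f = float(num / den)
    p = float(2 * min(stats.f.sf(f, n1 - 1, n2 - 1), stats.f.cdf(f, n1 - 1, n2 - 1)))
    return TestResult(f, min(p, 1.0), df=(n1 - 1, n2 - 1), method="forkman")


# ---------------------------------------------------------------------------
# Correlations and covariate screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PearsonCI:
    r: float
    lower: float
    upper: float
    n: int
    test: TestResult


def pearson_ci_from_r(r: float, n: int, level: float = 0.95) -> PearsonCI:
    """Fisher-z confidence interval and t-test p-value from (r, n) alone."""
    if n < 4:
        raise ValueError("Fisher-z interval needs n >= 4")
    if abs(r) >= 1.0:
        sign = math.copysign(1.0, r)
        return PearsonCI(
            float(r), sign, sign, n,
            TestResult(math.inf, 0.0, df=n - 2, method="pearson_t",
                       flags=("degenerate",)),
        )
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / math.sqrt(n - 3)
    lower, upper = math.tanh(z - half), math.tanh(z + half)
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return PearsonCI(float(r), lower, upper, n,
                     TestResult(float(t), p, df=n - 2, method="pearson_t"))


def pearson_ci(x: np.ndarray, y: np.ndarray, level: float = 0.95) -> PearsonCI:
    """Pearson r with Fisher-z CI, on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 4:
        raise ValueError("Pearson CI needs n >= 4 complete pairs")
    r = float(np.corrcoef(x, y)[0, 1])
    if 1.0 - abs(r) < 1e-12:
        r = math.copysign(1.0, r)
    return pearson_ci_from_r(r, x.size, level)


def covariate_screen(
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    level: float = 0.95,
) -> tuple[list[str], pd.DataFrame]:
    """Keep covariates whose Pearson-r confidence interval excludes zero.

    Returns the kept covariate names (column order preserved) and a detail
    table with r, CI bounds and p per candidate.
    """
    common = phenotype.index.intersection(covariates.index)
    y = phenotype.loc[common].to_numpy()
    kept: list[str] = []
    rows = []
    for name in covariates.columns:
        ci = pearson_ci(covariates.loc[common, name].to_numpy(), y, level)
        selected = ci.lower > 0 or ci.upper < 0
        if selected:
            kept.append(name)
        rows.append(
            {"covariate": name, "r": ci.r, "lower": ci.lower, "upper": ci.upper,
             "p": ci.test.p, "kept": selected}
        )
    return kept, pd.DataFrame(rows).set_index("covariate")
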