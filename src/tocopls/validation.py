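"""Robustness battery for a fitted PLS model.

Four checks, all driven by the same seeded venetian-blind fold machinery
as the engine's Q2:

* **CV-ANOVA** — F = [(SS_y - PRESS)/A] / [PRESS/(n - A - 1)] referred to
  F(A, n - A - 1). The degrees of freedom are a transparent ANOVA
  decomposition (explained-by-predictive-components vs cross-validated
  residual); commercial implementations do not publish their exact df
  convention.
* **Permutation validation** — the response is shuffled ``n_perm`` times,
  the model refitted (fixed variable set, re-chosen component count) and
  (|corr with original y|, R2, Q2) recorded; straight lines of R2 and Q2
  against |corr| (anchored by the unpermuted model at |corr| = 1) are
  fitted, and their intercepts reported. Pass criteria follow standard
  chemometrics guidance: Q2-intercept < 0.05 and R2-intercept < 0.4.
* **Leave-k-out** — Q2 recomputed with folds of size k for each requested k.
* **Coefficient stability** — the model refitted on each fold complement;
  per-variable spread, delete-group jackknife interval and sign-consistency
  fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TestResult
from .pls import (
    autoscale,
    fold_assignments,
    press_from_folds,
    pls_fit,
    select_components,
    unstandardized_coefficients,
)

__all__ = [
    "cv_anova",
    "permutation_validation",
    "leave_k_out",
    "coefficient_stability",
    "PermutationReport",
    "ValidationReport",
]


def cv_anova(X, y, A: int, folds: int = 7, seed: int = 0) -> TestResult:
    """Cross-validation ANOVA significance test of a PLS model.

    PRESS comes from the same fold scheme (and seed) as the engine's Q2, so
    the two reports agree bit-for-bit on that quantity. F <= 0 (PRESS at
    least SS_y, i.e. no predictive ability) reports p = 1.
    """
    Xs, ys, _ = autoscale(X, y)
    n = len(ys)
    if n - A - 1 < 1:
        raise ValueError("CV-ANOVA needs n - A - 1 >= 1")
    assign = fold_assignments(n, min(folds, n), seed)
    press = press_from_folds(Xs, ys, A, assign)
    ss_y = float(ys @ ys)
    f = ((ss_y - press) / A) / (press / (n - A - 1))
    if f <= 0:
        return TestResult(float(f), 1.0, df=(A, n - A - 1), method="cv_anova",
                          flags=("no_predictive_ability",))
    p = float(stats.f.sf(f, A, n - A - 1))
    return TestResult(float(f), p, df=(A, n - A - 1), method="cv_anova")


@dataclass
class PermutationReport:
    records: pd.DataFrame           # columns: corr, r2, q2 (one row per permutation)
    real_r2: float
    real_q2: float
    r2_intercept: float
    q2_intercept: float
    passed: bool
    n_perm: int


def permutation_validation(X, y, A: int | None = None, n_perm: int = 100,
                           seed: int = 0, folds: int = 7) -> PermutationReport:
    """Y-scrambling validation of a PLS model with a fixed variable set."""
    if n_perm < 20:
        warnings.warn("fewer than 20 permutations: intercepts will be unstable",
                      stacklevel=2)
    y = np.asarray(y, dtype=float).ravel()
    real = pls_fit(X, y, A=A, folds=folds, seed=seed)
    real_q2 = float(real.q2_cum[real.A - 1])
    rng = np.random.default_rng(seed)
    rows = []
    y_sd = y.std()
    for _ in range(n_perm):
        yp = rng.permutation(y)
        corr = abs(float(np.corrcoef(y, yp)[0, 1])) if y_sd > 0 else 1.0
        m = pls_fit(X, yp, A=None, folds=folds, seed=seed)
        rows.append((corr, m.r2, float(m.q2_cum[m.A - 1])))
    records = pd.DataFrame(rows, columns=["corr", "r2", "q2"])
    # anchor the regression lines with the unpermuted model at |corr| = 1
    xs = np.append(records["corr"].to_numpy(), 1.0)
    r2_line = np.polyfit(xs, np.append(records["r2"].to_numpy(), real.r2), 1)
    q2_line = np.polyfit(xs, np.append(records["q2"].to_numpy(), real_q2), 1)
    r2_int, q2_int = float(r2_line[1]), float(q2_line[1])
    return PermutationReport(
        records, real.r2, real_q2, r2_int, q2_int,
        passed=bool(q2_int < 0.05 and r2_int < 0.4), n_perm=n_perm,
    )


def leave_k_out(X, y, A: int, ks=(1, 3, 7), seed: int = 0) -> pd.DataFrame:
    """Q2 under leave-k-out cross-validation for each k (seeded partitions)."""
    Xs, ys, _ = autoscale(X, y)
    n = len(ys)
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        if not 1 <= k < n:
            raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")
        order = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        assign[order] = np.arange(n) // k
        press = press_from_folds(Xs, ys, A, assign)
        ss_y = float(ys @ ys)
        rows.append({"k": k, "q2": 1.0 - press / ss_y})
    out = pd.DataFrame(rows)
    out.attrs["max_drop"] = float(out["q2"].max() - out["q2"].min())
    return out


def coefficient_stability(X, y, A: int, folds: int = 7, seed: int = 0) -> pd.DataFrame:
    """Refit on each fold complement; summarise per-variable coefficient spread.

    Returns a table indexed by variable with the full-data unstandardized
    coefficient, the across-fold mean and SD, a delete-group jackknife
    interval and the fraction of refits agreeing in sign with the full fit.
    """
    full = pls_fit(X, y, A=A, folds=folds, seed=seed)
    b_full, _ = unstandardized_coefficients(full)
    n = full.n
    assign = fold_assignments(n, min(folds, n), seed)
    X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y_arr = np.asarray(y, dtype=float).ravel()
    coefs = []
    for f in np.unique(assign):
        train = assign != f
        m = pls_fit(pd.DataFrame(X_arr[train], columns=full.columns),
                    y_arr[train], A=A, folds=min(folds, int(train.sum())), seed=seed)
        b, _ = unstandardized_coefficients(m)
        coefs.append(b)
    B = np.vstack(coefs)             # folds x variables
    m_folds = B.shape[0]
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1) if m_folds > 1 else np.zeros_like(mean)
    jack_se = np.sqrt((m_folds - 1) / m_folds * ((B - mean) ** 2).sum(axis=0))
    t_crit = stats.t.ppf(0.975, max(m_folds - 1, 1))
    sign_full = np.sign(b_full)
    sign_consistency = (np.sign(B) == sign_full).mean(axis=0)
    return pd.DataFrame(
        {
            "full_coef": b_full,
            "mean_coef": mean,
            "sd_coef": sd,
            "jack_lower": mean - t_crit * jack_se,
            "jack_upper": mean + t_crit * jack_se,
            "sign_consistency": sign_consistency,
        },
        index=list(full.columns),
    )


@dataclass
class ValidationReport:
    """Bundle of the four robustness checks for one final model."""

    cv_anova: TestResult
    permutation: PermutationReport
    leave_k_out: pd.DataFrame
    stability: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "cv_anova": {
                "F": self.cv_anova.statistic,
                "df": list(self.cv_anova.df) if self.cv_anova.df else None,
                "p": self.cv_anova.p,
            },
            "permutation": {
                "n_perm": self.permutation.n_perm,
                "real_r2": self.permutation.real_r2,
                "real_q2": self.permutation.real_q2,
                "r2_intercept": self.permutation.r2_intercept,
                "q2_intercept": self.permutation.q2_intercept,
                "passed": self.permutation.passed,
            },
            "leave_k_out": self.leave_k_out.to_dict(orient="records"),
            "stability": self.stability.reset_index(names="variable").to_dict(
                orient="records"
            ),
        }
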