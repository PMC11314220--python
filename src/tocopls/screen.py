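"""Per-SNP association screening under additive and dominant codings.

Every QC-passed SNP is tested twice against the aggregated phenotype: once
with the minor-allele count as regressor (additive) and once with a
carrier indicator (dominant: dosages 1 and 2 collapse to 1). A SNP enters
a test only if every genotype class of that coding holds at least
``min_obs`` observations (default 5). The test is simple least squares
with a Wald statistic B/SE referred to Student's t on n-2 df; SNPs with
p < alpha are retained as candidate predictors for the multivariate step.

A SNP significant under both codings contributes two candidates only when
the coded regressors differ as vectors (i.e. dosage-2 carriers exist);
identical codings keep the additive entry alone, so candidates are never
double counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CODING_ADDITIVE, CODING_DOMINANT, CODINGS, GenotypeMatrix

__all__ = [
    "AssociationResult",
    "encode",
    "group_count_filter",
    "ols_assoc",
    "screen_all",
    "design_matrix",
    "variable_name",
]


@dataclass(frozen=True)
class AssociationResult:
    """Univariate association of one (SNP, coding) pair with the phenotype."""

    snp_id: str
    coding: str
    beta: float          # phenotype units per allele copy / per carrier
    se: float
    p: float
    group_counts: tuple[int, ...]
    n: int
    flags: tuple[str, ...] = ()


def encode(dosages: np.ndarray, model: str) -> np.ndarray:
    """Code dosages for a genetic model; missing (NaN) propagates.

    additive: identity; dominant: 0 -> 0, {1, 2} -> 1.
    """
    d = np.asarray(dosages, dtype=float)
    if model == CODING_ADDITIVE:
        return d.copy()
    if model == CODING_DOMINANT:
        out = d.copy()
        out[out == 2] = 1.0
        return out
    raise ValueError(f"unknown coding model {model!r}; expected one of {CODINGS}")


def group_count_filter(dosages: np.ndarray, model: str, min_obs: int = 5) -> bool:
    """True iff every genotype class of the coding has >= ``min_obs`` calls.

    Additive requires all three dosage classes (0/1/2); dominant requires
    both collapsed classes (non-carrier / carrier).
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    n0 = int(np.count_nonzero(d == 0))
    n1 = int(np.count_nonzero(d == 1))
    n2 = int(np.count_nonzero(d == 2))
    if model == CODING_ADDITIVE:
        return min(n0, n1, n2) >= min_obs
    if model == CODING_DOMINANT:
        return min(n0, n1 + n2) >= min_obs
    raise ValueError(f"unknown coding model {model!r}")


def ols_assoc(y: np.ndarray, g: np.ndarray, snp_id: str = "",
              coding: str = CODING_ADDITIVE) -> AssociationResult:
    """Simple least squares y = b0 + B g with a Wald t-test on B.

    Missing values are dropped pairwise; the Wald statistic B/SE is
    referred to t on n-2 df (the conservative small-sample reading of the
    asymptotic test at n = 42).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    mask = ~(np.isnan(y) | np.isnan(g))
    y, g = y[mask], g[mask]
    n = y.size
    if n < 3:
        raise ValueError("association test needs >= 3 complete pairs")
    sxx = float(((g - g.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("constant regressor")
    beta = float(((g - g.mean()) * (y - y.mean())).sum() / sxx)
    b0 = y.mean() - beta * g.mean()
    resid = y - b0 - beta * g
    sigma2 = float(resid @ resid) / (n - 2)
    se = math.sqrt(sigma2 / sxx)
    if se == 0:
        t, p = math.inf, 0.0
        flags = ("perfect_fit",)
    else:
        t = beta / se
        p = float(2 * stats.t.sf(abs(t), n - 2))
        flags = ()
    counts = (
        int(np.count_nonzero(g == 0)),
        int(np.count_nonzero(g == 1)),
        int(np.count_nonzero(g == 2)),
    )
    return AssociationResult(snp_id, coding, beta, se, p, counts, n, flags)


def screen_all(
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    alpha: float = 0.05,
    min_obs: int = 5,
) -> tuple[list[AssociationResult], list[AssociationResult]]:
    """Test every SNP under both codings; retain results with p < alpha.

    ``y`` is the aggregated phenotype, aligned on participant id when given
    as a Series. Returns (all tested results, retained candidates); the
    retained list is ranked by ascending p within coding model (additive
    block first) and de-duplicated so identical additive/dominant codings
    keep only the additive entry.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(g.participant_ids).to_numpy()
    else:
        y = np.asarray(y, dtype=float)
        if y.size != g.n_participants:
            raise ValueError("phenotype length does not match participants")

    tested: list[AssociationResult] = []
    for snp in g.snp_ids:
        dosage = g.column(snp)
        for coding in CODINGS:
            if not group_count_filter(dosage, coding, min_obs):
                continue
            regressor = encode(dosage, coding)
            tested.append(ols_assoc(y, regressor, snp_id=snp, coding=coding))

    significant = [r for r in tested if r.p < alpha]
    # identical additive/dominant codings (no dosage-2 class analysed):
    # keep only the additive entry for that SNP
    drop: set[tuple[str, str]] = set()
    by_snp: dict[str, list[AssociationResult]] = {}
    for r in significant:
        by_snp.setdefault(r.snp_id, []).append(r)
    for snp, results in by_snp.items():
        if len(results) == 2:
            add = next(r for r in results if r.coding == CODING_ADDITIVE)
            if add.group_counts[2] == 0:
                drop.add((snp, CODING_DOMINANT))
    retained = [r for r in significant if (r.snp_id, r.coding) not in drop]
    retained.sort(key=lambda r: (CODINGS.index(r.coding), r.p))
    return tested, retained


def variable_name(snp_id: str, coding: str) -> str:
    return f"{snp_id}|{coding[:3]}"


def design_matrix(
    g: GenotypeMatrix,
    retained: list[AssociationResult],
    covariates: pd.DataFrame | None = None,
    kept_covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple]]:
    """Assemble the multivariate design from retained candidates.

    One column per retained (SNP, coding) pair — encoded dosages with
    missing values mean-imputed after QC — plus one column per kept
    covariate. Returns the design and a variable map
    ``name -> ("snp", snp_id, coding) | ("covariate", name)``.
    """
    columns: dict[str, np.ndarray] = {}
    var_map: dict[str, tuple] = {}
    for r in retained:
        coded = encode(g.column(r.snp_id), r.coding)
        if np.isnan(coded).any():
            coded = np.where(np.isnan(coded), np.nanmean(coded), coded)
        name = variable_name(r.snp_id, r.coding)
        columns[name] = coded
        var_map[name] = ("snp", r.snp_id, r.coding)
    X = pd.DataFrame(columns, index=g.participant_ids)
    if covariates is not None and kept_covariates:
        cov = covariates.reindex(g.participant_ids)
        for name in kept_covariates:
            X[name] = cov[name].to_numpy()
            var_map[name] = ("covariate", name)
    return X, var_map
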