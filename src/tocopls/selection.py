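"""VIP-threshold sweep and final model selection.

Starting from the full model (all screened SNP candidates plus kept
covariates), models are refitted at increasing VIP thresholds: at each
threshold only the variables whose VIP in the *current* model reaches the
threshold survive, the model is refitted (component count re-chosen by
cross-validation) and VIPs are recomputed before the next threshold
(dynamic re-ranking; a static mode filtering on the full model's VIPs is
available). Retained sets are therefore nested as thresholds increase.

Among the sweep entries with a significant CV-ANOVA p-value, the entry
maximizing the adjusted R2 wins (ties break toward fewer variables).
Finally, selected SNPs in mutual LD (squared dosage correlation above the
threshold) are pruned to the highest-VIP member per group and the model is
refitted on the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, TestResult
from .pls import PLSModel, adjusted_r2, pls_fit
from .qc import dosage_r2
from .validation import cv_anova

__all__ = [
    "SweepEntry",
    "SelectionTrace",
    "FinalModel",
    "default_vip_grid",
    "vip_sweep",
    "select_model",
    "ld_dedup_selected",
]


def default_vip_grid() -> np.ndarray:
    """Default threshold grid: 0.8 to 1.5 in steps of 0.05."""
    return np.round(np.arange(0.80, 1.5001, 0.05), 10)


@dataclass
class SweepEntry:
    """One VIP-threshold entry of the sweep."""

    threshold: float
    variables: tuple[str, ...]
    A: int
    r2: float
    adj_r2: float | None            # None when n - k - 1 < 1
    q2: float
    cv_anova_p: float
    vips: dict[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.variables)


@dataclass
class SelectionTrace:
    entries: list[SweepEntry] = field(default_factory=list)
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [e.threshold for e in self.entries],
                "k": [e.k for e in self.entries],
                "A": [e.A for e in self.entries],
                "r2": [e.r2 for e in self.entries],
                "adj_r2": [e.adj_r2 for e in self.entries],
                "q2": [e.q2 for e in self.entries],
                "cv_anova_p": [e.cv_anova_p for e in self.entries],
                "variables": [";".join(e.variables) for e in self.entries],
            }
        )


def _entry_for(X: pd.DataFrame, y, model: PLSModel, threshold: float,
               folds: int, seed: int) -> SweepEntry:
    n = model.n
    k = model.k
    adj = adjusted_r2(model.r2, n, k) if n - k - 1 >= 1 else None
    q2 = float(model.q2_cum[model.A - 1])
    p = cv_anova(X, y, model.A, folds=folds, seed=seed).p
    return SweepEntry(
        threshold, tuple(model.columns), model.A, model.r2, adj, q2, p,
        vips=dict(zip(model.columns, model.vips)),
    )


def vip_sweep(X: pd.DataFrame, y, thresholds=None, folds: int = 7,
              seed: int = 0, dynamic: bool = True) -> SelectionTrace:
    """Fit the threshold ladder of VIP-filtered PLS models.

    ``dynamic=True`` re-ranks VIPs after every refit; ``dynamic=False``
    filters every threshold against the full model's VIPs. Thresholds that
    eliminate all variables produce an empty entry and do not advance the
    filter state.
    """
    if thresholds is None:
        thresholds = default_vip_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")

    y = np.asarray(y, dtype=float).ravel()
    trace = SelectionTrace(n=len(y))

    model = pls_fit(X, y, folds=folds, seed=seed)
    current_cols = list(model.columns)
    current_vips = dict(zip(model.columns, model.vips))
    current_entry: SweepEntry | None = None

    for thr in thresholds:
        keep = [c for c in current_cols if current_vips[c] >= thr]
        if not keep:
            trace.entries.append(
                SweepEntry(float(thr), (), 0, float("nan"), None, float("nan"), 1.0)
            )
            continue
        if keep != current_cols or current_entry is None:
            model = pls_fit(X[keep], y, folds=folds, seed=seed)
            entry = _entry_for(X[keep], y, model, float(thr), folds, seed)
        else:
            entry = SweepEntry(
                float(thr), current_entry.variables, current_entry.A,
                current_entry.r2, current_entry.adj_r2, current_entry.q2,
                current_entry.cv_anova_p, dict(current_entry.vips),
            )
        trace.entries.append(entry)
        current_entry = entry
        current_cols = list(entry.variables)
        if dynamic:
            current_vips = dict(entry.vips)
    return trace


def select_model(trace: SelectionTrace, alpha: float = 0.05) -> SweepEntry | None:
    """Best sweep entry: significant CV-ANOVA, maximal adjusted R2, fewest k.

    Returns ``None`` (the explicit no-model outcome) when no entry is
    significant.
    """
    candidates = [
        e for e in trace.entries
        if e.k > 0 and e.adj_r2 is not None and e.cv_anova_p < alpha
    ]
    if not candidates:
        return None
    best = candidates[0]
    for e in candidates[1:]:
        if e.adj_r2 > best.adj_r2 or (e.adj_r2 == best.adj_r2 and e.k < best.k):
            best = e
    return best


@dataclass
class FinalModel:
    """Selected model after post-selection LD pruning and refit."""

    variables: tuple[str, ...]
    dropped_ld: tuple[str, ...]
    model: PLSModel
    r2: float
    adj_r2: float | None
    q2: float
    cv_anova: TestResult

    @property
    def k(self) -> int:
        return len(self.variables)


def ld_dedup_selected(
    entry: SweepEntry,
    X: pd.DataFrame,
    y,
    genotypes: GenotypeMatrix,
    var_map: dict[str, tuple] | None = None,
    r2_threshold: float = 0.80,
    folds: int = 7,
    seed: int = 0,
) -> FinalModel:
    """Prune selected SNPs in mutual LD, keep the highest VIP, refit.

    LD groups are connected components of pairwise squared dosage
    correlation above ``r2_threshold`` among the entry's SNP variables
    (covariates are never pruned); ties in VIP break by the entry's
    variable order. The refitted model re-verifies CV-ANOVA significance —
    a model losing significance after pruning is reported as such through
    the returned ``cv_anova``.
    """
    var_map = var_map or {}

    def snp_of(name: str) -> str | None:
        info = var_map.get(name)
        if info is not None:
            return info[1] if info[0] == "snp" else None
        head = name.split("|")[0]
        return head if head in genotypes.snp_ids else None

    names = list(entry.variables)
    snp_vars = [v for v in names if snp_of(v) is not None]
    idx = {v: i for i, v in enumerate(names)}

    parent = {v: v for v in snp_vars}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, a in enumerate(snp_vars):
        for b in snp_vars[i + 1:]:
            r2 = dosage_r2(genotypes.column(snp_of(a)), genotypes.column(snp_of(b)))
            if not np.isnan(r2) and r2 > r2_threshold:
                parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for v in snp_vars:
        groups.setdefault(find(v), []).append(v)

    dropped: list[str] = []
    for members in groups.values():
        if len(members) > 1:
            # max VIP; ties break toward the earliest entry-order variable
            best = max(members, key=lambda v: (entry.vips.get(v, 0.0), -idx[v]))
            dropped.extend(v for v in members if v != best)

    survivors = [v for v in names if v not in set(dropped)]
    model = pls_fit(X[survivors], y, folds=folds, seed=seed)
    n, k = model.n, model.k
    adj = adjusted_r2(model.r2, n, k) if n - k - 1 >= 1 else None
    anova = cv_anova(X[survivors], y, model.A, folds=folds, seed=seed)
    return FinalModel(
        tuple(survivors), tuple(dropped), model, model.r2, adj,
        float(model.q2_cum[model.A - 1]), anova,
    )
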