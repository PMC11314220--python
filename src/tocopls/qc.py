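"""Genotype quality control: the SNP filter cascade.

Order of stages (mirroring a standard candidate-gene workflow):

1. call-rate filter (SNPs genotyped in < 95% of participants are dropped),
2. Hardy-Weinberg equilibrium exclusion (Pearson chi-square, 1 df, p < 0.05),
3. greedy tag-SNP selection within gene groups at squared dosage
   correlation r2 > 0.80,
4. de-duplication of perfectly correlated SNP pairs (r2 = 1), one random
   (seeded) survivor per duplicate group.

LD is measured on the cohort's own dosages as the squared Pearson
correlation of minor-allele counts (the composite genotype correlation),
so the cascade is self-contained: no external reference panel is needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, QCReport, QCStage, TestResult

__all__ = [
    "call_rate_filter",
    "hwe_test",
    "hwe_filter",
    "dosage_r2",
    "tag_snp_selection",
    "dedup_perfect_pairs",
    "run_qc",
]


def call_rate_filter(
    g: GenotypeMatrix, min_rate: float = 0.95
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop SNPs whose fraction of non-missing calls is below ``min_rate``."""
    if g.n_participants == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    excluded = [s for s in g.snp_ids if g.call_rate(s) < min_rate]
    kept = [s for s in g.snp_ids if s not in set(excluded)]
    return g.subset(kept), excluded


def hwe_test(n0: int, n1: int, n2: int) -> TestResult:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (1 df).

    ``n0, n1, n2`` are the observed counts of the 0/1/2 minor-allele dosage
    classes. The allele frequency is estimated as p = (n1 + 2 n2) / 2n and
    expected counts are n(1-p)^2, 2np(1-p), np^2. No continuity correction.
    Monomorphic SNPs (p in {0, 1}) return a zero statistic flagged
    ``"monomorphic"`` rather than an error.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one observation")
    p_hat = (n1 + 2 * n2) / (2 * n)
    if p_hat in (0.0, 1.0):
        return TestResult(0.0, 1.0, df=1, method="hwe_chi2", flags=("monomorphic",))
    expected = np.array(
        [n * (1 - p_hat) ** 2, 2 * n * p_hat * (1 - p_hat), n * p_hat**2]
    )
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return TestResult(chi2, p_value, df=1, method="hwe_chi2")


def hwe_filter(
    g: GenotypeMatrix, alpha: float = 0.05
) -> tuple[GenotypeMatrix, list[str], dict[str, TestResult]]:
    """Exclude SNPs departing from HWE at level ``alpha``."""
    results: dict[str, TestResult] = {}
    excluded: list[str] = []
    for snp in g.snp_ids:
        result = hwe_test(*g.genotype_counts(snp))
        results[snp] = result
        if result.p < alpha:
            excluded.append(snp)
    kept = [s for s in g.snp_ids if s not in set(excluded)]
    return g.subset(kept), excluded, results


def dosage_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed on pairwise-complete observations; returns ``NaN`` when fewer
    than 3 complete pairs remain or either vector is constant (the
    "missing-LD" condition).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = ~(np.isnan(g1) | np.isnan(g2))
    x, y = g1[mask], g2[mask]
    if x.size < 3:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def _r2_matrix(g: GenotypeMatrix, snps: list[str]) -> np.ndarray:
    cols = [g.column(s) for s in snps]
    k = len(snps)
    out = np.full((k, k), np.nan)
    for i in range(k):
        out[i, i] = 1.0
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = dosage_r2(cols[i], cols[j])
    return out


def tag_snp_selection(
    g: GenotypeMatrix, r2_threshold: float = 0.80
) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy tag-SNP binning within gene groups.

    Within each gene group (from the annotation; SNPs without a gene label
    form one extra group), repeatedly pick the unassigned SNP linked
    (r2 > threshold) to the most other unassigned SNPs, make it the bin's
    tag and assign its linked SNPs to the bin (most-connected-first, the
    Carlson-style rule). Ties break by input order. Singletons tag
    themselves. Returns the tags (in input order) and the tag -> members
    mapping.
    """
    groups: dict[str, list[str]] = {}
    for snp in g.snp_ids:
        gene = g.gene_of(snp) or ""
        groups.setdefault(gene, []).append(snp)

    bins: dict[str, list[str]] = {}
    tags: set[str] = set()
    for members in groups.values():
        r2 = _r2_matrix(g, members)
        linked = np.nan_to_num(r2, nan=0.0) > r2_threshold
        np.fill_diagonal(linked, False)
        unassigned = list(range(len(members)))
        while unassigned:
            degree = [int(linked[i, unassigned].sum()) for i in unassigned]
            if max(degree) == 0:  # all remaining are singletons
                for j in unassigned:
                    tags.add(members[j])
                    bins[members[j]] = [members[j]]
                break
            best = unassigned[int(np.argmax(degree))]  # argmax -> first max: input order
            bin_members = [best] + [j for j in unassigned if linked[best, j] and j != best]
            tag = members[best]
            tags.add(tag)
            bins[tag] = [members[j] for j in bin_members]
            assigned = set(bin_members)
            unassigned = [j for j in unassigned if j not in assigned]
    ordered_tags = [s for s in g.snp_ids if s in tags]
    return ordered_tags, bins


def dedup_perfect_pairs(
    g: GenotypeMatrix, seed: int = 0, tol: float = 1e-12
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep one seeded-random survivor per group of perfectly correlated SNPs.

    Groups are connected components of the r2 = 1 relation across the whole
    matrix. The survivor is drawn with a seeded generator so reruns are
    reproducible.
    """
    snps = g.snp_ids
    k = len(snps)
    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    cols = [g.column(s) for s in snps]
    for i in range(k):
        for j in range(i + 1, k):
            r2 = dosage_r2(cols[i], cols[j])
            if not np.isnan(r2) and r2 >= 1.0 - tol:
                parent[find(i)] = find(j)

    components: dict[int, list[int]] = {}
    for i in range(k):
        components.setdefault(find(i), []).append(i)

    rng = np.random.default_rng(seed)
    excluded: list[str] = []
    for component in components.values():
        if len(component) > 1:
            survivor = component[rng.integers(len(component))]
            excluded.extend(snps[i] for i in component if i != survivor)
    kept = [s for s in snps if s not in set(excluded)]
    return g.subset(kept), excluded


def run_qc(
    g: GenotypeMatrix,
    *,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 0.05,
    ld_r2: float = 0.80,
    seed: int = 0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full filter cascade: call rate -> HWE -> tag selection -> perfect-pair dedup.

    Returns the surviving matrix (column order preserved) and a chained
    :class:`QCReport`. Idempotent: a second run on the output excludes
    nothing.
    """
    report = QCReport()

    g1, dropped = call_rate_filter(g, call_rate_min)
    report.stages.append(
        QCStage("call_rate", g.n_snps, {s: "call_rate" for s in dropped})
    )

    g2, dropped, _ = hwe_filter(g1, hwe_alpha)
    report.stages.append(QCStage("hwe", g1.n_snps, {s: "hwe" for s in dropped}))

    tags, _bins = tag_snp_selection(g2, ld_r2)
    dropped = [s for s in g2.snp_ids if s not in set(tags)]
    g3 = g2.subset(tags)
    report.stages.append(QCStage("ld_tag", g2.n_snps, {s: "ld_tag" for s in dropped}))

    g4, dropped = dedup_perfect_pairs(g3, seed=seed)
    report.stages.append(
        QCStage("perfect_dedup", g3.n_snps, {s: "perfect_duplicate" for s in dropped})
    )

    report.validate_chain()
    return g4, report
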