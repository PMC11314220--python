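"""Shared data containers used across pipeline stages.

The pipeline's central object is the :class:`GenotypeMatrix`: a participants
x SNPs grid of minor-allele dosages (0, 1, 2; ``NaN`` for missing calls)
carried as a :class:`pandas.DataFrame`, optionally paired with a per-SNP
annotation table (gene symbol, allele pair, allele frequency, gene region,
optional regulatory score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CODING_ADDITIVE = "additive"
CODING_DOMINANT = "dominant"
CODINGS = (CODING_ADDITIVE, CODING_DOMINANT)

#: Columns expected in a SNP annotation table (``reg_score`` is optional).
ANNOTATION_COLUMNS = ("snp_id", "gene", "alleles", "alt_freq", "region", "reg_score")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single statistical test.

    ``df`` is ``None`` for tests without a classical degrees-of-freedom
    parameter, a float for one-parameter reference distributions (t, chi2)
    and a pair for F-type tests. ``flags`` records degenerate conditions
    (e.g. ``"monomorphic"``, ``"zero_variance"``) instead of raising.
    """

    statistic: float
    p: float
    df: float | tuple[float, float] | None = None
    method: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isnan(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _check_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    annotation = annotation.copy()
    if annotation.index.name != "snp_id":
        if "snp_id" in annotation.columns:
            annotation = annotation.set_index("snp_id")
        else:
            annotation.index.name = "snp_id"
    if "alt_freq" in annotation.columns:
        freq = annotation["alt_freq"].dropna()
        if ((freq < 0) | (freq > 1)).any():
            raise ValueError("annotation alt_freq outside [0, 1]")
    if "reg_score" in annotation.columns:
        score = pd.to_numeric(annotation["reg_score"], errors="coerce").dropna()
        if ((score < 0) | (score > 1)).any():
            raise ValueError("annotation reg_score outside [0, 1]")
    return annotation


@dataclass
class GenotypeMatrix:
    """Participants x SNPs minor-allele dosage matrix with missingness.

    Parameters
    ----------
    dosage
        DataFrame indexed by participant id, one column per SNP; entries in
        {0, 1, 2} or ``NaN`` for missing genotype calls.
    annotation
        Optional per-SNP annotation, indexed by (or containing) ``snp_id``.
    """

    dosage: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        dosage = self.dosage.astype(float)
        if dosage.index.has_duplicates:
            raise ValueError("duplicate participant ids")
        if dosage.columns.has_duplicates:
            raise ValueError("duplicate SNP ids")
        values = dosage.to_numpy()
        bad = ~(np.isnan(values) | (values == 0) | (values == 1) | (values == 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage value {values[i, j]!r} for SNP {dosage.columns[j]!r} "
                "not in {0, 1, 2, NA}"
            )
        dosage.index.name = "participant_id"
        self.dosage = dosage
        if self.annotation is not None:
            self.annotation = _check_annotation(self.annotation)

    # -- basic introspection -------------------------------------------------
    @property
    def participant_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_participants(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP (``NaN`` = missing)."""
        return self.dosage[snp_id].to_numpy()

    def call_rate(self, snp_id: str) -> float:
        col = self.column(snp_id)
        return float(np.count_nonzero(~np.isnan(col))) / len(col)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """Counts of the 0/1/2 genotype classes on non-missing calls."""
        col = self.column(snp_id)
        return (
            int(np.count_nonzero(col == 0)),
            int(np.count_nonzero(col == 1)),
            int(np.count_nonzero(col == 2)),
        )

    def gene_of(self, snp_id: str) -> str | None:
        if self.annotation is None or "gene" not in self.annotation.columns:
            return None
        if snp_id in self.annotation.index:
            value = self.annotation.loc[snp_id, "gene"]
            return None if pd.isna(value) else str(value)
        return None

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset preserving this matrix's SNP order."""
        wanted = set(snp_ids)
        missing = wanted - set(self.dosage.columns)
        if missing:
            raise KeyError(f"unknown SNP ids: {sorted(missing)}")
        keep = [s for s in self.dosage.columns if s in wanted]
        annotation = None
        if self.annotation is not None:
            annotation = self.annotation.reindex(
                [s for s in keep if s in self.annotation.index]
            )
        return GenotypeMatrix(self.dosage[keep].copy(), annotation)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return self.dosage.equals(other.dosage)


@dataclass
class QCStage:
    """One stage of the SNP filter cascade."""

    name: str
    n_in: int
    excluded: dict[str, str] = field(default_factory=dict)  # snp_id -> reason

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_excluded


@dataclass
class QCReport:
    """Stage-by-stage audit of the SNP filter cascade.

    Invariants: ``n_out = n_in - n_excluded`` at every stage (by
    construction) and stages chain (each stage's output count equals the
    next stage's input count); :meth:`validate_chain` asserts the latter.
    """

    stages: list[QCStage] = field(default_factory=list)

    def validate_chain(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_out != nxt.n_in:
                raise ValueError(
                    f"QC stages do not chain: {prev.name} out={prev.n_out} "
                    f"but {nxt.name} in={nxt.n_in}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.name for s in self.stages],
                "n_in": [s.n_in for s in self.stages],
                "n_excluded": [s.n_excluded for s in self.stages],
                "n_out": [s.n_out for s in self.stages],
            }
        )

    def exclusions_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s.name, "snp_id": snp, "reason": reason}
            for s in self.stages
            for snp, reason in s.excluded.items()
        ]
        return pd.DataFrame(rows, columns=["stage", "snp_id", "reason"])
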