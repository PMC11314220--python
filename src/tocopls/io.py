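"""Readers, writers and pipeline configuration.

Interchange formats are plain text, bit-exact for fixtures: tab-delimited,
UTF-8, ``NA`` for missing, no quoting.

* dosage TSV — header ``participant_id`` then SNP ids; cells 0/1/2/NA.
* annotation TSV — snp_id, gene, alleles, alt_freq, region, reg_score.
* phenotype TSV — one row per (participant, meal, time) replicate with
  columns participant_id, meal, time, adipose_atoc.
* covariate TSV — keyed by participant_id, one column per covariate.
* PLINK text — .ped allele pairs plus .map SNP order; the minor allele is
  inferred from the sample allele frequencies (ties resolved alphabetically,
  first allele counted) and converted to dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ANNOTATION_COLUMNS, GenotypeMatrix

__all__ = [
    "PipelineConfig",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_covariates_tsv",
    "write_covariates_tsv",
    "read_plink_text",
    "read_genotypes",
]

_NA = "NA"


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the end-to-end pipeline."""

    call_rate_min: float = 0.95
    hwe_alpha: float = 0.05
    ld_r2: float = 0.80
    min_group: int = 5
    screen_alpha: float = 0.05
    ci_level: float = 0.95
    vip_grid: tuple[float, float, float] = (0.80, 1.50, 0.05)
    cv_folds: int = 7
    n_perm: int = 100
    grubbs_alpha: float = 0.05
    leave_k_out_ks: tuple[int, ...] = (1, 3, 7)
    seed: int = 0

    def validate(self) -> None:
        for name in ("call_rate_min", "hwe_alpha", "ld_r2", "screen_alpha",
                     "ci_level", "grubbs_alpha"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name}={value} outside (0, 1]")
        start, stop, step = self.vip_grid
        if step <= 0 or stop < start:
            raise ValueError("empty VIP grid")
        if self.cv_folds < 2 or self.min_group < 1 or self.n_perm < 1:
            raise ValueError("invalid count parameter")

    def vip_thresholds(self) -> np.ndarray:
        start, stop, step = self.vip_grid
        return np.round(np.arange(start, stop + step / 2, step), 10)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["vip_grid"] = ":".join(str(v) for v in self.vip_grid)
        data["leave_k_out_ks"] = list(self.leave_k_out_ks)
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if isinstance(data.get("vip_grid"), str):
            data["vip_grid"] = tuple(float(v) for v in data["vip_grid"].split(":"))
        if "leave_k_out_ks" in data:
            data["leave_k_out_ks"] = tuple(int(k) for k in data["leave_k_out_ks"])
        config = cls(**data)
        config.validate()
        return config


# ---------------------------------------------------------------------------
# Dosage matrices
# ---------------------------------------------------------------------------

def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    frame = g.dosage.copy()
    out = frame.map(lambda v: _NA if pd.isna(v) else str(int(v)))
    out.index.name = "participant_id"
    out.to_csv(path, sep="\t")


def read_dosage_tsv(path: str | Path,
                    annotation: pd.DataFrame | None = None) -> GenotypeMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.columns[0] != "participant_id":
        raise ValueError(f"{path.name}: first column must be 'participant_id'")
    frame = frame.set_index("participant_id")
    values = np.full(frame.shape, np.nan)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame[col]):
            if cell == _NA or pd.isna(cell):
                continue
            if cell not in ("0", "1", "2"):
                raise ValueError(
                    f"{path.name}: line {i + 2}: cell {cell!r} for SNP {col!r} "
                    "not in {0, 1, 2, NA}"
                )
            values[i, j] = float(cell)
    dosage = pd.DataFrame(values, index=frame.index, columns=frame.columns)
    return GenotypeMatrix(dosage, annotation)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.reset_index() if annotation.index.name == "snp_id" else annotation
    out.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[_NA])
    missing = {"snp_id", "gene"} - set(frame.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns {sorted(missing)}")
    for col in ANNOTATION_COLUMNS:
        if col not in frame.columns and col != "snp_id":
            frame[col] = np.nan
    return frame.set_index("snp_id")


# ---------------------------------------------------------------------------
# Phenotypes and covariates
# ---------------------------------------------------------------------------

def write_phenotype_tsv(measurements: pd.DataFrame, path: str | Path) -> None:
    cols = ["participant_id", "meal", "time", "adipose_atoc"]
    measurements[cols].to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[_NA])
    required = {"participant_id", "meal", "time", "adipose_atoc"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns {sorted(missing)}")
    return frame


def write_covariates_tsv(covariates: pd.DataFrame, path: str | Path) -> None:
    out = covariates.copy()
    out.index.name = "participant_id"
    out.to_csv(path, sep="\t", na_rep=_NA)


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[_NA])
    if "participant_id" not in frame.columns:
        raise ValueError("covariate file lacks a participant_id column")
    return frame.set_index("participant_id")


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path,
                    annotation: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Convert .ped/.map allele pairs into a minor-allele dosage matrix."""
    map_path, ped_path = Path(map_path), Path(ped_path)
    snps: list[str] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{map_path.name}: line {lineno}: expected 4 columns")
        snps.append(parts[1])

    participants: list[str] = []
    pairs: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * len(snps):
            raise ValueError(
                f"{ped_path.name}: line {lineno}: expected {6 + 2 * len(snps)} "
                f"fields for {len(snps)} mapped SNPs, found {len(parts)}"
            )
        participants.append(parts[1])
        pairs.append(list(zip(parts[6::2], parts[7::2])))

    values = np.full((len(participants), len(snps)), np.nan)
    for j, snp in enumerate(snps):
        counts: dict[str, int] = {}
        for row in pairs:
            for allele in row[j]:
                if allele != "0":
                    counts[allele] = counts.get(allele, 0) + 1
        if not counts:
            continue
        if len(counts) > 2:
            raise ValueError(f"{ped_path.name}: SNP {snp!r} has >2 alleles")
        # minor allele by frequency; ties resolved alphabetically
        minor = min(counts, key=lambda a: (counts[a], a))
        for i, row in enumerate(pairs):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            values[i, j] = float((a1 == minor) + (a2 == minor))
    dosage = pd.DataFrame(values, index=participants, columns=snps)
    return GenotypeMatrix(dosage, annotation)


def read_genotypes(path: str | Path, fmt: str = "dosage-tsv",
                   annotation: pd.DataFrame | None = None,
                   map_path: str | Path | None = None) -> GenotypeMatrix:
    """Dispatch on format: ``dosage-tsv`` or ``plink-text`` (.ped + .map)."""
    if fmt == "dosage-tsv":
        return read_dosage_tsv(path, annotation)
    if fmt == "plink-text":
        if map_path is None:
            map_path = Path(path).with_suffix(".map")
        return read_plink_text(path, map_path, annotation)
    raise ValueError(f"unknown genotype format {fmt!r}")
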