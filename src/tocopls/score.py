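"""Genetic score for adipose-tissue alpha-tocopherol concentration.

The score is an affine predictor: intercept plus one term per SNP,

    concentration = b0 + sum_i r_i * c_i

where c_i is the minor-allele count for additively coded SNPs and a
carrier indicator (dosage 2 counts as 1) for dominantly coded ones. The
published 10-SNP model (intercept 35.7 nmol/g protein) ships as a packaged
fixture, loadable with :func:`published_score_model`, so the exact published
score is runnable out of the box.

Missing genotypes make the score fail loudly by default (a clinical-style
predictor should not silently impute); an explicit mean-dosage fallback
can be enabled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CODINGS, GenotypeMatrix
from .pls import PLSModel, unstandardized_coefficients

__all__ = [
    "ScoreEntry",
    "GeneticScoreModel",
    "score",
    "score_from_fit",
    "published_score_model",
]


@dataclass(frozen=True)
class ScoreEntry:
    snp_id: str
    coding: str                  # "additive" or "dominant"
    coefficient: float           # concentration units per allele / per carrier
    gene: str = ""
    vip: float | None = None

    def __post_init__(self) -> None:
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")


@dataclass(frozen=True)
class GeneticScoreModel:
    intercept: float
    entries: tuple[ScoreEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.snp_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate SNP ids in score model")

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    # -- serialization (exact round trip) -----------------------------------
    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "entries": [
                {
                    "snp_id": e.snp_id,
                    "gene": e.gene,
                    "coding": e.coding,
                    "coefficient": e.coefficient,
                    "vip": e.vip,
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneticScoreModel":
        return cls(
            float(data["intercept"]),
            tuple(
                ScoreEntry(
                    str(e["snp_id"]),
                    str(e["coding"]),
                    float(e["coefficient"]),
                    gene=str(e.get("gene", "")),
                    vip=None if e.get("vip") is None else float(e["vip"]),
                )
                for e in data["entries"]
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GeneticScoreModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _code(dosage: float, coding: str) -> float:
    if coding == "dominant" and dosage == 2:
        return 1.0
    return float(dosage)


def score(
    genotypes: GenotypeMatrix | pd.DataFrame | pd.Series | Mapping[str, float],
    model: GeneticScoreModel,
    mean_impute: bool = False,
):
    """Apply a genetic score to one genotype row or a whole cohort.

    For a single row (Series/mapping) returns a float; for a matrix returns
    a Series indexed by participant. Missing genotypes raise an error
    listing the SNPs, unless ``mean_impute=True``, in which case the
    cohort's mean dosage for that SNP fills in (single rows cannot be
    mean-imputed).
    """
    if isinstance(genotypes, GenotypeMatrix):
        genotypes = genotypes.dosage
    if isinstance(genotypes, (pd.Series, Mapping)):
        row = dict(genotypes)
        missing = [e.snp_id for e in model.entries
                   if e.snp_id not in row or pd.isna(row[e.snp_id])]
        if missing:
            raise ValueError(f"missing genotypes for score SNPs: {missing}")
        return model.intercept + sum(
            e.coefficient * _code(row[e.snp_id], e.coding) for e in model.entries
        )

    frame: pd.DataFrame = genotypes
    absent = [e.snp_id for e in model.entries if e.snp_id not in frame.columns]
    if absent:
        raise ValueError(f"missing genotypes for score SNPs: {absent}")
    total = pd.Series(model.intercept, index=frame.index, dtype=float)
    for e in model.entries:
        col = frame[e.snp_id].astype(float)
        if e.coding == "dominant":
            col = col.where(col != 2, 1.0)
        if col.isna().any():
            if not mean_impute:
                bad = list(frame.index[col.isna()])
                raise ValueError(
                    f"missing genotype at {e.snp_id} for participants {bad}; "
                    "enable mean_impute to fall back to the cohort mean dosage"
                )
            col = col.fillna(col.mean())
        total += e.coefficient * col
    return total


def score_from_fit(
    model: PLSModel, var_map: Mapping[str, tuple]
) -> tuple[GeneticScoreModel, dict[str, float]]:
    """Export a fitted PLS model as a genetic score.

    ``var_map`` maps design-matrix column names to
    ``("snp", snp_id, coding)`` or ``("covariate", name)``. Non-SNP
    variables are returned separately (second element) and excluded from
    the genetic score, which is then restricted to the genetic part.
    Scoring the export reproduces the model's predictions exactly on
    complete genotype data when no covariates are present.
    """
    b, intercept = unstandardized_coefficients(model)
    entries = []
    covariate_part: dict[str, float] = {}
    for name, coef in zip(model.columns, b):
        info = var_map.get(name)
        if info is None or info[0] != "snp":
            covariate_part[name] = float(coef)
            continue
        _, snp_id, coding = info
        vip_value = None
        if model.vips.size:
            vip_value = float(model.vips[list(model.columns).index(name)])
        entries.append(
            ScoreEntry(snp_id, coding, float(coef), vip=vip_value)
        )
    return GeneticScoreModel(float(intercept), tuple(entries)), covariate_part


def published_score_model() -> GeneticScoreModel:
    """The packaged published 10-SNP score (intercept 35.7 nmol/g protein)."""
    text = (
        resources.files("tocopls").joinpath("data/published_score.json").read_text()
    )
    return GeneticScoreModel.from_dict(json.loads(text))
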