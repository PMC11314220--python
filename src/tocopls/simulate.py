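"""Synthetic cohort generator emulating the study's data structure.

The generator produces cohorts with the statistical structure the analysis
assumes, so every downstream stage is testable without any real data:

* genotypes drawn in Hardy-Weinberg equilibrium at specified counted-allele
  frequencies, with optional LD between SNP pairs emulated by allele
  copying with calibrated flip probabilities (the target squared dosage
  correlation is hit exactly in expectation and the partner's marginal
  frequency is preserved);
* a linear genetic architecture: latent concentration = intercept + sum of
  per-SNP effects (additive: per minor-allele copy; dominant: per carrier)
  plus Normal residual noise between participants;
* 2-6 technical replicates per participant laid out on the meal x time
  grid, with Normal within-participant noise;
* covariates (age, BMI, blood lipids, fasting plasma alpha-tocopherol)
  drawn jointly with the latent phenotype through a Gaussian construction
  so their Pearson correlations approach configurable targets.

The default study configuration (:func:`study_config`) reproduces the
published cohort's shape: 42 participants, the 77-SNP screened panel at
its printed allele frequencies, the published 10-SNP effect sizes with
intercept 35.7 nmol/g protein, and residual noise solved analytically so
the between-participant CV of the concentration is about 61%.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import CODING_ADDITIVE, CODING_DOMINANT, CODINGS, GenotypeMatrix
from .phenotype import MEALS, TIMES

__all__ = [
    "SNPSpec",
    "EffectSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "published_screen_table",
    "panel_from_published_screen",
    "published_effects",
    "expected_phenotype_moments",
    "residual_sd_for_cv",
    "study_config",
    "null_config",
]

#: Fasting covariate means and SDs for a healthy-adult-male cohort
#: (means and SEM-derived SDs from the study's baseline table, SEM * sqrt(42);
#: the HDL-C SEM prints as 0.0 so a plausible 0.08 g/L SD is assumed).
COVARIATE_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (31.3, 12.31),                 # years
    "bmi": (23.0, 1.94),                  # kg/m2
    "total_cholesterol": (1.6, 0.65),     # g/L
    "ldl_c": (1.0, 0.65),                 # g/L
    "hdl_c": (0.5, 0.08),                 # g/L
    "triglycerides": (0.8, 0.65),         # g/L
    "plasma_atoc": (25.5, 5.83),          # umol/L
}

DEFAULT_COVARIATE_TARGETS: dict[str, float] = {
    "total_cholesterol": 0.36,
    "plasma_atoc": 0.24,
}


@dataclass(frozen=True)
class SNPSpec:
    """One SNP of the simulated panel.

    ``freq`` is the frequency of the counted (alternate) allele; dosages
    are drawn as Binomial(2, freq), i.e. Hardy-Weinberg proportions
    ((1-p)^2, 2p(1-p), p^2). ``ld_partner``/``ld_r2`` make this SNP an LD
    copy of another panel SNP at the target squared dosage correlation.
    """

    snp_id: str
    freq: float
    gene: str = ""
    ld_partner: str | None = None
    ld_r2: float | None = None


@dataclass(frozen=True)
class EffectSpec:
    snp_id: str
    coding: str
    beta: float                    # phenotype units per allele copy / carrier


@dataclass
class SimulationConfig:
    panel: tuple[SNPSpec, ...]
    effects: tuple[EffectSpec, ...] = ()
    n_participants: int = 42
    intercept: float = 35.7        # nmol/g protein
    residual_sd: float = 0.0       # between-participant noise
    technical_sd: float = 0.0      # within-participant replicate noise
    n_replicates: int = 6
    vary_replicates: bool = False  # draw counts uniformly from {2..6}
    covariate_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_TARGETS)
    )
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        ids = [s.snp_id for s in self.panel]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate SNP ids in panel")
        known = set(ids)
        for s in self.panel:
            if not 0.0 < s.freq < 1.0:
                raise ValueError(f"{s.snp_id}: frequency must be in (0, 1)")
            if s.ld_partner is not None:
                if s.ld_partner not in known:
                    raise ValueError(f"{s.snp_id}: LD partner {s.ld_partner!r} "
                                     "not in panel")
                if s.ld_r2 is None or not 0.0 <= s.ld_r2 <= 1.0:
                    raise ValueError(f"{s.snp_id}: LD target r2 must be in [0, 1]")
        for e in self.effects:
            if e.snp_id not in known:
                raise ValueError(f"effect refers to unknown SNP {e.snp_id!r}")
            if e.coding not in CODINGS:
                raise ValueError(f"unknown coding {e.coding!r}")
        if self.residual_sd < 0 or self.technical_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _flip_prob(p_source: float, p_partner: float, r_target: float) -> float:
    """Per-allele flip probability hitting the target allele correlation.

    The partner allele copies the source allele with probability 1 - f and
    is redrawn as Bernoulli(p_partner) with probability f. When the
    frequencies match, corr = 1 - f exactly; otherwise f solves the
    correlation equation numerically.
    """
    if r_target >= 1.0:
        return 0.0
    if r_target <= 0.0:
        return 1.0
    qs = 1 - p_source

    def corr(f: float) -> float:
        pb = (1 - f) * p_source + f * p_partner
        return (1 - f) * np.sqrt(p_source * qs / (pb * (1 - pb)))

    if abs(p_source - p_partner) < 1e-12:
        return 1.0 - r_target
    return float(optimize.brentq(lambda f: corr(f) - r_target, 0.0, 1.0))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a seeded HWE genotype matrix (with optional LD and missingness)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_participants
    spec_of = {s.snp_id: s for s in config.panel}

    alleles: dict[str, np.ndarray] = {}      # snp -> (n, 2) allele indicators

    def generate(snp_id: str, stack: tuple[str, ...] = ()) -> np.ndarray:
        if snp_id in alleles:
            return alleles[snp_id]
        if snp_id in stack:
            raise ValueError(f"circular LD dependency through {snp_id!r}")
        spec = spec_of[snp_id]
        if spec.ld_partner is None:
            a = (rng.random((n, 2)) < spec.freq).astype(float)
        else:
            source = generate(spec.ld_partner, stack + (snp_id,))
            f = _flip_prob(spec_of[spec.ld_partner].freq, spec.freq,
                           float(np.sqrt(spec.ld_r2)))
            redraw = rng.random((n, 2)) < f
            fresh = (rng.random((n, 2)) < spec.freq).astype(float)
            a = np.where(redraw, fresh, source)
        alleles[snp_id] = a
        return a

    dosage = {}
    for spec in config.panel:
        dosage[spec.snp_id] = generate(spec.snp_id).sum(axis=1)
    frame = pd.DataFrame(dosage, index=[f"P{i + 1:03d}" for i in range(n)])

    if config.missing_rate > 0:
        mask = rng.random(frame.shape) < config.missing_rate
        frame = frame.mask(mask)

    annotation = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in config.panel],
            "gene": [s.gene for s in config.panel],
            "alleles": "A>G",
            "alt_freq": [s.freq for s in config.panel],
            "region": "intron",
            "reg_score": np.nan,
        }
    ).set_index("snp_id")
    return GenotypeMatrix(frame, annotation)


# ---------------------------------------------------------------------------
# Phenotypes and covariates
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    measurements: pd.DataFrame      # participant_id, meal, time, adipose_atoc
    covariates: pd.DataFrame        # indexed by participant_id
    latent: pd.Series               # true between-participant concentration


def _encode_effect(dosage: np.ndarray, coding: str) -> np.ndarray:
    d = np.asarray(dosage, dtype=float)
    d = np.where(np.isnan(d), np.nanmean(d), d)   # impute mean if missing
    if coding == CODING_DOMINANT:
        d = np.where(d == 2, 1.0, d)
    return d


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> SimulatedCohort:
    """Generate replicate measurements and covariates for a genotype matrix."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    n = genotypes.n_participants

    latent = np.full(n, config.intercept, dtype=float)
    for effect in config.effects:
        if effect.snp_id not in genotypes.dosage.columns:
            raise ValueError(f"effect SNP {effect.snp_id!r} absent from matrix")
        latent += effect.beta * _encode_effect(
            genotypes.column(effect.snp_id), effect.coding
        )
    latent += rng.normal(0.0, config.residual_sd, size=n)

    # covariates: Gaussian construction on the standardized latent phenotype
    sd = latent.std(ddof=1)
    z_y = (latent - latent.mean()) / sd if sd > 0 else np.zeros(n)
    covariates = {}
    for name, (mean, scale) in COVARIATE_MOMENTS.items():
        r = float(config.covariate_targets.get(name, 0.0))
        z = r * z_y + np.sqrt(max(1 - r * r, 0.0)) * rng.normal(size=n)
        covariates[name] = mean + scale * z
    cov_frame = pd.DataFrame(covariates, index=genotypes.participant_ids)
    cov_frame.index.name = "participant_id"

    grid = [(m, t) for m in MEALS for t in TIMES]
    rows = []
    for i, pid in enumerate(genotypes.participant_ids):
        k = (int(rng.integers(2, 7)) if config.vary_replicates
             else min(config.n_replicates, len(grid)))
        cells = rng.choice(len(grid), size=k, replace=False) if k < len(grid) \
            else np.arange(len(grid))
        for c in sorted(cells):
            meal, time = grid[c]
            value = latent[i] + rng.normal(0.0, config.technical_sd)
            rows.append(
                {"participant_id": pid, "meal": meal, "time": time,
                 "adipose_atoc": max(value, 0.0)}   # concentrations are >= 0
            )
    measurements = pd.DataFrame(rows)
    return SimulatedCohort(
        measurements, cov_frame,
        pd.Series(latent, index=genotypes.participant_ids, name="latent"),
    )


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, SimulatedCohort]:
    """Genotypes plus phenotypes in one seeded call."""
    g = simulate_genotypes(config)
    return g, simulate_phenotypes(g, config)


# ---------------------------------------------------------------------------
# Published-table configurations
# ---------------------------------------------------------------------------

def published_screen_table() -> pd.DataFrame:
    """The 77-SNP univariate screen table packaged with the library."""
    text = resources.files("tocopls").joinpath("data/published_panel.tsv").read_text()
    return pd.read_csv(_io.StringIO(text), sep="\t")


def panel_from_published_screen(only_causal: bool = False) -> tuple[SNPSpec, ...]:
    """Build a simulation panel from the packaged 77-SNP table."""
    table = published_screen_table()
    causal = {e.snp_id for e in published_effects()}
    specs = []
    for _, row in table.iterrows():
        if only_causal and row["snp_id"] not in causal:
            continue
        specs.append(SNPSpec(row["snp_id"], float(row["alt_freq"]),
                             gene=str(row["gene"])))
    return tuple(specs)


def published_effects() -> tuple[EffectSpec, ...]:
    """The published 10-SNP architecture (coefficients in nmol/g protein)."""
    from .score import published_score_model

    model = published_score_model()
    return tuple(
        EffectSpec(e.snp_id, e.coding, e.coefficient) for e in model.entries
    )


def expected_phenotype_moments(config: SimulationConfig) -> tuple[float, float]:
    """Analytic mean and genetic SD of the latent phenotype (no LD assumed)."""
    freq = {s.snp_id: s.freq for s in config.panel}
    mean = config.intercept
    var = 0.0
    for e in config.effects:
        p = freq[e.snp_id]
        if e.coding == CODING_ADDITIVE:
            mu, v = 2 * p, 2 * p * (1 - p)
        else:
            carrier = 1 - (1 - p) ** 2
            mu, v = carrier, carrier * (1 - carrier)
        mean += e.beta * mu
        var += e.beta**2 * v
    return mean, float(np.sqrt(var))


def residual_sd_for_cv(config: SimulationConfig, target_cv: float) -> float:
    """Residual SD so the between-participant CV hits ``target_cv``.

    Solves (target_cv * mean)^2 = genetic variance + residual variance with
    the analytic moments; returns 0 when the genetic variance alone already
    exceeds the target.
    """
    mean, sd_g = expected_phenotype_moments(config)
    total_var = (target_cv * mean) ** 2
    return float(np.sqrt(max(total_var - sd_g**2, 0.0)))


def study_config(
    n_participants: int = 42,
    seed: int = 0,
    include_noise_snps: bool = True,
    target_cv: float = 0.61,
    technical_sd: float = 18.0,
    vary_replicates: bool = True,
    residual_sd: float | None = None,
    missing_rate: float = 0.0,
) -> SimulationConfig:
    """Default study-shaped cohort configuration.

    The panel is the published 77-SNP screen table (or only its 10 causal
    SNPs), effects are the published coefficients with intercept 35.7, and
    the residual SD defaults to the value solving for a 61%
    between-participant CV.
    """
    config = SimulationConfig(
        panel=panel_from_published_screen(only_causal=not include_noise_snps),
        effects=published_effects(),
        n_participants=n_participants,
        technical_sd=technical_sd,
        vary_replicates=vary_replicates,
        missing_rate=missing_rate,
        seed=seed,
    )
    config.residual_sd = (
        residual_sd if residual_sd is not None
        else residual_sd_for_cv(config, target_cv)
    )
    return config


def null_config(n_participants: int = 42, seed: int = 0,
                residual_sd: float = 21.8) -> SimulationConfig:
    """Cohort with no genetic effects (the screening null).

    The default residual SD (0.61 x the 35.7 intercept) keeps the
    between-participant CV in the study's regime.
    """
    config = study_config(n_participants=n_participants, seed=seed,
                          residual_sd=residual_sd, vary_replicates=False)
    return replace_effects(config, ())


def replace_effects(config: SimulationConfig,
                    effects: tuple[EffectSpec, ...]) -> SimulationConfig:
    new = replace(config)
    new.effects = effects
    return new
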