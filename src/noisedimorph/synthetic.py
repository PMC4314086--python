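"""Synthetic expression, trait, and dispersal data generators.

The generators produce inputs with the statistical structure the
downstream analyses assume, so the whole pipeline runs and is testable
without any external download:

* :func:`gen_expression` — a strain x sex x replicate expression matrix
  with per-transcript multiplicative replicate noise whose CV is
  inflated in males by a factor ``gamma`` (``gamma = 1``: no sexual
  dimorphism in expression noise).
* :func:`gen_traits` — grouped trait assays in the three replication
  designs used for startle response, starvation resistance and chill
  coma recovery.
* :func:`gen_dispersal` — species tables with a configurable
  probability that the heterogametic sex is the one dispersing most.
* :func:`load_dispersal_fixture` — the packaged 36-species dispersal
  table.

All randomness flows through an explicit integer seed; identical
configurations give bit-identical outputs. There is no global RNG state.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import (
    ExpressionDataset,
    HETEROGAMETIC_SEX,
    SEXES,
    annotate_dispersal,
    validate_trait_table,
)
from .exceptions import ConfigError, FixtureError

#: Strain layout mirroring a six-strain, two-genotype microarray design:
#: one reference strain, two strains sharing one genotype, three sharing another.
DEFAULT_GENOTYPE_MAP = {
    "REC": "REC",
    "INV1": "INV",
    "INV2": "INV",
    "SIM1": "SIM/REV",
    "REV1": "SIM/REV",
    "REV2": "SIM/REV",
}

TRAIT_DESIGNS = ("per_individual_by_day", "vial_means", "group_means")


@dataclass
class SimExprConfig:
    """Configuration for the expression-matrix simulator.

    Per transcript *g*, a positive mean abundance ``m_g`` is drawn
    log-normally and a baseline (female) coefficient of variation is
    drawn from a gamma distribution, optionally damped by a power-law
    mean–noise coupling ``cv ∝ m^(-mean_cv_coupling)``. Replicate
    values for sex *s* are ``m_g * (1 + eps)`` with
    ``eps ~ Normal(0, cv_{g,s}^2)`` redrawn while non-positive, and
    ``cv_{g,male} = noise_inflation_gamma * cv_{g,female}``.
    """

    n_transcripts: int = 16_637
    n_strains: int = 6
    genotype_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_MAP)
    )
    replicates_per_sex: int = 3
    mean_log_location: float = 3.0
    mean_log_scale: float = 1.0
    base_cv_shape: float = 4.0
    base_cv_scale: float = 0.05
    mean_cv_coupling: float = 0.5
    noise_inflation_gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1 or self.n_strains < 1:
            raise ConfigError("n_transcripts and n_strains must be positive")
        if self.replicates_per_sex < 2:
            raise ConfigError("replicates_per_sex must be >= 2 (CV needs >= 2 values)")
        if self.noise_inflation_gamma <= 0:
            raise ConfigError("noise_inflation_gamma must be > 0")
        if self.mean_log_scale <= 0 or self.base_cv_shape <= 0 or self.base_cv_scale <= 0:
            raise ConfigError("scale/shape parameters must be > 0")
        if len(self.genotype_map) < self.n_strains:
            raise ConfigError(
                f"genotype_map covers {len(self.genotype_map)} strains, "
                f"need {self.n_strains}"
            )

    @property
    def strains(self) -> list[str]:
        return list(self.genotype_map)[: self.n_strains]


@dataclass
class SimTraitConfig:
    """Configuration for the grouped trait-assay simulator.

    ``trait_design`` selects the replication structure:

    * ``per_individual_by_day`` — individuals of one strain and sex
      assayed together on a given day are the replicates (startle-like);
      ``groups_per_cell`` is the number of assay days.
    * ``vial_means`` — per-vial averages are the replicates
      (starvation-like).
    * ``group_means`` — per-group averages are the replicates
      (chill-coma-like).

    ``sex_cv_pair`` is the target replicate-level (CV_female, CV_male).
    """

    trait_design: str = "per_individual_by_day"
    n_strains: int = 200
    groups_per_cell: int = 2
    individuals_per_group: int = 10
    sex_cv_pair: tuple[float, float] = (0.2, 0.2)
    mean_log_location: float = 3.0
    mean_log_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_design not in TRAIT_DESIGNS:
            raise ConfigError(
                f"unknown trait_design {self.trait_design!r}; "
                f"expected one of {TRAIT_DESIGNS}"
            )
        if min(self.n_strains, self.groups_per_cell, self.individuals_per_group) < 1:
            raise ConfigError("all counts must be positive")
        if min(self.sex_cv_pair) <= 0:
            raise ConfigError("target CVs must be > 0")


@dataclass
class SimDispersalConfig:
    """Configuration for the species dispersal-table simulator."""

    n_species: int = 36
    p_het_biased: float = 0.5
    system_composition: dict[str, int] = field(
        default_factory=lambda: {"XY": 16, "XO": 3, "ZW": 15, "ZO": 2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_het_biased <= 1.0:
            raise ConfigError("p_het_biased must lie in [0, 1]")
        unknown = set(self.system_composition) - set(HETEROGAMETIC_SEX)
        if unknown:
            raise ConfigError(f"unknown chromosome systems: {sorted(unknown)}")
        if any(v < 0 for v in self.system_composition.values()):
            raise ConfigError("composition counts must be non-negative")
        total = sum(self.system_composition.values())
        if total != self.n_species:
            raise ConfigError(
                f"system_composition sums to {total}, expected n_species={self.n_species}"
            )


def _truncated_multiplicative_noise(
    rng: np.random.Generator, means: np.ndarray, cvs: np.ndarray, n_rep: int
) -> np.ndarray:
    """Draw ``means * (1 + eps)``, redrawing eps while any value is <= 0.

    ``means`` and ``cvs`` are per-transcript; returns shape
    ``(len(means), n_rep)``. Truncation keeps the expression matrix
    strictly positive; for realistic CVs (< 0.3) redraws are rare, so
    the realized CV stays close to the nominal one.
    """
    g = len(means)
    eps = rng.normal(0.0, 1.0, size=(g, n_rep)) * cvs[:, None]
    vals = means[:, None] * (1.0 + eps)
    bad = vals <= 0
    while bad.any():
        eps = rng.normal(0.0, 1.0, size=int(bad.sum())) * np.broadcast_to(
            cvs[:, None], vals.shape
        )[bad]
        vals[bad] = np.broadcast_to(means[:, None], vals.shape)[bad] * (1.0 + eps)
        bad = vals <= 0
    return vals


def gen_expression(config: SimExprConfig) -> ExpressionDataset:
    """Simulate a strain x sex x replicate expression matrix.

    Transcript means and female CVs are shared across strains; the
    replicate noise is independent per strain, sex and replicate, so
    every strain provides an exchangeable, same-law realization — the
    structure the paired-CV Monte Carlo test assumes under the null.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_transcripts
    means = rng.lognormal(config.mean_log_location, config.mean_log_scale, size=g)
    base_cv = rng.gamma(config.base_cv_shape, config.base_cv_scale, size=g)
    coupling = (means / np.median(means)) ** (-config.mean_cv_coupling)
    cv_f = base_cv * coupling
    cv_m = config.noise_inflation_gamma * cv_f

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for strain in config.strains:
        for sex, cvs in (("female", cv_f), ("male", cv_m)):
            block = _truncated_multiplicative_noise(
                rng, means, cvs, config.replicates_per_sex
            )
            for r in range(config.replicates_per_sex):
                sid = f"{strain}_{sex}_r{r + 1}"
                columns[sid] = block[:, r]
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "strain": strain,
                        "genotype": config.genotype_map[strain],
                        "sex": sex,
                        "replicate": r + 1,
                    }
                )

    transcript_ids = [f"tr{i:05d}" for i in range(1, g + 1)]
    values = pd.DataFrame(columns, index=pd.Index(transcript_ids, name="transcript_id"))
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame(
        {"mean": means, "cv_female": cv_f, "cv_male": cv_m},
        index=values.index,
    )
    return ExpressionDataset(values=values, samples=samples, truth=truth)


def gen_traits(config: SimTraitConfig) -> pd.DataFrame:
    """Simulate a long-format trait table under one of the three designs.

    Each (strain, sex) cell gets a log-normal location; the target CV of
    ``sex_cv_pair`` is injected at the replicate level of the design —
    the individual level for ``per_individual_by_day``, the group level
    for the two group-averaged designs (where a small within-group
    residual CV of 0.05 is added on top).
    """
    rng = np.random.default_rng(config.seed)
    cv_by_sex = dict(zip(SEXES, config.sex_cv_pair))
    rows = []
    for s in range(1, config.n_strains + 1):
        strain = f"line{s:04d}"
        for sex in SEXES:
            mu = rng.lognormal(config.mean_log_location, config.mean_log_scale)
            cv = cv_by_sex[sex]
            for grp in range(1, config.groups_per_cell + 1):
                group = (
                    f"day{grp}"
                    if config.trait_design == "per_individual_by_day"
                    else f"g{grp}"
                )
                if config.trait_design == "per_individual_by_day":
                    # individuals are the replicates: full CV at individual level
                    vals = mu * _positive_factors(
                        rng, cv, config.individuals_per_group
                    )
                else:
                    # group means are the replicates: CV between groups,
                    # small residual noise within
                    group_mu = mu * _positive_factors(rng, cv, 1)[0]
                    vals = group_mu * _positive_factors(
                        rng, 0.05, config.individuals_per_group
                    )
                for i, v in enumerate(vals, start=1):
                    rows.append(
                        {
                            "strain": strain,
                            "sex": sex,
                            "group": group,
                            "individual": i,
                            "value": v,
                        }
                    )
    return validate_trait_table(pd.DataFrame(rows))


def _positive_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative factors 1 + Normal(0, cv^2), redrawn while <= 0."""
    f = 1.0 + rng.normal(0.0, cv, size=n)
    while (f <= 0).any():
        bad = f <= 0
        f[bad] = 1.0 + rng.normal(0.0, cv, size=int(bad.sum()))
    return f


def gen_dispersal(config: SimDispersalConfig) -> pd.DataFrame:
    """Simulate a species dispersal table.

    Each species receives a chromosome-system tag from the configured
    composition (in random order) and a dispersing-most sex equal to its
    heterogametic sex with probability ``p_het_biased``.
    """
    rng = np.random.default_rng(config.seed)
    tags = np.repeat(
        list(config.system_composition),
        list(config.system_composition.values()),
    )
    rng.shuffle(tags)
    het = np.array([HETEROGAMETIC_SEX[t] for t in tags])
    other = np.where(het == "male", "female", "male")
    biased = rng.random(config.n_species) < config.p_het_biased
    df = pd.DataFrame(
        {
            "species": [f"sp{i:04d}" for i in range(1, config.n_species + 1)],
            "taxon": "simulated",
            "chromosome_system": tags,
            "dispersing_sex": np.where(biased, het, other),
        }
    )
    return annotate_dispersal(df)


def load_dispersal_fixture() -> pd.DataFrame:
    """Load the packaged 36-species sex-biased dispersal table.

    The table is a synthetic reconstruction of a published 36-species
    comparative dataset (the original supplementary species list is not
    redistributed here): it reproduces the published composition — 11
    birds, 11 insects, 14 mammals; five species lacking W/Y chromosomes
    — and the published heterogamety-biased dispersal fractions overall
    and within the with-W/Y and without-W/Y subsets. Species names are
    plausible exemplars of each taxon and chromosome system.
    """
    ref = importlib.resources.files("noisedimorph").joinpath(
        "data/dispersal_36species_synthetic.tsv"
    )
    try:
        with ref.open("r") as fh:
            df = pd.read_csv(fh, sep="\t")
    except (FileNotFoundError, OSError) as exc:
        raise FixtureError("packaged dispersal fixture is missing") from exc
    if df.shape[0] != 36 or df.isna().any().any():
        raise FixtureError("packaged dispersal fixture is corrupted")
    return annotate_dispersal(df)
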