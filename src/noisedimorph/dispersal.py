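"""Heterogamety-biased dispersal analysis.

For a comparative table of species with known chromosome systems and
sex-biased dispersal, the observed statistic is the fraction of species
whose heterogametic sex (XY/XO: male; ZW/ZO: female) is the one
dispersing most — overall and split by presence of sex-specific (W/Y)
chromosomes. The null permutes the chromosome-system tags across all
species while keeping each species' dispersing sex fixed; heterogamety
and W/Y presence are re-derived from the permuted tags, and subset
membership is re-formed from them as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import annotate_dispersal
from .exceptions import NoiseDimorphError

SUBSETS = ("all", "with_WY", "without_WY")
DEFAULT_N_SIM = 10_000


@dataclass
class DispersalTestResult:
    subset: str
    n: int
    observed_fraction: float
    p5: float
    p95: float
    p_upper: float
    p_lower: float
    simulated: np.ndarray = field(repr=False)
    n_sim: int = 0
    seed: int | None = None


def _subset_mask(df: pd.DataFrame, subset: str) -> np.ndarray:
    if subset == "all":
        return np.ones(len(df), dtype=bool)
    if subset == "with_WY":
        return df["has_WY"].to_numpy(dtype=bool)
    if subset == "without_WY":
        return ~df["has_WY"].to_numpy(dtype=bool)
    raise NoiseDimorphError(f"unknown subset {subset!r}; expected one of {SUBSETS}")


def het_biased_fraction(table: pd.DataFrame, subset: str = "all") -> float:
    """Fraction of the subset whose heterogametic sex disperses most."""
    if "heterogametic_sex" not in table.columns:
        table = annotate_dispersal(table)
    mask = _subset_mask(table, subset)
    if not mask.any():
        raise NoiseDimorphError(f"subset {subset!r} is empty")
    biased = (
        table.loc[mask, "dispersing_sex"].to_numpy()
        == table.loc[mask, "heterogametic_sex"].to_numpy()
    )
    return float(biased.mean())


def tag_permutation_test(
    table: pd.DataFrame,
    subset: str = "all",
    n_sim: int = DEFAULT_N_SIM,
    seed: int | None = None,
) -> DispersalTestResult:
    """Monte Carlo test of the heterogamety-biased dispersal fraction.

    Chromosome-system tags are permuted across the *full* table each
    replicate (dispersing sexes stay put); heterogametic sex and W/Y
    presence are re-derived from the permuted tags and the subset is
    re-formed from them before the fraction is recomputed.
    """
    if n_sim < 1:
        raise NoiseDimorphError("n_sim must be >= 1")
    if "heterogametic_sex" not in table.columns:
        table = annotate_dispersal(table)
    observed = het_biased_fraction(table, subset)
    n_obs = int(_subset_mask(table, subset).sum())

    het_male = (table["heterogametic_sex"] == "male").to_numpy()
    has_wy = table["has_WY"].to_numpy(dtype=bool)
    disp_male = (table["dispersing_sex"] == "male").to_numpy()
    n = len(table)

    rng = np.random.default_rng(seed)
    # permute tag *indices*; each tag carries (heterogametic sex, W/Y flag)
    perms = np.argsort(rng.random((n_sim, n)), axis=1)
    het_male_p = het_male[perms]
    if subset == "all":
        sub = np.ones((n_sim, n), dtype=bool)
    else:
        wy_p = has_wy[perms]
        sub = wy_p if subset == "with_WY" else ~wy_p
    biased = (het_male_p == disp_male[None, :]) & sub
    sizes = sub.sum(axis=1)
    if (sizes == 0).any():
        raise NoiseDimorphError(f"subset {subset!r} empty under permutation")
    fractions = biased.sum(axis=1) / sizes

    p5, p95 = np.percentile(fractions, [5, 95])
    return DispersalTestResult(
        subset=subset,
        n=n_obs,
        observed_fraction=observed,
        p5=float(p5),
        p95=float(p95),
        p_upper=float(np.mean(fractions >= observed)),
        p_lower=float(np.mean(fractions <= observed)),
        simulated=fractions,
        n_sim=n_sim,
        seed=seed,
    )


def dispersal_report(
    table: pd.DataFrame,
    n_sim: int = DEFAULT_N_SIM,
    seed: int | None = None,
) -> list[DispersalTestResult]:
    """Run the permutation test for all three standard subsets."""
    return [tag_permutation_test(table, s, n_sim=n_sim, seed=seed) for s in SUBSETS]
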