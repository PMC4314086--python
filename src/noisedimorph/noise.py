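"""Paired female/male coefficients of variation.

The unit of analysis is either a transcript (expression data, one CV
per sex over the biological replicates of a strain or pooled genotype)
or a trait cell (one CV per sex over the replicates defined by the
assay design). The output is always a *paired CV table*: a DataFrame
with columns ``unit_id``, ``cv_f``, ``cv_m`` and optionally ``color``,
one row per analysis unit with both members of the pair present.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, SEXES, validate_trait_table
from .exceptions import (
    DegenerateMeanError,
    InsufficientReplicationError,
    NoiseDimorphError,
)
from .synthetic import TRAIT_DESIGNS

logger = logging.getLogger(__name__)


def compute_cv(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over mean.

    Raises
    ------
    InsufficientReplicationError
        If fewer than two values are supplied.
    DegenerateMeanError
        If the mean is not strictly positive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("compute_cv expects a 1-D sequence")
    if arr.size < 2:
        raise InsufficientReplicationError(
            f"CV needs >= 2 replicate values, got {arr.size}"
        )
    if not np.isfinite(arr).all():
        raise ValueError("replicate values must be finite")
    mean = arr.mean()
    if mean <= 0:
        raise DegenerateMeanError(f"mean must be > 0, got {mean}")
    return float(arr.std(ddof=1) / mean)


def pool_by_genotype(
    ds: ExpressionDataset, genotype_map: dict[str, str]
) -> ExpressionDataset:
    """Relabel strains by genotype, merging same-genotype replicate groups.

    Expression values are untouched; the strain column is replaced by
    the mapped genotype label and replicate indices are renumbered
    within each (genotype, sex) cell, so three strains of one genotype
    with 3 replicates per sex become one group with 9.
    """
    unmapped = set(ds.samples["strain"].unique()) - set(genotype_map)
    if unmapped:
        raise NoiseDimorphError(
            f"strains missing from genotype map: {sorted(unmapped)}"
        )
    samples = ds.samples.copy()
    samples["strain"] = samples["strain"].map(genotype_map)
    samples["genotype"] = samples["strain"]
    samples["replicate"] = samples.groupby(["strain", "sex"], sort=False).cumcount() + 1
    return ExpressionDataset(values=ds.values, samples=samples, truth=ds.truth)


def _sex_blocks(ds: ExpressionDataset, group: str) -> dict[str, np.ndarray]:
    """Per-sex value blocks (transcripts x replicates) for one strain label."""
    mask = ds.samples["strain"] == group
    if not mask.any():
        raise NoiseDimorphError(f"no samples for group {group!r}")
    blocks = {}
    for sex in SEXES:
        cols = ds.samples.index[mask & (ds.samples["sex"] == sex)]
        if len(cols) == 0:
            raise NoiseDimorphError(f"group {group!r} has no {sex} samples")
        if len(cols) < 2:
            raise InsufficientReplicationError(
                f"group {group!r} has {len(cols)} {sex} replicate(s); need >= 2"
            )
        blocks[sex] = ds.values[list(cols)].to_numpy(dtype=float)
    return blocks


def paired_cv_expression(ds: ExpressionDataset, group: str) -> pd.DataFrame:
    """Per-transcript (CV_F, CV_M) over one strain's (or pooled genotype's)
    female and male replicates.

    Transcripts whose replicate mean is not strictly positive in either
    sex are excluded (normalized microarray values can dip below zero);
    the exclusion count is logged.
    """
    blocks = _sex_blocks(ds, group)
    cvs = {}
    keep = np.ones(ds.n_transcripts, dtype=bool)
    for sex, block in blocks.items():
        means = block.mean(axis=1)
        keep &= means > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            cvs[sex] = block.std(axis=1, ddof=1) / means
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "group %s: excluded %d transcript(s) with non-positive mean",
            group,
            n_dropped,
        )
    out = pd.DataFrame(
        {
            "unit_id": ds.values.index[keep],
            "cv_f": cvs["female"][keep],
            "cv_m": cvs["male"][keep],
        }
    ).reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def paired_cv_traits(ds: pd.DataFrame, design: str) -> pd.DataFrame:
    """Paired per-unit (CV_F, CV_M) for a grouped trait assay.

    * ``per_individual_by_day`` — unit is (strain, day); replicates are
      the individuals assayed together.
    * ``vial_means`` / ``group_means`` — unit is the strain; replicates
      are the per-vial (per-group) averages.

    Units missing a sex or with fewer than two replicates in either sex
    are dropped; the number dropped is logged and recorded in
    ``result.attrs['n_dropped']``.
    """
    if design not in TRAIT_DESIGNS:
        raise NoiseDimorphError(
            f"unknown design {design!r}; expected one of {TRAIT_DESIGNS}"
        )
    ds = validate_trait_table(ds)
    if design == "per_individual_by_day":
        reps = ds.rename(columns={"value": "rep_value"})
        reps["unit_id"] = reps["strain"].astype(str) + ":" + reps["group"].astype(str)
    else:
        reps = (
            ds.groupby(["strain", "sex", "group"], sort=False, as_index=False)["value"]
            .mean()
            .rename(columns={"value": "rep_value"})
        )
        reps["unit_id"] = reps["strain"].astype(str)

    rows = []
    n_dropped = 0
    for unit_id, sub in reps.groupby("unit_id", sort=True):
        by_sex = {sex: grp["rep_value"].to_numpy() for sex, grp in sub.groupby("sex")}
        if set(by_sex) != set(SEXES) or min(len(v) for v in by_sex.values()) < 2:
            n_dropped += 1
            continue
        try:
            rows.append(
                {
                    "unit_id": unit_id,
                    "cv_f": compute_cv(by_sex["female"]),
                    "cv_m": compute_cv(by_sex["male"]),
                }
            )
        except DegenerateMeanError:
            n_dropped += 1
    if n_dropped:
        logger.info(
            "design %s: dropped %d unit(s) failing the replication filter",
            design,
            n_dropped,
        )
    out = pd.DataFrame(rows, columns=["unit_id", "cv_f", "cv_m"])
    out.attrs["n_dropped"] = n_dropped
    return out


def write_paired_cv_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_paired_cv_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"unit_id", "cv_f", "cv_m"} - set(df.columns)
    if missing:
        raise NoiseDimorphError(f"paired CV table missing columns: {sorted(missing)}")
    return df
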