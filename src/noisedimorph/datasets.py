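"""Core in-memory containers and their TSV round-trips.

The package works on three tabular objects:

``ExpressionDataset``
    A transcripts x samples matrix of positive, normalized expression
    values together with per-sample annotations (strain, genotype, sex,
    replicate index).

``TraitDataset``
    A long-format table of individual trait measurements: one row per
    measured individual, annotated with strain, sex and a replication
    group (assay day or vial).

``DispersalTable``
    One row per species with its chromosome system (XY / XO / ZW / ZO)
    and the sex that disperses most; heterogamety columns are derived.

Trait and dispersal tables are plain :class:`pandas.DataFrame` objects
with documented, validated schemas; the expression matrix gets a small
dataclass because matrix and annotations must stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParseError

SEXES = ("female", "male")

#: Chromosome systems and the heterogametic sex each one implies.
HETEROGAMETIC_SEX = {"XY": "male", "XO": "male", "ZW": "female", "ZO": "female"}

#: Systems in which the heterogametic sex carries a sex-specific (W/Y) chromosome.
HAS_WY = {"XY": True, "ZW": True, "XO": False, "ZO": False}

TRAIT_COLUMNS = ["strain", "sex", "group", "individual", "value"]
DISPERSAL_COLUMNS = ["species", "taxon", "chromosome_system", "dispersing_sex"]


@dataclass
class ExpressionDataset:
    """Normalized expression matrix plus sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by transcript id, one column per sample id.
        Values are positive expression units (already normalized).
    samples
        DataFrame indexed by sample id with columns ``strain``,
        ``genotype``, ``sex`` and ``replicate``. Column order of
        ``values`` must match the index of ``samples``.
    truth
        Optional per-transcript ground truth attached by the simulator
        (columns ``mean``, ``cv_female``, ``cv_male``); absent for real
        data and ignored by all analyses.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample columns of `values` must match `samples` index")
        missing = {"strain", "genotype", "sex", "replicate"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample annotations missing columns: {sorted(missing)}")
        bad_sex = set(self.samples["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise ValueError(f"sex must be one of {SEXES}, got {sorted(bad_sex)}")
        if self.values.index.has_duplicates:
            raise ValueError("transcript ids must be unique")

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def write_tsv(self, matrix_path, metadata_path) -> None:
        """Write matrix and sample metadata as two TSV files."""
        out = self.values.copy()
        out.index.name = "transcript_id"
        out.to_csv(matrix_path, sep="\t")
        meta = self.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")

    @classmethod
    def read_tsv(cls, matrix_path, metadata_path) -> "ExpressionDataset":
        values = pd.read_csv(matrix_path, sep="\t", index_col="transcript_id")
        samples = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        extra = set(values.columns) ^ set(samples.index)
        if extra:
            raise ParseError(
                f"matrix and metadata disagree on samples: {sorted(extra)}"
            )
        # order metadata rows to match the matrix columns
        samples = samples.loc[list(values.columns)]
        return cls(values=values, samples=samples)


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format trait schema and return the frame."""
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"trait table missing columns: {sorted(missing)}")
    if not np.isfinite(df["value"]).all():
        raise ParseError("trait measurements must be finite")
    bad_sex = set(df["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ParseError(f"sex must be one of {SEXES}, got {sorted(bad_sex)}")
    return df


def read_trait_tsv(path) -> pd.DataFrame:
    return validate_trait_table(pd.read_csv(path, sep="\t"))


def annotate_dispersal(df: pd.DataFrame) -> pd.DataFrame:
    """Derive heterogametic sex and W/Y presence from chromosome systems.

    Rows whose dispersing sex is missing or not one of female/male
    (e.g. species with unknown or unbiased dispersal) are dropped; the
    number of dropped rows is recorded in ``df.attrs['n_dropped']``.
    """
    missing = set(DISPERSAL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"dispersal table missing columns: {sorted(missing)}")
    bad = set(df["chromosome_system"].unique()) - set(HETEROGAMETIC_SEX)
    if bad:
        raise ParseError(f"unknown chromosome systems: {sorted(bad)}")
    keep = df["dispersing_sex"].isin(SEXES)
    n_dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True).copy()
    df["heterogametic_sex"] = df["chromosome_system"].map(HETEROGAMETIC_SEX)
    df["has_WY"] = df["chromosome_system"].map(HAS_WY)
    df.attrs["n_dropped"] = n_dropped
    return df


def read_dispersal_tsv(path) -> pd.DataFrame:
    return annotate_dispersal(pd.read_csv(path, sep="\t"))
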