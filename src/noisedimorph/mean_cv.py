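"""Quadratic mean-CV regression and the female/male R-squared ratio.

Gene expression noise is usually dominated by the mean expression
level: CV falls predictably with abundance. Fitting ``CV ~ mean +
mean^2`` per sex and comparing the coefficients of determination asks
how much of each sex's noise is explained by that coupling alone. A
smaller male R-squared indicates additional, mean-independent noise in
males.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .exceptions import DegenerateFitError
from .noise import paired_cv_expression

logger = logging.getLogger(__name__)


@dataclass
class QuadraticFit:
    """OLS fit of y on (1, x, x^2)."""

    b0: float
    b1: float
    b2: float
    r2: float
    n_points: int


@dataclass
class SexR2Comparison:
    r2_female: float
    r2_male: float
    #: r2_female / r2_male, or None when r2_male is exactly zero
    ratio: float | None


def fit_quadratic(x, y, log_scale: bool = False) -> QuadraticFit:
    """Ordinary least squares of y on (1, x, x^2).

    With ``log_scale`` both variables are log10-transformed first
    (requires positive values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 4:
        raise DegenerateFitError("need >= 4 points for a quadratic fit")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if log_scale:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log_scale requires positive x and y")
        x, y = np.log10(x), np.log10(y)
    design = np.column_stack([np.ones_like(x), x, x * x])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateFitError("degenerate design: x values are collinear")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        warnings.warn("constant y: R^2 defined as 0", RuntimeWarning, stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - float((resid**2).sum()) / sst
    return QuadraticFit(
        b0=float(coef[0]),
        b1=float(coef[1]),
        b2=float(coef[2]),
        r2=max(0.0, min(1.0, r2)),
        n_points=x.size,
    )


def sex_mean_cv(ds: ExpressionDataset, group: str) -> pd.DataFrame:
    """Per-transcript replicate mean and CV for each sex of one group.

    Returns columns ``mean_female``, ``cv_female``, ``mean_male``,
    ``cv_male`` indexed by transcript, restricted to transcripts with
    positive means in both sexes.
    """
    pairs = paired_cv_expression(ds, group)
    from .noise import _sex_blocks  # shared replicate-block selection

    blocks = _sex_blocks(ds, group)
    keep = ds.values.index.isin(pairs["unit_id"])
    out = pd.DataFrame(index=ds.values.index[keep])
    for sex, block in blocks.items():
        means = block.mean(axis=1)[keep]
        out[f"mean_{sex}"] = means
        out[f"cv_{sex}"] = block.std(axis=1, ddof=1)[keep] / means
    return out


def r2_sex_ratio(
    ds: ExpressionDataset, group: str, log_scale: bool = False
) -> SexR2Comparison:
    """Quadratic mean-CV R-squared per sex and their female/male ratio.

    ``ratio`` is None (an "infinite" flag) when the male R-squared is
    exactly zero.
    """
    table = sex_mean_cv(ds, group)
    r2 = {}
    for sex in ("female", "male"):
        fit = fit_quadratic(
            table[f"mean_{sex}"].to_numpy(),
            table[f"cv_{sex}"].to_numpy(),
            log_scale=log_scale,
        )
        r2[sex] = fit.r2
    if r2["male"] == 0.0:
        logger.warning("group %s: male R^2 is zero; ratio undefined", group)
        ratio = None
    else:
        ratio = r2["female"] / r2["male"]
    return SexR2Comparison(r2_female=r2["female"], r2_male=r2["male"], ratio=ratio)
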