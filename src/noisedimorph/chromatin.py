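"""Chromatin-color assignment and the color-stratified Monte Carlo test.

The fly genome can be segmented into five chromatin states named by
colors — YELLOW (broadly expressed), BLACK and RED (repressive /
nuclear-periphery associated), BLUE and GREEN (heterochromatin). A gene
receives a color only if its whole span lies inside a *single* tract of
that color; genes crossing any tract boundary (even between two tracts
of the same color) stay unassigned.

All genomic coordinates are 0-based half-open internally. BED input is
used natively; GFF3 gene features are converted on read (1-based
inclusive start becomes start-1). Containment is inclusive of exact
boundary equality.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import rankdata

from .exceptions import NoiseDimorphError, ParseError
from .signed_rank import DEFAULT_N_SIM, SignedRankResult, _CHUNK, summarize, wilcoxon_w

logger = logging.getLogger(__name__)

COLORS = ("YELLOW", "BLACK", "BLUE", "RED", "GREEN")
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ColorTract:
    chrom: str
    start: int
    end: int
    color: str


@dataclass(frozen=True)
class GeneSpan:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."


def _check_interval(chrom: str, start: int, end: int, lineno: int, path) -> None:
    if start < 0 or start >= end:
        raise ParseError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")


def read_color_tracts(path) -> list[ColorTract]:
    """Read color tracts from BED4 (name column = color word, any case)."""
    tracts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = fields[:4]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            _check_interval(chrom, start, end, lineno, path)
            color = name.upper()
            if color not in COLORS:
                raise ParseError(
                    f"{path}:{lineno}: unknown color {name!r}; expected one of {COLORS}"
                )
            tracts.append(ColorTract(chrom, start, end, color))
    _check_non_overlapping(tracts)
    return tracts


def _check_non_overlapping(tracts: list[ColorTract]) -> None:
    by_chrom: dict[str, list[ColorTract]] = {}
    for t in tracts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        ts = sorted(ts, key=lambda t: t.start)
        for prev, cur in zip(ts, ts[1:]):
            if cur.start < prev.end:
                raise ParseError(
                    f"overlapping tracts on {chrom}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )


def read_gene_spans(path) -> list[GeneSpan]:
    """Read gene spans from BED6 or GFF3 (``gene`` features only).

    Format is chosen by extension: ``.bed`` is read natively (0-based
    half-open); ``.gff``/``.gff3`` is converted to 0-based half-open.
    """
    path = str(path)
    if path.endswith(".bed"):
        return _read_genes_bed(path)
    if path.endswith((".gff", ".gff3")):
        return _read_genes_gff3(path)
    raise ParseError(f"cannot infer gene-span format from extension: {path}")


def _read_genes_bed(path) -> list[GeneSpan]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            _check_interval(chrom, start, end, lineno, path)
            genes.append(GeneSpan(name, chrom, start, end, strand))
    _check_unique_ids(genes)
    return genes


_GFF_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id)=([^;]+)")


def _read_genes_gff3(path) -> list[GeneSpan]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start) - 1, int(end)  # 1-based inclusive -> half-open
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            _check_interval(chrom, start, end, lineno, path)
            m = _GFF_ID.search(attrs)
            if not m:
                raise ParseError(f"{path}:{lineno}: gene feature lacks an ID attribute")
            genes.append(GeneSpan(m.group(1), chrom, start, end, strand))
    _check_unique_ids(genes)
    return genes


def _check_unique_ids(genes: list[GeneSpan]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ParseError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)


def merge_same_color(tracts: list[ColorTract]) -> list[ColorTract]:
    """Merge touching or adjacent tracts of identical color on a chromosome."""
    merged: list[ColorTract] = []
    by_chrom: dict[str, list[ColorTract]] = {}
    for t in tracts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom in sorted(by_chrom):
        ts = sorted(by_chrom[chrom], key=lambda t: t.start)
        cur = ts[0]
        for nxt in ts[1:]:
            if nxt.color == cur.color and nxt.start <= cur.end:
                cur = ColorTract(chrom, cur.start, max(cur.end, nxt.end), cur.color)
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    return merged


def assign_colors(
    genes: list[GeneSpan],
    tracts: list[ColorTract],
    merge_adjacent: bool = False,
) -> pd.Series:
    """Color per gene by full single-tract containment.

    A gene gets color *c* iff one tract of color *c* has
    ``tract.start <= gene.start`` and ``gene.end <= tract.end``;
    otherwise it is UNASSIGNED. With ``merge_adjacent`` touching
    same-color tracts are merged before the containment test (off by
    default: a gene crossing any tract boundary stays unassigned).
    """
    if merge_adjacent:
        tracts = merge_same_color(tracts)
    trees: dict[str, IntervalTree] = {}
    for t in tracts:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.color)
    calls = {}
    for g in genes:
        color = UNASSIGNED
        tree = trees.get(g.chrom)
        if tree is not None:
            # tracts are non-overlapping: at most one tract covers g.start
            for iv in tree.at(g.start):
                if iv.begin <= g.start and g.end <= iv.end:
                    color = iv.data
        calls[g.gene_id] = color
    out = pd.Series(calls, name="color")
    n_un = int((out == UNASSIGNED).sum())
    logger.info("assigned colors to %d/%d genes", len(out) - n_un, len(out))
    return out


def stratified_test(
    pairs: pd.DataFrame,
    n_sim: int = DEFAULT_N_SIM,
    seed: int | None = None,
) -> dict[str, SignedRankResult]:
    """Per-color Monte Carlo Wilcoxon tests with a shared permutation null.

    ``pairs`` must carry a ``color`` column; UNASSIGNED rows never enter
    any stratum. Ranks are computed *within* each color. Each of the
    ``n_sim`` null replicates draws one global rearrangement of all the
    colored CV values (pooled across colors and sexes) and recomputes
    every color's within-color W from it, so the per-color nulls share
    permutations.
    """
    if "color" not in pairs.columns:
        raise NoiseDimorphError("paired CV table lacks a 'color' column")
    colored = pairs[pairs["color"].isin(COLORS)].reset_index(drop=True)
    if len(colored) == 0:
        raise NoiseDimorphError("no colored pairs to test")
    skipped = sorted(set(pairs["color"]) - set(COLORS) - {UNASSIGNED})
    if skipped:
        logger.info("ignoring unknown color labels: %s", skipped)

    present = [c for c in COLORS if (colored["color"] == c).any()]
    idx_by_color = {
        c: np.flatnonzero((colored["color"] == c).to_numpy()) for c in present
    }
    observed = {c: wilcoxon_w(colored.iloc[idx_by_color[c]]) for c in present}

    n = len(colored)
    pool = np.concatenate(
        [
            colored["cv_f"].to_numpy(dtype=float),
            colored["cv_m"].to_numpy(dtype=float),
        ]
    )
    rng = np.random.default_rng(seed)
    sims = {c: np.empty(n_sim) for c in present}
    for start in range(0, n_sim, _CHUNK):
        m = min(_CHUNK, n_sim - start)
        mat = np.tile(pool, (m, 1))
        rng.permuted(mat, axis=1, out=mat)
        d = mat[:, :n] - mat[:, n:]
        for c in present:
            sub = d[:, idx_by_color[c]]
            ranks = rankdata(np.abs(sub), axis=1)
            sims[c][start : start + m] = (np.sign(sub) * ranks).sum(axis=1)

    return {
        c: summarize(
            observed[c],
            sims[c],
            n_pairs=len(idx_by_color[c]),
            seed=seed,
            label=c,
        )
        for c in present
    }
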