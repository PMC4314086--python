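"""Color assignment by single-tract containment and the stratified test."""

import numpy as np
import pandas as pd
import pytest

from noisedimorph import (
    ColorTract,
    GeneSpan,
    assign_colors,
    mc_wilcoxon_test,
    read_color_tracts,
    read_gene_spans,
    stratified_test,
)
from noisedimorph.chromatin import UNASSIGNED, merge_same_color
from noisedimorph.exceptions import NoiseDimorphError, ParseError

COLORS = ("YELLOW", "BLACK", "BLUE", "RED", "GREEN")


def naive_assign(genes, tracts):
    """O(genes x tracts) double-loop containment oracle."""
    out = {}
    for g in genes:
        out[g.gene_id] = UNASSIGNED
        for t in tracts:
            if t.chrom == g.chrom and t.start <= g.start and g.end <= t.end:
                out[g.gene_id] = t.color
    return out


class TestAssignColors:
    def test_gene_inside_tract(self):
        calls = assign_colors(
            [GeneSpan("g", "2L", 100, 200)], [ColorTract("2L", 50, 300, "YELLOW")]
        )
        assert calls["g"] == "YELLOW"

    def test_boundary_crossing_gene_unassigned(self):
        tracts = [ColorTract("2L", 50, 300, "RED"), ColorTract("2L", 300, 500, "RED")]
        calls = assign_colors([GeneSpan("g", "2L", 250, 400)], tracts)
        assert calls["g"] == UNASSIGNED

    def test_gene_exactly_equal_to_tract(self):
        calls = assign_colors(
            [GeneSpan("g", "2L", 100, 200)], [ColorTract("2L", 100, 200, "BLUE")]
        )
        assert calls["g"] == "BLUE"

    def test_merge_option_rescues_same_color_boundary(self):
        tracts = [ColorTract("2L", 50, 300, "RED"), ColorTract("2L", 300, 500, "RED")]
        gene = [GeneSpan("g", "2L", 250, 400)]
        assert assign_colors(gene, tracts)["g"] == UNASSIGNED
        assert assign_colors(gene, tracts, merge_adjacent=True)["g"] == "RED"
        assert len(merge_same_color(tracts)) == 1

    def test_wrong_chromosome_unassigned(self):
        calls = assign_colors(
            [GeneSpan("g", "3R", 100, 200)], [ColorTract("2L", 0, 1000, "GREEN")]
        )
        assert calls["g"] == UNASSIGNED

    def test_exhaustive_small_coordinates_vs_double_loop(self):
        """All gene placements on a small coordinate line against the
        naive containment oracle, for a boundary-rich tract layout."""
        tracts = [
            ColorTract("c", 0, 3, "YELLOW"),
            ColorTract("c", 3, 5, "YELLOW"),
            ColorTract("c", 5, 8, "BLACK"),
        ]
        genes = [
            GeneSpan(f"g_{s}_{e}", "c", s, e)
            for s in range(9)
            for e in range(s + 1, 10)
        ]
        calls = assign_colors(genes, tracts)
        assert calls.to_dict() == naive_assign(genes, tracts)

    def test_random_instances_vs_double_loop(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            cuts = np.unique(rng.integers(0, 200, size=12))
            tracts = [
                ColorTract("c", int(a), int(b), COLORS[rng.integers(5)])
                for a, b in zip(cuts, cuts[1:])
                if rng.random() < 0.7  # leave gaps
            ]
            genes = []
            for i in range(40):
                s = int(rng.integers(0, 199))
                e = int(rng.integers(s + 1, 201))
                genes.append(GeneSpan(f"g{i}", "c", s, e))
            calls = assign_colors(genes, tracts)
            assert calls.to_dict() == naive_assign(genes, tracts)


class TestParsing:
    def test_bed_round_trip(self, tmp_path):
        bed = tmp_path / "tracts.bed"
        bed.write_text("2L\t0\t100\tyellow\n2L\t100\t250\tBLACK\n")
        tracts = read_color_tracts(bed)
        assert tracts == [
            ColorTract("2L", 0, 100, "YELLOW"),
            ColorTract("2L", 100, 250, "BLACK"),
        ]

    def test_malformed_interval_reports_line(self, tmp_path):
        bed = tmp_path / "tracts.bed"
        bed.write_text("2L\t0\t100\tyellow\n2L\t90\t50\tred\n")
        with pytest.raises(ParseError, match=":2:"):
            read_color_tracts(bed)

    def test_overlapping_tracts_rejected(self, tmp_path):
        bed = tmp_path / "tracts.bed"
        bed.write_text("2L\t0\t100\tyellow\n2L\t50\t150\tred\n")
        with pytest.raises(ParseError, match="overlapping"):
            read_color_tracts(bed)

    def test_unknown_color_rejected(self, tmp_path):
        bed = tmp_path / "tracts.bed"
        bed.write_text("2L\t0\t100\tmauve\n")
        with pytest.raises(ParseError, match="mauve"):
            read_color_tracts(bed)

    def test_gff3_coordinates_converted(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "2L\tsrc\tgene\t101\t200\t.\t+\t.\tID=gene1\n"
            "2L\tsrc\texon\t101\t150\t.\t+\t.\tID=exon1\n"
        )
        genes = read_gene_spans(gff)
        assert genes == [GeneSpan("gene1", "2L", 100, 200, "+")]

    def test_bed_genes_native_coordinates(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("2L\t100\t200\tgene1\t0\t-\n")
        assert read_gene_spans(bed) == [GeneSpan("gene1", "2L", 100, 200, "-")]


def colored_pairs(rng, sizes):
    rows = []
    for color, n in sizes.items():
        for i in range(n):
            rows.append(
                {"unit_id": f"{color}_{i}", "cv_f": rng.random(),
                 "cv_m": rng.random(), "color": color}
            )
    return pd.DataFrame(rows)


class TestStratifiedTest:
    def test_single_color_reduces_to_plain_test(self):
        rng = np.random.default_rng(0)
        pairs = colored_pairs(rng, {"YELLOW": 40})
        strat = stratified_test(pairs, n_sim=300, seed=5)["YELLOW"]
        plain = mc_wilcoxon_test(pairs, n_sim=300, seed=5)
        assert strat.observed_w == plain.observed_w
        np.testing.assert_array_equal(strat.simulated_w, plain.simulated_w)
        assert (strat.p_upper, strat.p_lower) == (plain.p_upper, plain.p_lower)

    def test_maximal_per_stratum_statistics(self):
        na, nb = 6, 4
        rows = []
        for i in range(na):
            rows.append({"unit_id": f"a{i}", "cv_f": 1.0 + i, "cv_m": 0.5,
                         "color": "YELLOW"})
        for i in range(nb):
            rows.append({"unit_id": f"b{i}", "cv_f": 0.1, "cv_m": 2.0 + i,
                         "color": "BLACK"})
        res = stratified_test(pd.DataFrame(rows), n_sim=10, seed=1)
        assert res["YELLOW"].observed_w == na * (na + 1) / 2
        assert res["BLACK"].observed_w == -nb * (nb + 1) / 2

    def test_unassigned_rows_never_enter_strata(self):
        rng = np.random.default_rng(2)
        pairs = colored_pairs(rng, {"BLUE": 10})
        un = colored_pairs(rng, {UNASSIGNED: 5})
        res = stratified_test(pd.concat([pairs, un]), n_sim=50, seed=3)
        assert set(res) == {"BLUE"}
        assert res["BLUE"].n_pairs == 10

    def test_requires_color_column(self, paired_table):
        with pytest.raises(NoiseDimorphError, match="color"):
            stratified_test(paired_table, n_sim=10, seed=0)

    def test_nulls_share_permutations_across_colors(self):
        """Strata drawn from one global rearrangement: identical seeds give
        identical per-color null streams regardless of other colors' data."""
        rng = np.random.default_rng(4)
        pairs = colored_pairs(rng, {"YELLOW": 20, "GREEN": 10})
        r1 = stratified_test(pairs, n_sim=100, seed=9)
        r2 = stratified_test(pairs, n_sim=100, seed=9)
        for c in ("YELLOW", "GREEN"):
            np.testing.assert_array_equal(r1[c].simulated_w, r2[c].simulated_w)
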