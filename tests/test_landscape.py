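"""Intergenic regions, window tiling, RPM/REL quantification and
neighbor expression."""

import numpy as np
import pandas as pd
import pytest

from chancexpr import io, landscape
from chancexpr.landscape import (
    ExcludedFeature,
    Gene,
    GenomeAnnotation,
    IntergenicRegion,
    build_intergenic_regions,
    extended_footprint,
    gene_expression_and_reference,
    merge_intervals,
    neighbor_expression,
    regions_to_bed,
    tile_windows,
    window_expression,
    window_rel_tests,
)


class TestFootprints:
    def test_annotated_utr_extended_outward(self):
        # two genes whose UTRs end at 1000 / start at 1601:
        # footprints reach 1200 and 1401, leaving region 1201-1400
        g1 = Gene("g1", "chr1", "+", 600, 900, utr5=(500, 599), utr3=(901, 1000))
        g2 = Gene("g2", "chr1", "+", 1701, 2200, utr5=(1601, 1700), utr3=(2201, 2300))
        ann = GenomeAnnotation(genes=[g1, g2], chrom_lengths={"chr1": 3000})
        regions = build_intergenic_regions(ann)
        mid = [r for r in regions if r.start > 1000 and r.end < 1601]
        assert len(mid) == 1
        assert (mid[0].start, mid[0].end) == (1201, 1400)
        assert mid[0].length == 200
        assert (mid[0].left_gene, mid[0].right_gene) == ("g1", "g2")

    def test_gene_without_utrs_allocated_200(self):
        g = Gene("g", "chr1", "+", 5001, 6000)
        assert extended_footprint(g) == (4801, 6200)

    def test_rna_gene_allocated_50(self):
        g = Gene("r", "chr1", "+", 2001, 2100, gtype="tRNA")
        assert extended_footprint(g) == (1951, 2150)

    def test_excluded_features_masked(self):
        g = Gene("g", "chr1", "+", 1001, 2000)
        telo = ExcludedFeature("chr1", 1, 500, "telomere")
        ann = GenomeAnnotation(genes=[g], excluded=[telo], chrom_lengths={"chr1": 5000})
        regions = build_intergenic_regions(ann)
        spans = {(r.start, r.end) for r in regions}
        assert spans == {(501, 800), (2201, 5000)}

    def test_fully_masked_chromosome_gives_no_regions(self):
        g = Gene("g", "chr1", "+", 201, 800)
        ann = GenomeAnnotation(genes=[g], chrom_lengths={"chr1": 1000})
        assert build_intergenic_regions(ann) == []

    def test_out_of_bounds_gene_rejected(self):
        g = Gene("g", "chr1", "+", 1, 2000)
        ann = GenomeAnnotation(genes=[g], chrom_lengths={"chr1": 1000})
        with pytest.raises(ValueError, match="bounds"):
            build_intergenic_regions(ann)

    def test_footprints_and_regions_partition_chromosome(self, null_landscape):
        ann = null_landscape.annotation
        regions = build_intergenic_regions(ann)
        for chrom, clen in ann.chrom_lengths.items():
            masks = [
                extended_footprint(g) for g in ann.genes if g.chrom == chrom
            ] + [(f.start, f.end) for f in ann.excluded if f.chrom == chrom]
            covered = merge_intervals(
                masks + [(r.start, r.end) for r in regions if r.chrom == chrom]
            )
            assert covered == [(1, clen)]


class TestWindows:
    @pytest.mark.parametrize("L,n", [(47, 2), (40, 2), (19, 0), (20, 1)])
    def test_window_count(self, L, n):
        r = IntergenicRegion("r", "chr1", 101, 100 + L)
        w = tile_windows(r)
        assert len(w) == n
        if n:
            assert w["start"].iloc[0] == 101
            assert (w["end"] - w["start"] == 19).all()

    @pytest.mark.parametrize("L,N", [(240, 2), (241, 3), (120, 1), (1, 1)])
    def test_segment_ceiling(self, L, N):
        assert IntergenicRegion("r", "chr1", 1, L).n_segments == N


def windows_counts(rows):
    return pd.DataFrame(
        rows,
        columns=["region_id", "window_index", "strand", "environment", "replicate", "count"],
    )


TOTALS = pd.DataFrame({"environment": ["E"], "replicate": [1], "total": [1e7]})


class TestWindowExpression:
    def test_rpm_arithmetic(self):
        out = window_expression(windows_counts([("r", 0, "+", "E", 1, 5)]), TOTALS)
        assert out["rpm"].iloc[0] == pytest.approx(0.5)

    def test_zero_reads_zero_rpm(self):
        out = window_expression(windows_counts([("r", 0, "-", "E", 1, 0)]), TOTALS)
        assert out["rpm"].iloc[0] == 0.0

    def test_scale_invariance(self):
        counts = windows_counts([("r", 0, "+", "E", 1, 5)])
        a = window_expression(counts, TOTALS)["rpm"]
        counts2 = counts.assign(count=counts["count"] * 2)
        totals2 = TOTALS.assign(total=TOTALS["total"] * 2)
        b = window_expression(counts2, totals2)["rpm"]
        assert np.allclose(a, b)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            window_expression(windows_counts([("r", 0, "+", "E", 1, -1)]), TOTALS)


class TestGeneExpression:
    def _gene_counts(self, per_gene):
        rows = []
        for gid, window_rpms in per_gene.items():
            for w, v in enumerate(window_rpms):
                rows.append((gid, w, "+", "E", 1, v * 10))  # total 1e7 -> rpm = v
        return pd.DataFrame(
            rows, columns=["gene_id", "window_index", "strand", "environment", "replicate", "count"]
        )

    def test_gene_is_mean_of_windows(self):
        ge, _ = gene_expression_and_reference(self._gene_counts({"g": [1, 3]}), TOTALS)
        assert ge["expr"].iloc[0] == pytest.approx(2.0)

    def test_reference_is_median_over_genes(self):
        counts = self._gene_counts({"a": [2], "b": [4], "c": [10]})
        _, ref = gene_expression_and_reference(counts, TOTALS)
        assert ref["reference"].iloc[0] == pytest.approx(4.0)

    def test_uniform_genes_give_unit_rel(self):
        counts = self._gene_counts({"a": [5], "b": [5], "c": [5]})
        _, ref = gene_expression_and_reference(counts, TOTALS)
        wexp = window_expression(windows_counts([("r", 0, "+", "E", 1, 50)]), TOTALS)
        rel = wexp["rpm"].iloc[0] / ref["reference"].iloc[0]
        assert rel == pytest.approx(1.0)


class TestWindowRelTests:
    def _wexp(self, rels_by_rep, reference=10.0):
        rows = [
            ("r", 0, "+", "E", rep, rel * reference * 10)
            for rep, rel in enumerate(rels_by_rep, start=1)
        ]
        counts = windows_counts(rows)
        totals = pd.DataFrame(
            {"environment": "E", "replicate": range(1, len(rels_by_rep) + 1),
             "total": 1e7}
        )
        ref = totals.drop(columns="total").assign(reference=reference)
        return window_expression(counts, totals), ref

    def test_zero_rels_exceed_nothing(self):
        wexp, ref = self._wexp([0.0, 0.0, 0.0])
        grid = window_rel_tests(wexp, ref)["E"]
        assert not grid.filter(like="exceeds").to_numpy().any()

    def test_replicate_rels_near_two_exceed_unity(self):
        wexp, ref = self._wexp([2.0, 2.1, 1.9])
        grid = window_rel_tests(wexp, ref)["E"]
        assert grid["p_1.0"].iloc[0] < 0.01
        assert grid["exceeds_1.0"].iloc[0]

    def test_bins_monotone_on_simulated_landscape(self, null_arm):
        grid = null_arm["grids"]["YPD"]
        for lo, hi in zip(np.arange(0.1, 1.0, 0.1), np.arange(0.2, 1.05, 0.1)):
            assert (grid[f"exceeds_{hi:.1f}"] <= grid[f"exceeds_{lo:.1f}"]).all()


class TestNeighborExpression:
    REGION = IntergenicRegion("r", "chr1", 1000, 1500, left_gene="gl", right_gene="gr")

    def test_mean_of_both_neighbors(self):
        v = neighbor_expression(self.REGION, {"gl": 10.0, "gr": 20.0}, {"gl": "+", "gr": "+"}, "+")
        assert v["mean_both"] == pytest.approx(15.0)

    def test_readthrough_requires_matching_strand(self):
        expr = {"gl": 10.0, "gr": 20.0}
        same = neighbor_expression(self.REGION, expr, {"gl": "+", "gr": "-"}, "+")
        assert same["readthrough"] == pytest.approx(10.0)
        opposite = neighbor_expression(self.REGION, expr, {"gl": "-", "gr": "-"}, "+")
        assert opposite["readthrough"] == 0.0

    def test_direction_flip_switches_upstream_side(self):
        expr = {"gl": 10.0, "gr": 20.0}
        strands = {"gl": "+", "gr": "-"}
        fwd = neighbor_expression(self.REGION, expr, strands, "+")
        rev = neighbor_expression(self.REGION, expr, strands, "-")
        assert fwd["upstream"] == 10.0 and rev["upstream"] == 20.0

    def test_missing_neighbor_undefined_not_zero(self):
        region = IntergenicRegion("r", "chr1", 1, 100, left_gene=None, right_gene="gr")
        v = neighbor_expression(region, {"gr": 20.0}, {"gr": "+"}, "+")
        assert np.isnan(v["mean_both"]) and np.isnan(v["upstream"])


class TestIO:
    def test_bed_conversion_is_half_open(self):
        bed = regions_to_bed([IntergenicRegion("chr1:101-200", "chr1", 101, 200)])
        assert bed.loc[0, "start"] == 100 and bed.loc[0, "end"] == 200
        assert bed.loc[0, "end"] - bed.loc[0, "start"] == 100

    def test_gff3_round_trip_preserves_regions(self, tmp_path, null_landscape):
        path = tmp_path / "toy.gff3"
        io.write_gff3(null_landscape.annotation, path)
        back = io.read_gff3(path)
        assert back.chrom_lengths == null_landscape.annotation.chrom_lengths
        a = {r.region_id for r in build_intergenic_regions(null_landscape.annotation)}
        b = {r.region_id for r in build_intergenic_regions(back)}
        assert a == b

    def test_gff3_round_trip_preserves_gene_details(self, tmp_path):
        genes = [
            Gene("g1", "chr1", "+", 600, 900, utr5=(500, 599), utr3=(901, 1000)),
            Gene("g2", "chr1", "-", 2001, 2100, gtype="tRNA"),
        ]
        ann = GenomeAnnotation(
            genes=genes,
            excluded=[ExcludedFeature("chr1", 1, 100, "telomere")],
            chrom_lengths={"chr1": 3000},
        )
        path = tmp_path / "two.gff3"
        io.write_gff3(ann, path)
        back = io.read_gff3(path)
        g1 = next(g for g in back.genes if g.gene_id == "g1")
        assert (g1.start, g1.end, g1.utr5, g1.utr3) == (600, 900, (500, 599), (901, 1000))
        g2 = next(g for g in back.genes if g.gene_id == "g2")
        assert g2.gtype == "tRNA" and g2.strand == "-"
        assert back.excluded[0].ftype == "telomere"
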