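"""Nearest-feature assignment, scale-aware collapsing and the gene-level table."""

import numpy as np
import pytest

from trackwise.core import (
    AttachedColumn,
    GeneAnnotation,
    GenomicInterval,
    NOT_DEFINED,
    Scale,
    ScaleKind,
    Track,
)
from trackwise.aggregate import (
    aggregate_column,
    aggregate_one,
    assign_to_features,
    bin_numeric_to_ordinal,
    build_aggregated_table,
    count_intervals,
)
from trackwise.track_io import Config


def brute_force_assign(track, annotation, max_distance):
    """Exhaustive all-pairs minimum-gap oracle with the documented tie-break."""
    out = []
    for iv in track.intervals:
        best = None
        for fid, giv in sorted(
            annotation.entries, key=lambda e: (e[1].chrom, e[1].start, e[0])
        ):
            gap = iv.gap(giv)
            if gap is None or gap > max_distance:
                continue
            if best is None or gap < best[0]:
                best = (gap, fid)
        out.append(best[1] if best else None)
    return out


def random_instance(rng, n_genes, n_intervals):
    entries = []
    for g in range(n_genes):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, 95_000))
        entries.append((f"g{g:03d}", GenomicInterval(chrom, start, start + int(rng.integers(1, 5_000)))))
    ann = GeneAnnotation(entries=entries)
    intervals = []
    for _ in range(n_intervals):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, 99_000))
        intervals.append(GenomicInterval(chrom, start, start + int(rng.integers(1, 1_000))))
    track = Track(id="t", technology="x", condition="y", intervals=intervals)
    return track, ann


class TestAssignToFeatures:
    def test_containment_gives_gap_zero(self):
        ann = GeneAnnotation(entries=[("g", GenomicInterval("chr1", 900, 2_000))])
        track = Track(id="t", technology="x", condition="y",
                      intervals=[GenomicInterval("chr1", 1_000, 1_200)])
        assert assign_to_features(track, ann, 0).feature_of == ["g"]

    def test_distance_cap_excludes_far_feature(self):
        # interval ends 500 bp before gene A, starts 2000 bp after gene B
        ann = GeneAnnotation(entries=[
            ("geneA", GenomicInterval("chr1", 10_500, 11_000)),
            ("geneB", GenomicInterval("chr1", 1_000, 8_000)),
        ])
        track = Track(id="t", technology="x", condition="y",
                      intervals=[GenomicInterval("chr1", 10_000, 10_000 + 1)])
        a = assign_to_features(track, ann, max_distance=1_000)
        assert a.feature_of == ["geneA"]

    def test_unassigned_outside_cap(self):
        ann = GeneAnnotation(entries=[("g", GenomicInterval("chr1", 100_000, 101_000))])
        track = Track(id="t", technology="x", condition="y",
                      intervals=[GenomicInterval("chr1", 0, 100)])
        assert assign_to_features(track, ann, 10_000).feature_of == [None]

    def test_equidistant_tie_breaks_to_lowest_start_then_id(self):
        ann = GeneAnnotation(entries=[
            ("zzz", GenomicInterval("chr1", 2_000, 3_000)),
            ("aaa", GenomicInterval("chr1", 0, 1_000)),
        ])
        # interval sits exactly 100 bp from both genes
        track = Track(id="t", technology="x", condition="y",
                      intervals=[GenomicInterval("chr1", 1_100, 1_900)])
        assert assign_to_features(track, ann, 10_000).feature_of == ["aaa"]
        # same start: feature id decides
        ann2 = GeneAnnotation(entries=[
            ("b", GenomicInterval("chr1", 0, 1_000)),
            ("a", GenomicInterval("chr1", 0, 1_000)),
        ])
        assert assign_to_features(track, ann2, 10_000).feature_of == ["a"]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            track, ann = random_instance(
                rng, n_genes=int(rng.integers(2, 30)), n_intervals=int(rng.integers(1, 80))
            )
            max_distance = int(rng.choice([0, 100, 5_000, 50_000]))
            got = assign_to_features(track, ann, max_distance).feature_of
            assert got == brute_force_assign(track, ann, max_distance)

    def test_conservation_of_assigned_intervals(self):
        rng = np.random.default_rng(11)
        track, ann = random_instance(rng, 20, 200)
        a = assign_to_features(track, ann, 5_000)
        counts = count_intervals(a, ann.feature_ids)
        assert sum(counts.values()) == a.n_assigned

    def test_enlarging_cap_never_unassigns(self):
        rng = np.random.default_rng(12)
        track, ann = random_instance(rng, 15, 150)
        small = assign_to_features(track, ann, 1_000).feature_of
        large = assign_to_features(track, ann, 20_000).feature_of
        for s, l in zip(small, large):
            if s is not None:
                assert l is not None


RAT = Scale(ScaleKind.RATIONAL)
ORD = Scale(ScaleKind.ORDINAL, ("low", "medium", "high"))


class TestAggregateValues:
    def test_max_of_two_peak_scores(self):
        assert aggregate_one([5.0, 9.0], RAT, "max") == 9.0

    def test_mean_of_two_expression_values(self):
        assert aggregate_one([4.0, 6.0], RAT, "mean") == 5.0

    def test_mode_majority(self):
        assert aggregate_one(["low", "high", "high"], ORD, "mode") == "high"

    def test_ordinal_median_is_a_real_level(self):
        assert aggregate_one(["low", "high", "medium", "high"], ORD, "median") == "medium"

    def test_empty_group_is_not_defined(self):
        out = aggregate_column({}, RAT, "mean", ["g1"])
        assert out["g1"] is NOT_DEFINED

    @pytest.mark.parametrize(
        "values,scale,aggregator",
        [
            ([3.7], RAT, "mean"),
            ([3.7], RAT, "max"),
            ([3.7], Scale(ScaleKind.INTERVAL), "median"),
            (["medium"], ORD, "median"),
            (["medium"], ORD, "mode"),
        ],
    )
    def test_singleton_group_is_identity(self, values, scale, aggregator):
        assert aggregate_one(values, scale, aggregator) == values[0]

    def test_illegal_aggregator_for_scale(self):
        with pytest.raises(ValueError, match="not legal"):
            aggregate_one(["a", "b"], Scale(ScaleKind.NOMINAL, ("a", "b", "c")), "mean")


class TestCountIntervals:
    def test_counts_and_zero_for_empty(self, micro_table):
        # value-less ATAC track: 2 intervals on geneA, 1 on geneE, 0 elsewhere
        col = micro_table.data["open.count"]
        assert col["geneA"] == 2
        assert col["geneE"] == 1
        assert col["geneB"] == 0  # zero is a real count, not missing
        assert micro_table.n_defined("open.count") == micro_table.n_features


class TestBuildAggregatedTable:
    def test_column_arithmetic(self, micro_table):
        # 3 tracks: one with score column, one with fpkm, one value-less -> 3 columns
        assert micro_table.n_features == 5
        assert [c.name for c in micro_table.columns] == [
            "expr.fpkm", "open.count", "peaks.score",
        ]

    def test_three_aggregation_cases(self, micro_table):
        # several peak scores on one gene -> max; several expression values -> mean
        assert micro_table.cell("geneA", "peaks.score") == 9.0
        assert micro_table.cell("geneA", "expr.fpkm") == 5.0
        # no interval on the gene -> not-defined
        assert micro_table.cell("geneC", "peaks.score") is NOT_DEFINED

    def test_track_order_invariance(self, micro_annotation, peak_track,
                                    expression_track, countless_track):
        config = Config(aggregators={"score": "max"})
        t1 = build_aggregated_table(
            [peak_track, expression_track, countless_track], micro_annotation, config)
        t2 = build_aggregated_table(
            [countless_track, peak_track, expression_track], micro_annotation, config)
        assert t1.data.equals(t2.data)

    def test_custom_ranges_replace_genes(self, peak_track):
        enhancers = GeneAnnotation(
            entries=[
                ("enh1", GenomicInterval("chr1", 1_000, 1_300)),
                ("enh2", GenomicInterval("chr1", 1_900, 2_200)),
                ("enh3", GenomicInterval("chr1", 10_400, 10_700)),
                ("enh4", GenomicInterval("chr2", 5_000, 5_500)),
            ],
            source="custom-ranges",
        )
        table = build_aggregated_table([peak_track], enhancers, Config(max_distance=0))
        assert table.feature_ids == ["enh1", "enh2", "enh3", "enh4"]
        assert table.cell("enh1", "peaks.score") == 5.0

    def test_binning_declared_column(self, micro_annotation):
        track = Track(
            id="meth", technology="RRBS", condition="wt",
            intervals=[GenomicInterval("chr1", 1_100, 1_200),
                       GenomicInterval("chr1", 10_500, 10_600),
                       GenomicInterval("chr2", 2_100, 2_200)],
            columns=[AttachedColumn("fraction", [0.1, 0.5, 0.9])],
        )
        config = Config(binning_columns=["fraction"])
        table = build_aggregated_table([track], micro_annotation, config)
        info = table.column_info("meth.fraction")
        assert info.scale.kind is ScaleKind.ORDINAL
        assert table.cell("geneA", "meth.fraction") == "low"
        assert table.cell("geneB", "meth.fraction") == "medium"
        assert table.cell("geneD", "meth.fraction") == "high"


class TestBinning:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.1, "low"),
            (0.5, "medium"),
            (0.9, "high"),
            (0.2, "medium"),  # boundary joins the middle bin ("between 20% and 80%")
            (0.8, "medium"),
            (0.0, "low"),
            (1.0, "high"),
        ],
    )
    def test_default_breaks(self, value, expected):
        assert bin_numeric_to_ordinal([value], [0.2, 0.8], ["low", "medium", "high"]) == [expected]

    def test_missing_stays_missing(self):
        assert bin_numeric_to_ordinal([None, 0.5], [0.2, 0.8], ["l", "m", "h"]) == [None, "m"]

    def test_non_numeric_rejected(self):
        with pytest.raises(ValueError, match="non-numeric"):
            bin_numeric_to_ordinal(["x"], [0.2, 0.8], ["l", "m", "h"])

    def test_bad_breaks_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            bin_numeric_to_ordinal([0.5], [0.8, 0.2], ["l", "m", "h"])
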