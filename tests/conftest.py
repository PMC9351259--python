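import pytest

from trackwise.core import (
    AttachedColumn,
    GeneAnnotation,
    GenomicInterval,
    Scale,
    ScaleKind,
    Track,
)
from trackwise.aggregate import build_aggregated_table
from trackwise.track_io import Config


@pytest.fixture
def micro_annotation():
    """Five genes on two chromosomes."""
    return GeneAnnotation(
        entries=[
            ("geneA", GenomicInterval("chr1", 1_000, 3_000)),
            ("geneB", GenomicInterval("chr1", 10_000, 12_000)),
            ("geneC", GenomicInterval("chr1", 50_000, 55_000)),
            ("geneD", GenomicInterval("chr2", 2_000, 4_000)),
            ("geneE", GenomicInterval("chr2", 30_000, 31_000)),
        ]
    )


def make_track(track_id, intervals, columns=(), technology="ChIP", condition="wt"):
    return Track(
        id=track_id,
        technology=technology,
        condition=condition,
        intervals=[GenomicInterval(*iv) for iv in intervals],
        columns=list(columns),
    )


@pytest.fixture
def peak_track():
    """Two peaks on geneA, one on geneB, none elsewhere; rational scores."""
    return make_track(
        "peaks",
        [("chr1", 1_100, 1_200), ("chr1", 2_000, 2_100), ("chr1", 10_500, 10_600)],
        [AttachedColumn("score", [5.0, 9.0, 7.0], Scale(ScaleKind.RATIONAL))],
    )


@pytest.fixture
def expression_track():
    return make_track(
        "expr",
        [("chr1", 1_000, 1_500), ("chr1", 1_600, 2_000), ("chr2", 2_100, 2_500)],
        [AttachedColumn("fpkm", [4.0, 6.0, 2.5], Scale(ScaleKind.RATIONAL))],
        technology="RNA-seq",
    )


@pytest.fixture
def countless_track():
    return make_track(
        "open",
        [("chr1", 1_050, 1_150), ("chr1", 2_500, 2_600), ("chr2", 30_100, 30_200)],
        technology="ATAC",
    )


@pytest.fixture
def micro_table(micro_annotation, peak_track, expression_track, countless_track):
    config = Config(aggregators={"score": "max"})
    return build_aggregated_table(
        [peak_track, expression_track, countless_track], micro_annotation, config
    )
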