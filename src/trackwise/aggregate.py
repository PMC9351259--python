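"""Aggregation of interval tracks to one gene-level matrix.

Each interval of each track is assigned to the closest annotation feature
within a configurable maximum distance (gap 0 on overlap, strand ignored);
the attached values of all intervals landing on the same feature are then
collapsed with a scale-appropriate aggregator.  A track without attached
values contributes a column of assigned-interval counts instead.  The result
is a single table with one row per feature and one column per attached value
column (or count column) of every track.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import (
    AUTO,
    GeneAnnotation,
    NOT_DEFINED,
    Scale,
    ScaleKind,
    Track,
    infer_scale,
    is_defined,
    normalize_chrom,
)
from .track_io import Config, scale_from_spec, scale_to_spec

__all__ = [
    "AggregatedColumnInfo",
    "AggregatedTable",
    "Assignment",
    "aggregate_column",
    "assign_to_features",
    "bin_numeric_to_ordinal",
    "build_aggregated_table",
    "count_intervals",
]

#: Marker for an interval that falls outside the distance cap of every feature.
UNASSIGNED = None

COUNT = "<count>"  # source_column marker for interval-count columns


@dataclass
class Assignment:
    """Interval → feature mapping for one track.

    ``feature_of[i]`` is the feature id the i-th interval was assigned to, or
    None when no feature lies within ``max_distance``.  ``by_feature`` is the
    inverse view restricted to assigned intervals.
    """

    track_id: str
    feature_of: list[str | None]
    by_feature: dict[str, list[int]]

    @property
    def n_assigned(self) -> int:
        return sum(f is not None for f in self.feature_of)


def assign_to_features(
    track: Track, annotation: GeneAnnotation, max_distance: int
) -> Assignment:
    """Assign every interval to the closest feature within ``max_distance``.

    Distance is the gene-body gap: 0 for any overlap, else the number of
    bases strictly between interval and feature; strand is ignored.  Ties on
    the gap are broken by the lowest (chromosome, start, feature id), so the
    outcome is deterministic and independent of input order.
    """
    # per-chromosome feature arrays in tie-break order
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for fid, iv in annotation.entries:
        by_chrom.setdefault(normalize_chrom(iv.chrom), []).append((iv.start, iv.end, fid))
    arrays: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, feats in by_chrom.items():
        feats.sort(key=lambda t: (t[0], t[2]))
        starts = np.array([f[0] for f in feats], dtype=np.int64)
        ends = np.array([f[1] for f in feats], dtype=np.int64)
        ids = [f[2] for f in feats]
        arrays[chrom] = (starts, ends, ids)

    feature_of: list[str | None] = []
    by_feature: dict[str, list[int]] = {}
    for i, iv in enumerate(track.intervals):
        entry = arrays.get(normalize_chrom(iv.chrom))
        if entry is None:
            feature_of.append(UNASSIGNED)
            continue
        starts, ends, ids = entry
        gaps = np.maximum(np.maximum(starts - iv.end, iv.start - ends), 0)
        j = int(np.argmin(gaps))  # first minimum == (start, feature_id) tie-break
        if gaps[j] > max_distance:
            feature_of.append(UNASSIGNED)
            continue
        fid = ids[j]
        feature_of.append(fid)
        by_feature.setdefault(fid, []).append(i)
    return Assignment(track_id=track.id, feature_of=feature_of, by_feature=by_feature)


# ---------------------------------------------------------------------------
# per-scale aggregation

_NUMERIC_AGGREGATORS = ("mean", "median", "max", "min", "sum")
_ORDINAL_AGGREGATORS = ("median", "max", "min", "mode", "concat")
_CATEGORICAL_AGGREGATORS = ("mode", "concat")


def _legal_aggregators(scale: Scale) -> tuple[str, ...]:
    if scale.kind in (ScaleKind.INTERVAL, ScaleKind.RATIONAL):
        return _NUMERIC_AGGREGATORS
    if scale.kind is ScaleKind.ORDINAL:
        return _ORDINAL_AGGREGATORS
    return _CATEGORICAL_AGGREGATORS


def default_aggregator(scale: Scale) -> str:
    """Scale-default combiner: numeric → mean, ordinal → median, nominal/binary → mode."""
    if scale.is_numeric:
        return "mean"
    if scale.kind is ScaleKind.ORDINAL:
        return "median"
    return "mode"


def _mode(values: list, level_order: Sequence[str] | None) -> Any:
    order = list(level_order) if level_order else sorted({str(v) for v in values})
    counts = {lev: 0 for lev in order}
    for v in values:
        counts[str(v)] += 1
    best = max(counts.values())
    for lev in order:  # tie -> first in level order
        if counts[lev] == best:
            return lev
    raise AssertionError("unreachable")


def _lower_median_rank(ranks: list[int]) -> int:
    ranks = sorted(ranks)
    return ranks[(len(ranks) - 1) // 2]


def aggregate_one(values: list, scale: Scale, aggregator: str) -> Any:
    """Collapse the values of one feature group to a single value."""
    if not values:
        return NOT_DEFINED
    if aggregator not in _legal_aggregators(scale):
        raise ValueError(
            f"aggregator {aggregator!r} is not legal for a {scale.kind.value}-scaled "
            f"column (allowed: {_legal_aggregators(scale)})"
        )
    if len(values) == 1 and aggregator != "concat":
        return values[0]
    if scale.is_numeric:
        arr = np.asarray(values, dtype=float)
        return {
            "mean": float(np.mean(arr)),
            "median": float(np.median(arr)),
            "max": float(np.max(arr)),
            "min": float(np.min(arr)),
            "sum": float(np.sum(arr)),
        }[aggregator]
    if aggregator == "concat":
        return ";".join(str(v) for v in values)
    if aggregator == "mode":
        return _mode(values, scale.levels)
    # ordinal order statistics on level ranks, mapped back to levels
    ranks = [scale.rank(v) for v in values]
    if aggregator == "median":
        return scale.levels[_lower_median_rank(ranks)]
    if aggregator == "max":
        return scale.levels[max(ranks)]
    if aggregator == "min":
        return scale.levels[min(ranks)]
    raise ValueError(f"unknown aggregator {aggregator!r}")


def aggregate_column(
    values_per_feature: dict[str, list],
    scale: Scale,
    aggregator: str,
    feature_ids: Sequence[str],
) -> dict[str, Any]:
    """One aggregated value per feature; empty groups become NOT_DEFINED."""
    out: dict[str, Any] = {}
    for fid in feature_ids:
        group = [v for v in values_per_feature.get(fid, []) if is_defined(v)]
        out[fid] = aggregate_one(group, scale, aggregator) if group else NOT_DEFINED
    return out


def count_intervals(assignment: Assignment, feature_ids: Sequence[str]) -> dict[str, int]:
    """Assigned-interval count per feature for a value-less track; 0 is a real zero."""
    return {fid: len(assignment.by_feature.get(fid, ())) for fid in feature_ids}


def bin_numeric_to_ordinal(
    values: Sequence, breaks: Sequence[float], labels: Sequence[str]
) -> list:
    """Bin numeric values into ordered categories.

    Values below the first break take the first label, values above the last
    break the last label; a value equal to a break joins the adjacent middle
    bin (middle bins are closed on both ends, so with breaks (0.2, 0.8) the
    middle category covers 20% to 80% inclusive).  Missing values stay
    missing.
    """
    breaks = list(breaks)
    if any(nxt <= prev for prev, nxt in zip(breaks, breaks[1:])):
        raise ValueError(f"breaks must be strictly increasing, got {breaks}")
    if len(labels) != len(breaks) + 1:
        raise ValueError(f"need {len(breaks) + 1} labels, got {len(labels)}")
    out = []
    for v in values:
        if not is_defined(v):
            out.append(None)
            continue
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ValueError(f"cannot bin non-numeric value {v!r}")
        if v < breaks[0]:
            out.append(labels[0])
        elif v > breaks[-1]:
            out.append(labels[-1])
        else:
            i = next(k for k, b in enumerate(breaks) if v <= b)
            out.append(labels[max(i, 1)])  # v == breaks[0] joins the middle bin
    return out


# ---------------------------------------------------------------------------
# the central table


@dataclass(frozen=True)
class AggregatedColumnInfo:
    """Provenance and typing of one column of the aggregated table."""

    name: str  # "trackid.columnname" or "trackid.count"
    track_id: str
    technology: str
    condition: str
    source_column: str  # original column name, or COUNT
    scale: Scale
    aggregator: str

    @property
    def is_count(self) -> bool:
        return self.source_column == COUNT


@dataclass
class AggregatedTable:
    """Genes × annotated-value-columns matrix, the hub of the whole workflow.

    ``data`` is a pandas DataFrame indexed by feature id; missing cells are
    NaN/None (exposed as NOT_DEFINED through :meth:`cell`).  ``columns``
    carries per-column provenance, scale and the aggregator used.
    """

    feature_ids: list[str]
    columns: list[AggregatedColumnInfo]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        assert list(self.data.index) == list(self.feature_ids)
        assert list(self.data.columns) == [c.name for c in self.columns]

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column_info(self, name: str) -> AggregatedColumnInfo:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(f"no column {name!r} in aggregated table")

    def cell(self, feature_id: str, name: str) -> Any:
        v = self.data.at[feature_id, name]
        return v if is_defined(v) else NOT_DEFINED

    def defined_values(self, name: str) -> list:
        return [v for v in self.data[name] if is_defined(v)]

    def n_defined(self, name: str) -> int:
        return int(self.data[name].notna().sum())

    # -- persistence (TSV matrix + JSON sidecar with column metadata) -------

    def save(self, path: str | Path) -> None:
        from .track_io import write_aggregated_table

        path = Path(path)
        write_aggregated_table(self, path)
        meta = [
            {
                "name": c.name,
                "track_id": c.track_id,
                "technology": c.technology,
                "condition": c.condition,
                "source_column": c.source_column,
                "scale": scale_to_spec(c.scale),
                "aggregator": c.aggregator,
            }
            for c in self.columns
        ]
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AggregatedTable":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        infos = [
            AggregatedColumnInfo(
                name=m["name"],
                track_id=m["track_id"],
                technology=m["technology"],
                condition=m["condition"],
                source_column=m["source_column"],
                scale=scale_from_spec(m["scale"]),
                aggregator=m["aggregator"],
            )
            for m in meta
        ]
        df = pd.read_csv(
            path, sep="\t", index_col=0, keep_default_na=False, na_values=["NA"]
        )
        df.index = df.index.astype(str)
        for info in infos:
            if info.scale.is_numeric or info.is_count:
                df[info.name] = pd.to_numeric(df[info.name], errors="coerce")
            else:
                df[info.name] = df[info.name].astype(object).where(df[info.name].notna(), None)
        return cls(feature_ids=list(df.index), columns=infos, data=df)


def _resolve_aggregator(info_name: str, source_column: str, technology: str,
                        scale: Scale, config: Config) -> str:
    for key in (info_name, source_column, technology):
        if key in config.aggregators:
            return config.aggregators[key]
    return default_aggregator(scale)


def build_aggregated_table(
    tracks: Sequence[Track],
    annotation: GeneAnnotation,
    config: Config | None = None,
) -> AggregatedTable:
    """Assign and collapse every track into the single gene-level table.

    Column order follows (track id, column name); cell values are invariant
    to the order tracks are supplied in.  Columns listed in
    ``config.binning_columns`` are binned to the configured ordered categories
    before aggregation, mirroring the methylation-fraction treatment.
    Aggregators resolve per-column override → per-technology override →
    scale default.
    """
    config = config or Config()
    feature_ids = annotation.feature_ids
    infos: list[AggregatedColumnInfo] = []
    series: dict[str, pd.Series] = {}

    for track in sorted(tracks, key=lambda t: t.id):
        assignment = assign_to_features(track, annotation, config.max_distance)
        if not track.columns:
            counts = count_intervals(assignment, feature_ids)
            name = f"{track.id}.count"
            infos.append(
                AggregatedColumnInfo(
                    name=name,
                    track_id=track.id,
                    technology=track.technology,
                    condition=track.condition,
                    source_column=COUNT,
                    scale=Scale(ScaleKind.INTERVAL),  # zeros are legal counts
                    aggregator="count",
                )
            )
            series[name] = pd.Series(
                [float(counts[fid]) for fid in feature_ids], index=feature_ids, dtype=float
            )
            continue

        for col in sorted(track.columns, key=lambda c: c.name):
            values = col.values
            declared = col.scale
            if col.name in config.binning_columns:
                values = bin_numeric_to_ordinal(
                    values, config.binning_breaks, config.binning_labels
                )
                declared = Scale(ScaleKind.ORDINAL, tuple(config.binning_labels))
            elif col.name in config.ordinal_levels and declared is AUTO:
                declared = Scale(ScaleKind.ORDINAL, tuple(config.ordinal_levels[col.name]))
            from .core import AttachedColumn

            scale = infer_scale(AttachedColumn(col.name, values, declared))
            name = f"{track.id}.{col.name}"
            aggregator = _resolve_aggregator(name, col.name, track.technology, scale, config)
            grouped: dict[str, list] = {}
            for idx, fid in enumerate(assignment.feature_of):
                if fid is not None:
                    grouped.setdefault(fid, []).append(values[idx])
            cells = aggregate_column(grouped, scale, aggregator, feature_ids)
            infos.append(
                AggregatedColumnInfo(
                    name=name,
                    track_id=track.id,
                    technology=track.technology,
                    condition=track.condition,
                    source_column=col.name,
                    scale=scale,
                    aggregator=aggregator,
                )
            )
            if scale.is_numeric:
                series[name] = pd.Series(
                    [
                        float(cells[fid]) if cells[fid] is not NOT_DEFINED else np.nan
                        for fid in feature_ids
                    ],
                    index=feature_ids,
                    dtype=float,
                )
            else:
                series[name] = pd.Series(
                    [cells[fid] if cells[fid] is not NOT_DEFINED else None for fid in feature_ids],
                    index=feature_ids,
                    dtype=object,
                )

    data = pd.DataFrame(series, index=pd.Index(feature_ids, name="feature_id"))
    data = data[[c.name for c in infos]]
    return AggregatedTable(feature_ids=list(feature_ids), columns=infos, data=data)
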