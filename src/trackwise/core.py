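"""Core domain model: intervals, tracks, scales of measurement, and dataset validation.

Every value column attached to a genomic track is classified on one of five
scales of measurement — binary, nominal, ordinal, interval or rational — and
that classification drives which summary statistic, plot and statistical test
is applied downstream.  Coordinates are 0-based half-open throughout the
package (the BED convention); readers convert on the way in.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "AUTO",
    "NOT_DEFINED",
    "AttachedColumn",
    "ConsistencyIssue",
    "ConsistencyReport",
    "DatasetMetadata",
    "GeneAnnotation",
    "GenomicInterval",
    "Scale",
    "ScaleError",
    "ScaleKind",
    "Track",
    "infer_scale",
    "is_defined",
    "normalize_chrom",
    "validate_dataset",
]


class _Sentinel:
    """Unique singleton markers (missing cell, automatic scale)."""

    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name

    def __reduce__(self):  # preserve identity under pickling
        return (_resolve_sentinel, (self._name,))


#: Dataset-wide missing marker, rendered "not-defined" in reports.
NOT_DEFINED = _Sentinel("not-defined")
#: Placeholder meaning "infer the scale from the values".
AUTO = _Sentinel("AUTO")


def _resolve_sentinel(name: str) -> _Sentinel:
    return {"not-defined": NOT_DEFINED, "AUTO": AUTO}[name]


def is_defined(value) -> bool:
    """True if *value* is a real data value (not missing in any encoding)."""
    if value is None or value is NOT_DEFINED:
        return False
    if isinstance(value, float) and math.isnan(value):
        return False
    return True


class ScaleError(ValueError):
    """A value column is inconsistent with its (declared or inferred) scale."""


class ScaleKind(str, enum.Enum):
    BINARY = "binary"
    NOMINAL = "nominal"
    ORDINAL = "ordinal"
    INTERVAL = "interval"
    RATIONAL = "rational"


@dataclass(frozen=True)
class Scale:
    """Scale of measurement of a value column.

    Categorical kinds (binary, nominal, ordinal) carry an explicit tuple of
    level labels; for ordinal columns the tuple order *is* the level order.
    Numeric kinds carry no levels; rational additionally requires every
    defined value to be strictly positive so that the geometric mean exists.
    """

    kind: ScaleKind
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        kind = ScaleKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        if kind is ScaleKind.BINARY:
            if self.levels is None or len(self.levels) != 2:
                raise ScaleError("binary scale requires exactly 2 levels")
        elif kind in (ScaleKind.NOMINAL, ScaleKind.ORDINAL):
            if self.levels is None or len(self.levels) < 2:
                raise ScaleError(f"{kind.value} scale requires >= 2 levels")
        else:
            if self.levels is not None:
                raise ScaleError(f"{kind.value} scale carries no levels")
        if self.levels is not None and len(set(self.levels)) != len(self.levels):
            raise ScaleError("scale levels must be unique")

    @property
    def is_categorical(self) -> bool:
        return self.kind in (ScaleKind.BINARY, ScaleKind.NOMINAL, ScaleKind.ORDINAL)

    @property
    def is_numeric(self) -> bool:
        return self.kind in (ScaleKind.INTERVAL, ScaleKind.RATIONAL)

    def rank(self, value) -> int:
        """Position of a categorical value in the level order."""
        if self.levels is None:
            raise ScaleError(f"{self.kind.value} scale has no levels")
        return self.levels.index(str(value))


_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def gap(self, other: "GenomicInterval") -> int | None:
        """Base pairs strictly between two intervals; 0 on overlap; None across chromosomes."""
        if normalize_chrom(self.chrom) != normalize_chrom(other.chrom):
            return None
        return max(other.start - self.end, self.start - other.end, 0)


@dataclass
class AttachedColumn:
    """One per-interval value column of a track.

    ``values`` aligns 1:1 with the owning track's intervals; ``None`` (or NaN)
    marks a missing value.  ``scale`` is either a concrete :class:`Scale` or
    the AUTO sentinel, resolved by :func:`infer_scale`.
    """

    name: str
    values: list
    scale: Scale | _Sentinel = AUTO

    def defined_values(self) -> list:
        return [v for v in self.values if is_defined(v)]


@dataclass
class Track:
    """One sample: genomic intervals with optional attached value columns."""

    id: str
    technology: str
    condition: str
    intervals: list[GenomicInterval]
    columns: list[AttachedColumn] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("track id must be non-empty")
        if not self.technology or not self.condition:
            raise ValueError(f"track {self.id!r}: technology and condition must be non-empty")

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def sort(self) -> None:
        """Bring intervals (and aligned column values) into canonical order."""
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (
                normalize_chrom(self.intervals[i].chrom),
                self.intervals[i].start,
                self.intervals[i].end,
            ),
        )
        self.intervals = [self.intervals[i] for i in order]
        for col in self.columns:
            col.values = [col.values[i] for i in order]


@dataclass
class GeneAnnotation:
    """Named reference ranges that aggregation targets (genes or custom ranges)."""

    entries: list[tuple[str, GenomicInterval]]
    source: str = "gene-model"  # or "custom-ranges"

    def __post_init__(self) -> None:
        ids = [fid for fid, _ in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids in annotation: {dupes[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return [fid for fid, _ in self.entries]

    def chromosomes(self) -> set[str]:
        return {normalize_chrom(iv.chrom) for _, iv in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DatasetMetadata:
    """Shape of a dataset: how many tracks/value columns, which labels occur."""

    n_tracks: int
    n_value_columns: int
    conditions: set[str]
    technologies: set[str]
    genome_label: str = ""

    @classmethod
    def from_tracks(cls, tracks: Sequence[Track], genome_label: str = "") -> "DatasetMetadata":
        # a value-less track still contributes one count column downstream
        n_cols = sum(max(1, len(t.columns)) for t in tracks)
        return cls(
            n_tracks=len(tracks),
            n_value_columns=n_cols,
            conditions={t.condition for t in tracks},
            technologies={t.technology for t in tracks},
            genome_label=genome_label,
        )


@dataclass(frozen=True)
class ConsistencyIssue:
    severity: str  # "error" | "warning"
    track_id: str
    message: str


@dataclass
class ConsistencyReport:
    issues: list[ConsistencyIssue]

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[ConsistencyIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ConsistencyIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def __str__(self) -> str:
        if not self.issues:
            return "consistency check passed (no issues)"
        lines = [f"consistency check {'passed' if self.passed else 'FAILED'}:"]
        lines += [f"  [{i.severity}] {i.track_id}: {i.message}" for i in self.issues]
        return "\n".join(lines)


def normalize_chrom(name: str) -> str:
    """Canonical chromosome key: strip a leading 'chr' prefix, keep case otherwise."""
    if name.lower().startswith("chr"):
        return name[3:]
    return name


def _is_numeric(value) -> bool:
    return isinstance(value, (int, float)) and not isinstance(value, bool)


def infer_scale(column: AttachedColumn, declared: Scale | _Sentinel | None = None) -> Scale:
    """Resolve the scale of a value column.

    A declared scale is validated against the values and returned unchanged.
    Under AUTO, numeric columns become rational (all defined values > 0) or
    interval; non-numeric columns with exactly two distinct values become
    binary, with more become nominal.  Ordinal is never inferred automatically
    because a level *order* cannot be read off the values — it must be
    declared.
    """
    if declared is None:
        declared = column.scale
    defined = column.defined_values()
    if not defined:
        raise ScaleError(f"empty column: {column.name!r} has no defined values")

    if isinstance(declared, Scale):
        _validate_against(column.name, defined, declared)
        return declared
    if declared is not AUTO:
        raise ScaleError(f"column {column.name!r}: declared scale must be a Scale or AUTO")

    if all(_is_numeric(v) for v in defined):
        if all(v > 0 for v in defined):
            return Scale(ScaleKind.RATIONAL)
        return Scale(ScaleKind.INTERVAL)

    distinct = sorted({str(v) for v in defined})
    if len(distinct) == 2:
        return Scale(ScaleKind.BINARY, tuple(distinct))
    if len(distinct) > 2:
        return Scale(ScaleKind.NOMINAL, tuple(distinct))
    raise ScaleError(
        f"column {column.name!r}: single categorical value {distinct[0]!r}; "
        "cannot infer a scale — declare one"
    )


def _validate_against(name: str, defined: list, scale: Scale) -> None:
    if scale.is_categorical:
        levels = set(scale.levels)  # type: ignore[arg-type]
        for v in defined:
            if str(v) not in levels:
                raise ScaleError(
                    f"column {name!r}: value {v!r} not among declared "
                    f"{scale.kind.value} levels {scale.levels}"
                )
        return
    for v in defined:
        if not _is_numeric(v):
            raise ScaleError(
                f"column {name!r}: non-numeric value {v!r} under {scale.kind.value} scale"
            )
        if scale.kind is ScaleKind.RATIONAL and v <= 0:
            raise ScaleError(
                f"column {name!r}: non-positive value {v!r} under rational scale"
            )


def validate_dataset(
    tracks: Sequence[Track],
    annotation: GeneAnnotation,
    normalize_chrom_names: bool = True,
) -> ConsistencyReport:
    """Formal consistency checks before any aggregation.

    The proxy for "all data belongs to the same reference genome" is
    chromosome-name overlap with the annotation (after optional 'chr' prefix
    normalization).  Nothing is raised here: all findings land in the report
    and the caller decides whether to abort on ``passed == False``.  As a side
    effect each track's intervals are brought into canonical sorted order.
    """
    if not tracks:
        return ConsistencyReport([ConsistencyIssue("error", "<dataset>", "no tracks provided")])
    issues: list[ConsistencyIssue] = []
    if len(annotation) == 0:
        issues.append(ConsistencyIssue("error", "<annotation>", "annotation is empty"))
        return ConsistencyReport(issues)

    norm = normalize_chrom if normalize_chrom_names else (lambda s: s)
    ann_chroms = {norm(iv.chrom) for _, iv in annotation.entries}

    seen_ids: set[str] = set()
    seen_tech_cond: dict[tuple[str, str], str] = {}
    for track in tracks:
        if track.id in seen_ids:
            issues.append(ConsistencyIssue("error", track.id, "duplicate track id"))
        seen_ids.add(track.id)
        key = (track.technology, track.condition)
        if key in seen_tech_cond:
            issues.append(
                ConsistencyIssue(
                    "warning",
                    track.id,
                    f"same technology/condition {key} as track {seen_tech_cond[key]!r} "
                    "(expected for replicates)",
                )
            )
        else:
            seen_tech_cond[key] = track.id

        if not track.intervals:
            issues.append(ConsistencyIssue("error", track.id, "track has no intervals"))
            continue
        for col in track.columns:
            if len(col.values) != len(track.intervals):
                issues.append(
                    ConsistencyIssue(
                        "error",
                        track.id,
                        f"column {col.name!r} has {len(col.values)} values for "
                        f"{len(track.intervals)} intervals",
                    )
                )

        track_chroms = {norm(iv.chrom) for iv in track.intervals}
        if not (track_chroms & ann_chroms):
            issues.append(
                ConsistencyIssue(
                    "error",
                    track.id,
                    "no shared chromosomes with the annotation "
                    f"(track: {sorted(track_chroms)[:4]}, annotation: {sorted(ann_chroms)[:4]})",
                )
            )
        else:
            extra = track_chroms - ann_chroms
            if extra:
                issues.append(
                    ConsistencyIssue(
                        "warning",
                        track.id,
                        f"chromosomes absent from annotation are ignored: {sorted(extra)[:6]}",
                    )
                )
        track.sort()
    return ConsistencyReport(issues)
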