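"""Readers and writers: BED and tabular tracks, gene annotations, JSON config, TSV export.

All on-disk coordinate conventions are converted to the internal 0-based
half-open model at read time.  Every malformed input raises a located
:class:`ParseError`; a reader never returns a partial track.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

from .core import (
    AUTO,
    AttachedColumn,
    GeneAnnotation,
    GenomicInterval,
    Scale,
    ScaleKind,
    Track,
    is_defined,
)

__all__ = [
    "Config",
    "ParseError",
    "TrackSpec",
    "read_config",
    "read_gene_annotation",
    "read_track_bed",
    "read_track_table",
    "scale_from_spec",
    "scale_to_spec",
    "write_aggregated_table",
    "write_config",
]


class ParseError(ValueError):
    """Malformed input file; message carries path and line number."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TrackSpec:
    """Declaration of one input track in the configuration file."""

    path: str
    format: str = "bed"  # bed | tsv | csv
    technology: str = ""
    condition: str = ""
    id: str = ""
    score_as_value: bool = False
    # tabular formats only:
    chrom_column: str = "chrom"
    start_column: str = "start"
    end_column: str = "end"
    coordinates: str = "0-based-half-open"  # or "1-based-closed"
    scales: dict[str, Any] = field(default_factory=dict)  # column -> scale spec

    _KEYS = {
        "path", "format", "technology", "condition", "id", "score_as_value",
        "chrom_column", "start_column", "end_column", "coordinates", "scales",
    }

    def __post_init__(self) -> None:
        if self.format not in ("bed", "tsv", "csv"):
            raise ValueError(f"track format must be bed/tsv/csv, got {self.format!r}")
        if self.coordinates not in ("0-based-half-open", "1-based-closed"):
            raise ValueError(f"unknown coordinate convention {self.coordinates!r}")


_ADJUST_METHODS = ("BH", "bonferroni", "none")
_CORR_METHODS = ("auto", "pearson", "spearman")


@dataclass
class Config:
    """Analysis parameters; every field has the workflow default.

    The defaults mirror the published workflow: a corrected-p significance
    gate of 0.1, three-digit p-value display, and methylation-style binning
    at 20%/80% into low/medium/high.
    """

    max_distance: int = 10_000
    significance_threshold: float = 0.1
    p_round_digits: int = 3
    adjust_method: str = "BH"
    correlation_method: str = "auto"
    aggregators: dict[str, str] = field(default_factory=dict)
    ordinal_levels: dict[str, list[str]] = field(default_factory=dict)
    binning_breaks: list[float] = field(default_factory=lambda: [0.2, 0.8])
    binning_labels: list[str] = field(default_factory=lambda: ["low", "medium", "high"])
    binning_columns: list[str] = field(default_factory=list)
    target_ranges: str = "genes"  # "genes" or path to a named BED of custom ranges
    annotation: str = ""
    annotation_format: str = "bed"  # bed | gtf | gff3
    feature_filter: str = "gene"
    seed: int = 0
    groups: dict[str, list[str]] = field(default_factory=dict)
    tracks: list[TrackSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.significance_threshold < 1):
            raise ValueError(
                f"significance_threshold must lie in (0, 1), got {self.significance_threshold}"
            )
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.p_round_digits < 0:
            raise ValueError("p_round_digits must be >= 0")
        if self.adjust_method not in _ADJUST_METHODS:
            raise ValueError(f"adjust_method must be one of {_ADJUST_METHODS}")
        if self.correlation_method not in _CORR_METHODS:
            raise ValueError(f"correlation_method must be one of {_CORR_METHODS}")
        breaks = list(self.binning_breaks)
        if any(nxt <= prev for prev, nxt in zip(breaks, breaks[1:])):
            raise ValueError(f"binning breaks must be strictly increasing, got {breaks}")
        if len(self.binning_labels) != len(breaks) + 1:
            raise ValueError(
                f"need {len(breaks) + 1} binning labels for {len(breaks)} breaks, "
                f"got {len(self.binning_labels)}"
            )
        self.tracks = [t if isinstance(t, TrackSpec) else TrackSpec(**t) for t in self.tracks]


_CONFIG_KEYS = {f for f in Config.__dataclass_fields__}  # noqa: C416


def read_config(path: str | Path) -> Config:
    """Load and validate a JSON configuration; unknown keys are rejected."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON: {exc}") from None
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a JSON object")
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        raise ParseError(f"{path}: unknown configuration keys: {unknown}")
    tracks = raw.pop("tracks", [])
    parsed_tracks = []
    for i, t in enumerate(tracks):
        bad = sorted(set(t) - TrackSpec._KEYS)
        if bad:
            raise ParseError(f"{path}: tracks[{i}]: unknown keys: {bad}")
        parsed_tracks.append(TrackSpec(**t))
    try:
        return Config(tracks=parsed_tracks, **raw)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_config(config: Config, path: str | Path) -> None:
    data = asdict(config)
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# scale (de)serialisation used by config files and fixtures


def scale_from_spec(spec) -> Scale | Any:
    """Parse a JSON-friendly scale spec.

    Accepts "auto", a kind name ("rational", "interval"), or a one-key
    mapping {"ordinal": [levels...]} / {"binary": [...]} / {"nominal": [...]}.
    """
    if spec is None or spec == "auto" or spec is AUTO:
        return AUTO
    if isinstance(spec, Scale):
        return spec
    if isinstance(spec, str):
        return Scale(ScaleKind(spec))
    if isinstance(spec, dict) and len(spec) == 1:
        (kind, levels), = spec.items()
        return Scale(ScaleKind(kind), tuple(levels))
    raise ValueError(f"cannot parse scale spec {spec!r}")


def scale_to_spec(scale: Scale | Any):
    if scale is AUTO:
        return "auto"
    if scale.levels is None:
        return scale.kind.value
    return {scale.kind.value: list(scale.levels)}


# ---------------------------------------------------------------------------
# track readers


def _parse_coord(token: str, path: Path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate {token!r}") from None


def _coerce(token: str):
    """Numeric if it looks numeric, else the bare string; '' / NA / . are missing."""
    if token in ("", ".", "NA", "na", "NaN", "nan", "not-defined"):
        return None
    try:
        f = float(token)
    except ValueError:
        return token
    if math.isnan(f):
        return None
    if f.is_integer() and "." not in token and "e" not in token.lower():
        return int(f)
    return f


def read_track_bed(
    path: str | Path,
    technology: str,
    condition: str,
    score_as_value: bool = False,
    track_id: str | None = None,
) -> Track:
    """Read a BED3+ file as one track.

    Field 5 (score) becomes an attached column named "score" only when
    ``score_as_value`` is set — BED scores are frequently placeholders.
    Field 6 populates the interval strand; fields 7+ become AUTO-scaled
    attached columns named after their 1-based field number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    scores: list = []
    extras: dict[int, list] = {}
    n_fields: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            if n_fields is None:
                n_fields = len(fields)
            elif len(fields) != n_fields:
                raise ParseError(
                    f"{path}:{lineno}: inconsistent field count "
                    f"({len(fields)} vs {n_fields})"
                )
            start = _parse_coord(fields[1], path, lineno)
            end = _parse_coord(fields[2], path, lineno)
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: interval start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if len(fields) >= 5:
                scores.append(_coerce(fields[4]))
            for i in range(6, len(fields)):
                extras.setdefault(i, []).append(_coerce(fields[i]))

    columns: list[AttachedColumn] = []
    if score_as_value and scores:
        columns.append(AttachedColumn("score", scores))
    for i in sorted(extras):
        columns.append(AttachedColumn(f"field{i + 1}", extras[i]))
    return Track(
        id=track_id or path.stem,
        technology=technology,
        condition=condition,
        intervals=intervals,
        columns=columns,
    )


def read_track_table(
    path: str | Path,
    dialect: str,
    technology: str,
    condition: str,
    chrom_column: str = "chrom",
    start_column: str = "start",
    end_column: str = "end",
    coordinates: str = "0-based-half-open",
    scales: dict[str, Any] | None = None,
    track_id: str | None = None,
) -> Track:
    """Read a TSV/CSV table with a header row as one track.

    Columns other than the three coordinate columns become attached value
    columns, with a declared scale from ``scales`` (a mapping column name →
    scale spec) or AUTO.  1-based closed coordinates are converted by
    decrementing the start.
    """
    path = Path(path)
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be tsv or csv, got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    scales = scales or {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        for mandatory in (chrom_column, start_column, end_column):
            if mandatory not in header:
                raise ParseError(f"{path}: missing mandatory column {mandatory!r}")
        idx = {name: header.index(name) for name in header}
        value_names = [
            h for h in header if h not in (chrom_column, start_column, end_column)
        ]
        intervals: list[GenomicInterval] = []
        values: dict[str, list] = {name: [] for name in value_names}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f for f in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            start = _parse_coord(row[idx[start_column]], path, lineno)
            end = _parse_coord(row[idx[end_column]], path, lineno)
            if coordinates == "1-based-closed":
                start -= 1  # closed end equals half-open end
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            intervals.append(GenomicInterval(row[idx[chrom_column]], start, end))
            for name in value_names:
                values[name].append(_coerce(row[idx[name]]))

    columns = [
        AttachedColumn(name, values[name], scale_from_spec(scales.get(name)))
        for name in value_names
    ]
    return Track(
        id=track_id or path.stem,
        technology=technology,
        condition=condition,
        intervals=intervals,
        columns=columns,
    )


def read_track(spec: TrackSpec) -> Track:
    """Dispatch on a TrackSpec from the configuration file."""
    if spec.format == "bed":
        return read_track_bed(
            spec.path,
            technology=spec.technology,
            condition=spec.condition,
            score_as_value=spec.score_as_value,
            track_id=spec.id or None,
        )
    return read_track_table(
        spec.path,
        dialect=spec.format,
        technology=spec.technology,
        condition=spec.condition,
        chrom_column=spec.chrom_column,
        start_column=spec.start_column,
        end_column=spec.end_column,
        coordinates=spec.coordinates,
        scales=spec.scales,
        track_id=spec.id or None,
    )


# ---------------------------------------------------------------------------
# gene annotation


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    # tolerate both GTF `key "value";` and GFF3 `key=value` dialects
    attrs: dict[str, str] = {}
    sep = "=" if ("=" in text and '"' not in text) else " "
    for part in text.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(sep)
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


def read_gene_annotation(
    path: str | Path,
    format: str | None = None,
    feature_filter: str = "gene",
) -> GeneAnnotation:
    """Read gene (or custom range) locations from GTF/GFF3 or named BED.

    GTF/GFF rows are filtered to ``feature_filter`` (third field) and keyed by
    their gene_id/ID attribute; BED rows are keyed by the name field.  GTF is
    1-based closed and converted on read.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"gtf": "gtf", "gff": "gff3", "gff3": "gff3", "bed": "bed"}.get(suffix, "bed")
    entries: list[tuple[str, GenomicInterval]] = []
    seen: set[str] = set()

    def add(fid: str, iv: GenomicInterval, lineno: int) -> None:
        if fid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate feature id {fid!r}")
        seen.add(fid)
        entries.append((fid, iv))

    with path.open() as fh:
        if format in ("gtf", "gff3"):
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GTF/GFF fields")
                if fields[2] != feature_filter:
                    continue
                start = _parse_coord(fields[3], path, lineno) - 1  # 1-based closed
                end = _parse_coord(fields[4], path, lineno)
                strand = fields[6] if fields[6] in ("+", "-") else "."
                attrs = _parse_gtf_attributes(fields[8])
                fid = attrs.get("gene_id") or attrs.get("ID") or attrs.get("Name")
                if not fid:
                    raise ParseError(f"{path}:{lineno}: no gene_id/ID attribute")
                try:
                    add(fid, GenomicInterval(fields[0], start, end, strand), lineno)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
        else:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track ", "browser ")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(
                        f"{path}:{lineno}: annotation BED requires a name field (>= 4 columns)"
                    )
                start = _parse_coord(fields[1], path, lineno)
                end = _parse_coord(fields[2], path, lineno)
                strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
                try:
                    add(fields[3], GenomicInterval(fields[0], start, end, strand), lineno)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None

    if not entries:
        raise ParseError(f"{path}: no features left after filtering for {feature_filter!r}")
    source = "gene-model" if format in ("gtf", "gff3") else "custom-ranges"
    return GeneAnnotation(entries=entries, source=source)


# ---------------------------------------------------------------------------
# aggregated table export


def write_aggregated_table(table, path: str | Path) -> None:
    """Write the genes × columns matrix as TSV.

    First column is the feature id; headers are "trackid.columnname"; missing
    cells are the literal "NA"; numerics are printed to 12 significant digits.
    """
    path = Path(path)
    names = [c.name for c in table.columns]
    with path.open("w") as fh:
        fh.write("\t".join(["feature_id"] + names) + "\n")
        for fid in table.feature_ids:
            row = [fid]
            for name in names:
                v = table.data.at[fid, name]
                if not is_defined(v):
                    row.append("NA")
                elif isinstance(v, float):
                    row.append(f"{v:.12g}")
                else:
                    row.append(str(v))
            fh.write("\t".join(row) + "\n")
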