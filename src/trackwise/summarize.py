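"""Scale-appropriate location/dispersion statistics and plot-kind selection.

The statistic and visualization for every column follow directly from its
scale of measurement:

==========  ====================  ==========================  ================
scale       location              dispersion                  visualization
==========  ====================  ==========================  ================
binary      most frequent value   both values present?        barplot
nominal     most frequent value   number of present values    barplot
ordinal     median (on ranks)     quantile levels 25/50/75%   ordered barplot
interval    arithmetic mean       standard deviation (n-1)    boxplot
rational    geometric mean        coefficient of variation    boxplot
==========  ====================  ==========================  ================

Group views collapse the columns of tracks sharing base technology (and
optionally condition) into one combined plot, e.g. side-by-side boxplots
colored by condition, to surface replicate agreement, batch effects or
knock-out shifts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .core import NOT_DEFINED, Scale, ScaleKind
from .aggregate import AggregatedTable
from .track_io import Config

__all__ = [
    "ColumnSummary",
    "GroupSpec",
    "GroupSummary",
    "PlotSpec",
    "build_groups",
    "dispersion",
    "location",
    "plot_kind_for_scale",
    "summarize_column",
    "summarize_group",
]

ORDINAL_QUANTILES = (0.25, 0.5, 0.75)


def _most_frequent(values: Sequence, levels: Sequence[str]) -> str:
    counts = Counter(str(v) for v in values)
    best = max(counts.values())
    for lev in levels:  # tie -> first in declared level order
        if counts.get(lev, 0) == best:
            return lev
    raise AssertionError("value outside declared levels")


def location(values: Sequence, scale: Scale) -> Any:
    """Location parameter appropriate for the scale.

    Binary/nominal: most frequent value.  Ordinal: median on level ranks
    (lower median for even n — always a real level).  Interval: arithmetic
    mean.  Rational: geometric mean, computed as exp(mean(log v)) for
    overflow safety.
    """
    values = list(values)
    if not values:
        raise ValueError("location of an empty value set")
    kind = scale.kind
    if kind in (ScaleKind.BINARY, ScaleKind.NOMINAL):
        return _most_frequent(values, scale.levels)  # type: ignore[arg-type]
    if kind is ScaleKind.ORDINAL:
        ranks = sorted(scale.rank(v) for v in values)
        return scale.levels[ranks[(len(ranks) - 1) // 2]]  # type: ignore[index]
    arr = np.asarray(values, dtype=float)
    if kind is ScaleKind.INTERVAL:
        return float(np.mean(arr))
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _ordinal_quantile_levels(values: Sequence, scale: Scale) -> tuple[str, ...]:
    # type-1 (inverse empirical CDF) quantiles on ranks, mapped back to levels
    ranks = sorted(scale.rank(v) for v in values)
    n = len(ranks)
    out = []
    for q in ORDINAL_QUANTILES:
        k = max(int(math.ceil(q * n)), 1) - 1
        out.append(scale.levels[ranks[k]])  # type: ignore[index]
    return tuple(out)


def dispersion(values: Sequence, scale: Scale) -> Any:
    """Dispersion parameter appropriate for the scale.

    Binary: are both levels present?  Nominal: number of distinct present
    values.  Ordinal: the quantile levels at 25/50/75%.  Interval: sample
    standard deviation.  Rational: coefficient of variation sd/mean.  A
    single numeric value has no dispersion and yields NOT_DEFINED.
    """
    values = list(values)
    if not values:
        raise ValueError("dispersion of an empty value set")
    kind = scale.kind
    if kind is ScaleKind.BINARY:
        return len({str(v) for v in values}) == 2
    if kind is ScaleKind.NOMINAL:
        return len({str(v) for v in values})
    if kind is ScaleKind.ORDINAL:
        return _ordinal_quantile_levels(values, scale)
    if len(values) < 2:
        return NOT_DEFINED
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1))
    if kind is ScaleKind.INTERVAL:
        return sd
    return sd / float(np.mean(arr))


def plot_kind_for_scale(scale: Scale) -> str:
    if scale.kind in (ScaleKind.BINARY, ScaleKind.NOMINAL):
        return "barplot"
    if scale.kind is ScaleKind.ORDINAL:
        return "ordered_barplot"
    return "boxplot"


@dataclass
class PlotSpec:
    """Abstract figure description; rendering happens in the report stage."""

    kind: str
    title: str
    series: dict[str, Any] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)


@dataclass
class ColumnSummary:
    column: str
    scale: Scale
    location: Any  # None when the column is entirely missing
    dispersion: Any
    n_defined: int
    n_missing: int
    plot_kind: str

    def plot_spec(self, table: AggregatedTable) -> PlotSpec:
        info = table.column_info(self.column)
        values = table.defined_values(self.column)
        if self.scale.is_categorical:
            counts = Counter(str(v) for v in values)
            return PlotSpec(
                kind=self.plot_kind,
                title=self.column,
                series={"levels": list(self.scale.levels), "counts": [counts.get(l, 0) for l in self.scale.levels]},  # type: ignore[union-attr]
                labels={"x": info.source_column, "y": "number of features"},
            )
        return PlotSpec(
            kind="boxplot",
            title=self.column,
            series={"groups": {self.column: [float(v) for v in values]}},
            labels={"y": info.source_column},
        )


def summarize_column(table: AggregatedTable, column: str) -> ColumnSummary:
    """Location, dispersion and plot kind for one column of the table."""
    info = table.column_info(column)
    values = table.defined_values(column)
    n_defined = len(values)
    n_missing = table.n_features - n_defined
    if n_defined == 0:
        return ColumnSummary(
            column=column,
            scale=info.scale,
            location=None,
            dispersion=None,
            n_defined=0,
            n_missing=n_missing,
            plot_kind=plot_kind_for_scale(info.scale),
        )
    return ColumnSummary(
        column=column,
        scale=info.scale,
        location=location(values, info.scale),
        dispersion=dispersion(values, info.scale),
        n_defined=n_defined,
        n_missing=n_missing,
        plot_kind=plot_kind_for_scale(info.scale),
    )


# ---------------------------------------------------------------------------
# groups


@dataclass
class GroupSpec:
    name: str
    kind: str  # tech_and_condition | technology | user
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")


@dataclass
class GroupSummary:
    group: GroupSpec
    member_summaries: list[ColumnSummary]
    plot: PlotSpec


def build_groups(table: AggregatedTable, config: Config | None = None) -> list[GroupSpec]:
    """Automatic groups plus user-defined ones.

    One group per observed (technology, condition) pair with at least two
    member columns (replicate views), one group per technology spanning all
    its conditions, and the user groups from the configuration verbatim.
    """
    config = config or Config()
    by_tc: dict[tuple[str, str], list[str]] = {}
    by_tech: dict[str, list[str]] = {}
    for c in table.columns:
        by_tc.setdefault((c.technology, c.condition), []).append(c.name)
        by_tech.setdefault(c.technology, []).append(c.name)

    groups: list[GroupSpec] = []
    for (tech, cond) in sorted(by_tc):
        members = by_tc[(tech, cond)]
        if len(members) >= 2:
            groups.append(GroupSpec(f"{tech} / {cond}", "tech_and_condition", members))
    for tech in sorted(by_tech):
        groups.append(GroupSpec(tech, "technology", by_tech[tech]))
    known = {c.name for c in table.columns}
    for name in sorted(config.groups):
        members = config.groups[name]
        missing = [m for m in members if m not in known]
        if missing:
            raise ValueError(f"user group {name!r} names unknown columns: {missing}")
        groups.append(GroupSpec(name, "user", list(members)))
    return groups


def summarize_group(table: AggregatedTable, group: GroupSpec) -> GroupSummary:
    """Member summaries plus one combined plot spec for the group.

    All members must belong to one scale family: numeric members yield
    side-by-side boxplots colored by condition, categorical members a grouped
    barplot of level frequencies per member.  Mixing families in one group is
    an error.
    """
    infos = [table.column_info(m) for m in group.members]
    numeric = [i.scale.is_numeric for i in infos]
    if any(numeric) and not all(numeric):
        raise ValueError(
            f"group {group.name!r} mixes categorical and numeric columns; "
            "group members must share a scale family"
        )
    summaries = [summarize_column(table, m) for m in group.members]
    if all(numeric):
        plot = PlotSpec(
            kind="grouped_boxplot",
            title=group.name,
            series={
                "groups": {m: [float(v) for v in table.defined_values(m)] for m in group.members},
                "conditions": {i.name: i.condition for i in infos},
            },
            labels={"y": "value"},
        )
    else:
        # union of levels, in first-seen declared order
        levels: list[str] = []
        for i in infos:
            for lev in i.scale.levels:  # type: ignore[union-attr]
                if lev not in levels:
                    levels.append(lev)
        freqs = {}
        for m in group.members:
            counts = Counter(str(v) for v in table.defined_values(m))
            freqs[m] = [counts.get(l, 0) for l in levels]
        plot = PlotSpec(
            kind="grouped_barplot",
            title=group.name,
            series={
                "levels": levels,
                "frequencies": freqs,
                "conditions": {i.name: i.condition for i in infos},
            },
            labels={"y": "number of features"},
        )
    return GroupSummary(group=group, member_summaries=summaries, plot=plot)
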