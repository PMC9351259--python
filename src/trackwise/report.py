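"""Report assembly and rendering.

The whole analysis is folded into one ordered document: dataset overview,
per-column summaries (one figure each), replicate/group views, per-technology
views, the full pairwise test table with figures for significant pairs, and
a closing association heatmap over all columns.  The document model is
rendered to Markdown (always) and optionally HTML with co-located PNG
figures; rendering never mutates upstream results.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__ as _version
from .core import NOT_DEFINED
from .aggregate import AggregatedTable
from .compare import ComparisonMatrix, format_pvalue, pair_plot_spec
from .summarize import ColumnSummary, GroupSummary, PlotSpec
from .track_io import Config

__all__ = [
    "OverviewHeatmap",
    "ReportDocument",
    "Section",
    "build_report",
    "overview_heatmap",
    "render",
    "render_plot_spec",
    "validate_report",
]


def slugify(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", text.lower()).strip("_")


# ---------------------------------------------------------------------------
# document model


@dataclass
class TextBlock:
    text: str


@dataclass
class TableBlock:
    headers: list[str]
    rows: list[list[str]]
    caption: str = ""


@dataclass
class FigureBlock:
    spec: PlotSpec
    slug: str
    caption: str = ""
    path: str | None = None  # filled in by render()


@dataclass
class Section:
    id: str
    title: str
    blocks: list = field(default_factory=list)

    def figures(self) -> list[FigureBlock]:
        return [b for b in self.blocks if isinstance(b, FigureBlock)]


@dataclass
class ReportDocument:
    sections: list[Section]
    metadata: dict[str, Any] = field(default_factory=dict)

    def section(self, sid: str) -> Section:
        for s in self.sections:
            if s.id == sid:
                return s
        raise KeyError(sid)


# ---------------------------------------------------------------------------
# overview heatmap


@dataclass
class OverviewHeatmap:
    """Square association matrix over all columns.

    Correlation-tested pairs carry the signed coefficient in [-1, 1]; for
    every other test kind the cell holds 1 - adjusted p in [0, 1] (unsigned
    association strength).  Skipped pairs are blank (NaN); the diagonal is the
    maximal association 1.  Cells are annotated with the formatted adjusted p.
    """

    columns: list[str]
    values: np.ndarray
    annotations: list[list[str]]


def overview_heatmap(matrix: ComparisonMatrix, p_round_digits: int = 3) -> OverviewHeatmap:
    cols = list(matrix.column_names)
    n = len(cols)
    values = np.full((n, n), np.nan)
    annotations = [["" for _ in cols] for _ in cols]
    np.fill_diagonal(values, 1.0)
    for i in range(n):
        annotations[i][i] = ""
    for i in range(n):
        for j in range(i + 1, n):
            r = matrix.get(cols[i], cols[j])
            if r.skipped:
                continue
            if r.test.startswith("correlation"):
                cell = float(r.statistic)
            else:
                cell = 1.0 - float(r.p_adjusted)
            values[i, j] = values[j, i] = cell
            note = format_pvalue(r.p_adjusted, p_round_digits)
            annotations[i][j] = annotations[j][i] = note
    return OverviewHeatmap(columns=cols, values=values, annotations=annotations)


# ---------------------------------------------------------------------------
# assembly


def _fmt(value, digits: int = 4) -> str:
    if value is None or value is NOT_DEFINED:
        return "not-defined"
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return f"{value:.{digits}g}"
    if isinstance(value, tuple):
        return "/".join(str(v) for v in value)
    return str(value)


def _summary_row(s: ColumnSummary) -> list[str]:
    return [
        s.column,
        s.scale.kind.value,
        _fmt(s.location),
        _fmt(s.dispersion),
        str(s.n_defined),
        str(s.n_missing),
        s.plot_kind,
    ]


def build_report(
    table: AggregatedTable,
    summaries: list[ColumnSummary],
    groups: list[GroupSummary],
    matrix: ComparisonMatrix,
    config: Config | None = None,
) -> ReportDocument:
    """Assemble the six report sections in their fixed order.

    Section 2 contains every aggregated column exactly once (columns ordered
    by track then column name); section 5 tabulates every non-skipped pair
    and carries a figure only for the significant ones.
    """
    config = config or Config()
    digits = config.p_round_digits

    # 1 -- dataset overview
    overview = Section("overview", "Dataset overview")
    track_rows: dict[str, list[str]] = {}
    for c in table.columns:
        row = track_rows.setdefault(c.track_id, [c.track_id, c.technology, c.condition, "0"])
        row[3] = str(int(row[3]) + 1)
    overview.blocks.append(
        TableBlock(
            headers=["track", "technology", "condition", "columns"],
            rows=[track_rows[k] for k in sorted(track_rows)],
            caption="Input tracks and their aggregated columns",
        )
    )
    tech_cond = Counter((c.technology, c.condition) for c in table.columns)
    techs = sorted({t for t, _ in tech_cond})
    conds = sorted({c for _, c in tech_cond})
    overview.blocks.append(
        TableBlock(
            headers=["condition"] + techs,
            rows=[[cond] + [str(tech_cond.get((t, cond), 0)) for t in techs] for cond in conds],
            caption="Columns per condition and base technology",
        )
    )
    overview.blocks.append(
        TextBlock(
            f"{table.n_features} features x {table.n_columns} aggregated columns; "
            f"{matrix.n_significant} of {len(matrix.results)} pairwise comparisons "
            f"significant at adjusted p <= {config.significance_threshold}."
        )
    )

    # 2 -- per-column summaries
    col_order = [c.name for c in sorted(table.columns, key=lambda c: (c.track_id, c.name))]
    by_name = {s.column: s for s in summaries}
    columns_sec = Section("columns", "Per-column summaries")
    columns_sec.blocks.append(
        TableBlock(
            headers=["column", "scale", "location", "dispersion", "defined", "missing", "plot"],
            rows=[_summary_row(by_name[n]) for n in col_order],
            caption="Scale-appropriate location and dispersion per column",
        )
    )
    for name in col_order:
        s = by_name[name]
        if s.n_defined == 0:
            columns_sec.blocks.append(TextBlock(f"{name}: all values not-defined; no figure."))
            continue
        columns_sec.blocks.append(
            FigureBlock(spec=s.plot_spec(table), slug=f"column__{slugify(name)}",
                        caption=f"{name} ({s.scale.kind.value}, {s.plot_kind})")
        )

    # 3 -- replicate / user groups
    groups_sec = Section("groups", "Group summaries (technology and condition)")
    tc_groups = [g for g in groups if g.group.kind in ("tech_and_condition", "user")]
    if not tc_groups:
        groups_sec.blocks.append(TextBlock("No replicate or user-defined groups."))
    for g in tc_groups:
        groups_sec.blocks.append(
            FigureBlock(spec=g.plot, slug=f"group__{slugify(g.group.name)}",
                        caption=f"{g.group.name} ({len(g.group.members)} columns)")
        )

    # 4 -- per-technology groups
    tech_sec = Section("technologies", "Per-technology summaries")
    for g in [g for g in groups if g.group.kind == "technology"]:
        tech_sec.blocks.append(
            FigureBlock(spec=g.plot, slug=f"technology__{slugify(g.group.name)}",
                        caption=f"{g.group.name} across conditions")
        )

    # 5 -- pairwise comparisons
    pair_sec = Section("pairwise", "Pairwise comparisons")
    tested = [r for r in matrix.results if not r.skipped]
    rows = []
    for r in sorted(matrix.results, key=lambda r: (r.col_a, r.col_b)):
        rows.append(
            [
                r.col_a,
                r.col_b,
                r.test if not r.skipped else "skipped",
                _fmt(r.statistic),
                format_pvalue(r.p_raw, digits) if r.p_raw is not None else "",
                format_pvalue(r.p_adjusted, digits) if r.p_adjusted is not None else "",
                str(r.n_used),
                "yes" if r.significant else "no",
                r.skipped_reason or "",
            ]
        )
    pair_sec.blocks.append(
        TableBlock(
            headers=["column a", "column b", "test", "statistic", "p", "adjusted p",
                     "n", "significant", "note"],
            rows=rows,
            caption=f"All {len(matrix.results)} pairwise tests "
                    f"({len(tested)} performed, {matrix.n_skipped} skipped)",
        )
    )
    if not tested:
        pair_sec.blocks.append(
            TextBlock("No pair admitted a meaningful test; no comparison figures.")
        )
    for r in sorted(tested, key=lambda r: (r.col_a, r.col_b)):
        if not r.significant:
            continue
        pair_sec.blocks.append(
            FigureBlock(
                spec=pair_plot_spec(r, table),
                slug=f"pair__{slugify(r.col_a)}__{slugify(r.col_b)}",
                caption=(
                    f"{r.col_a} vs {r.col_b}: {r.test}, adjusted p = "
                    f"{format_pvalue(r.p_adjusted, digits)}"
                ),
            )
        )

    # 6 -- overview heatmap
    heat = overview_heatmap(matrix, digits)
    heat_sec = Section("heatmap", "Association overview heatmap")
    heat_sec.blocks.append(
        TextBlock(
            "Cell encoding: signed correlation coefficient for numeric-numeric "
            "pairs; 1 - adjusted p for all other test kinds; blank where the "
            "comparison was skipped. Cells are annotated with the adjusted p."
        )
    )
    heat_sec.blocks.append(
        FigureBlock(
            spec=PlotSpec(
                kind="overview_heatmap",
                title="Pairwise association overview",
                series={
                    "columns": heat.columns,
                    "values": heat.values.tolist(),
                    "annotations": heat.annotations,
                },
            ),
            slug="overview_heatmap",
            caption="Association strength across all column pairs",
        )
    )

    metadata = {
        "tool": "trackwise",
        "version": _version,
        "generated": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "config": {
            "max_distance": config.max_distance,
            "significance_threshold": config.significance_threshold,
            "adjust_method": config.adjust_method,
            "p_round_digits": config.p_round_digits,
            "seed": config.seed,
        },
    }
    return ReportDocument(
        sections=[overview, columns_sec, groups_sec, tech_sec, pair_sec, heat_sec],
        metadata=metadata,
    )


def validate_report(doc: ReportDocument, table: AggregatedTable,
                    matrix: ComparisonMatrix) -> None:
    """Assert the structural invariants of a built report document."""
    col_slugs = [f.slug for f in doc.section("columns").figures()]
    expected = []
    by_name = {c.name: c for c in table.columns}
    for name in sorted(by_name, key=lambda n: (by_name[n].track_id, n)):
        if any(b for b in doc.section("columns").blocks
               if isinstance(b, TextBlock) and b.text.startswith(f"{name}:")):
            continue  # all-missing column, noted in text instead of a figure
        expected.append(f"column__{slugify(name)}")
    if col_slugs != expected:
        raise AssertionError("section 2 must show every aggregated column exactly once")

    pair_table = next(
        b for b in doc.section("pairwise").blocks if isinstance(b, TableBlock)
    )
    if len(pair_table.rows) != len(matrix.results):
        raise AssertionError("section 5 table must list every pair")
    n_sig = sum(r.significant for r in matrix.results)
    if len(doc.section("pairwise").figures()) != n_sig:
        raise AssertionError("section 5 figures must match the significant pairs")


# ---------------------------------------------------------------------------
# figure rendering


def _condition_colors(conditions: dict[str, str]) -> dict[str, Any]:
    uniq = sorted(set(conditions.values()))
    cmap = plt.get_cmap("tab10")
    return {cond: cmap(i % 10) for i, cond in enumerate(uniq)}


def render_plot_spec(spec: PlotSpec, path: Path) -> None:
    """Materialise one abstract plot spec as a PNG."""
    fig, ax = plt.subplots(figsize=(6.0, 4.0))
    kind = spec.kind
    s = spec.series
    try:
        if kind in ("barplot", "ordered_barplot"):
            ax.bar(range(len(s["levels"])), s["counts"], color="#4878a8")
            ax.set_xticks(range(len(s["levels"])), s["levels"])
        elif kind == "boxplot":
            groups = s["groups"]
            ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()))
            ax.tick_params(axis="x", rotation=30)
        elif kind == "grouped_boxplot":
            groups = s["groups"]
            colors = _condition_colors(s.get("conditions", {}))
            box = ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()),
                             patch_artist=True)
            for patch, name in zip(box["boxes"], groups.keys()):
                cond = s.get("conditions", {}).get(name)
                patch.set_facecolor(colors.get(cond, "#4878a8"))
            ax.tick_params(axis="x", rotation=60)
        elif kind == "grouped_barplot":
            levels = s["levels"]
            freqs = s["frequencies"]
            members = list(freqs.keys())
            width = 0.8 / max(len(members), 1)
            colors = _condition_colors(s.get("conditions", {}))
            for mi, m in enumerate(members):
                xs = [i + mi * width for i in range(len(levels))]
                cond = s.get("conditions", {}).get(m)
                ax.bar(xs, freqs[m], width=width, label=m,
                       color=colors.get(cond, None))
            ax.set_xticks([i + 0.4 for i in range(len(levels))], levels)
            if len(members) <= 12:
                ax.legend(fontsize=6)
        elif kind == "scatter":
            ax.plot(s["x"], s["y"], ".", markersize=3, alpha=0.5, color="#4878a8")
        elif kind == "boxplot_by_level":
            groups = s["groups"]
            ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()))
        elif kind == "count_heatmap":
            counts = np.asarray(s["counts"], dtype=float)
            im = ax.imshow(counts, cmap="viridis", aspect="auto")
            ax.set_xticks(range(len(s["cols"])), s["cols"])
            ax.set_yticks(range(len(s["rows"])), s["rows"])
            for i in range(counts.shape[0]):
                for j in range(counts.shape[1]):
                    ax.text(j, i, f"{int(counts[i, j])}", ha="center", va="center",
                            color="white", fontsize=8)
            fig.colorbar(im, ax=ax, label="number of features")
        elif kind == "overview_heatmap":
            values = np.asarray(s["values"], dtype=float)
            masked = np.ma.masked_invalid(values)
            cmap = plt.get_cmap("RdBu_r").copy()
            cmap.set_bad("#dddddd")
            im = ax.imshow(masked, cmap=cmap, vmin=-1, vmax=1)
            cols = s["columns"]
            ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
            ax.set_yticks(range(len(cols)), cols, fontsize=6)
            if len(cols) <= 15:
                for i in range(len(cols)):
                    for j in range(len(cols)):
                        note = s["annotations"][i][j]
                        if note:
                            ax.text(j, i, note, ha="center", va="center", fontsize=5)
            fig.colorbar(im, ax=ax, label="association")
        else:
            raise ValueError(f"unknown plot kind {kind!r}")
        ax.set_title(spec.title, fontsize=9)
        if "x" in spec.labels:
            ax.set_xlabel(spec.labels["x"], fontsize=8)
        if "y" in spec.labels:
            ax.set_ylabel(spec.labels["y"], fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=100)
    finally:
        plt.close(fig)


# ---------------------------------------------------------------------------
# writers


def _md_table(block: TableBlock) -> str:
    lines = []
    if block.caption:
        lines.append(f"*{block.caption}*\n")
    lines.append("| " + " | ".join(block.headers) + " |")
    lines.append("|" + "|".join([" --- "] * len(block.headers)) + "|")
    for row in block.rows:
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines)


def _render_markdown(doc: ReportDocument) -> str:
    md = ["# Track overview report", ""]
    meta = doc.metadata
    md.append(f"Tool: {meta.get('tool', '')} {meta.get('version', '')}")
    md.append(f"Generated: {meta.get('generated', '')}")
    cfg = meta.get("config", {})
    if cfg:
        md.append("Settings: " + ", ".join(f"{k}={v}" for k, v in sorted(cfg.items())))
    md.append("")
    for sec in doc.sections:
        md.append(f"## {sec.title}")
        md.append("")
        for block in sec.blocks:
            if isinstance(block, TextBlock):
                md.append(block.text)
            elif isinstance(block, TableBlock):
                md.append(_md_table(block))
            elif isinstance(block, FigureBlock):
                rel = block.path or f"figures/{block.slug}.png"
                md.append(f"![{block.caption}]({rel})")
            md.append("")
    return "\n".join(md).rstrip() + "\n"


def _html_escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _render_html(doc: ReportDocument) -> str:
    meta = doc.metadata
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        "<title>Track overview report</title>",
        "<style>body{font-family:sans-serif;max-width:960px;margin:2em auto;}"
        "table{border-collapse:collapse;font-size:0.85em;}"
        "td,th{border:1px solid #999;padding:2px 6px;}"
        "img{max-width:100%;}nav li{display:inline;margin-right:1em;}</style>",
        "</head><body>",
        "<h1>Track overview report</h1>",
        f"<p>Tool: {_html_escape(str(meta.get('tool', '')))} "
        f"{_html_escape(str(meta.get('version', '')))}<br>"
        f"Generated: {_html_escape(str(meta.get('generated', '')))}</p>",
        "<nav><ul>"
        + "".join(
            f"<li><a href='#{s.id}'>{_html_escape(s.title)}</a></li>" for s in doc.sections
        )
        + "</ul></nav>",
    ]
    for sec in doc.sections:
        parts.append(f"<h2 id='{sec.id}'>{_html_escape(sec.title)}</h2>")
        for block in sec.blocks:
            if isinstance(block, TextBlock):
                parts.append(f"<p>{_html_escape(block.text)}</p>")
            elif isinstance(block, TableBlock):
                rows = [
                    "<tr>" + "".join(f"<th>{_html_escape(h)}</th>" for h in block.headers) + "</tr>"
                ]
                rows += [
                    "<tr>" + "".join(f"<td>{_html_escape(c)}</td>" for c in row) + "</tr>"
                    for row in block.rows
                ]
                caption = (
                    f"<caption>{_html_escape(block.caption)}</caption>" if block.caption else ""
                )
                parts.append(f"<table>{caption}{''.join(rows)}</table>")
            elif isinstance(block, FigureBlock):
                rel = block.path or f"figures/{block.slug}.png"
                parts.append(
                    f"<figure><img src='{rel}' alt='{_html_escape(block.caption)}'>"
                    f"<figcaption>{_html_escape(block.caption)}</figcaption></figure>"
                )
    parts.append("</body></html>")
    return "\n".join(parts) + "\n"


def render(doc: ReportDocument, format: str = "markdown", outdir: str | Path = ".") -> list[Path]:
    """Write the report (Markdown always, HTML on request) plus all figures.

    Figures land in ``outdir/figures/`` named after their slug; the returned
    list contains every file written.
    """
    if format not in ("markdown", "html"):
        raise ValueError(f"format must be markdown or html, got {format!r}")
    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sec in doc.sections:
        for block in sec.blocks:
            if isinstance(block, FigureBlock):
                path = figdir / f"{block.slug}.png"
                render_plot_spec(block.spec, path)
                block.path = f"figures/{block.slug}.png"
                written.append(path)
    md_path = outdir / "report.md"
    md_path.write_text(_render_markdown(doc))
    written.append(md_path)
    if format == "html":
        html_path = outdir / "report.html"
        html_path.write_text(_render_html(doc))
        written.append(html_path)
    (outdir / "report_metadata.json").write_text(
        json.dumps(doc.metadata, indent=2, sort_keys=True) + "\n"
    )
    written.append(outdir / "report_metadata.json")
    return written
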