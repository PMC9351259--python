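"""All-pairs statistical comparison of aggregated columns.

Every unordered pair of columns of the aggregated table is tested with a
test chosen from both columns' scales of measurement:

===================  ==========================================
pair                 test
===================  ==========================================
categorical × categorical   Pearson chi-squared / Fisher exact (2×2)
categorical × numeric       Wilcoxon rank-sum (2 levels) / Kruskal-Wallis
numeric × numeric           correlation test (Pearson, optionally Spearman)
===================  ==========================================

Only features defined in both columns enter a test; pairs with fewer than
three complete observations or a constant side are skipped with a reason.
Raw p-values are corrected across the whole pairwise family
(Benjamini-Hochberg by default) and gated at the configured significance
threshold (0.1 by default).  All tests are rank- or count-based (or a
correlation), so none depends on the absolute height of the values — scaling
a column by a positive constant changes no p-value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Scale, is_defined
from .aggregate import AggregatedTable
from .summarize import PlotSpec
from .track_io import Config

__all__ = [
    "ComparisonMatrix",
    "TestResult",
    "adjust_pvalues",
    "compare_all",
    "format_pvalue",
    "pair_plot_spec",
    "run_test",
    "select_test",
]

MIN_COMPLETE_PAIRS = 3


def select_test(
    scale_a: Scale, scale_b: Scale, levels_a: int = 0, levels_b: int = 0
) -> str:
    """Choose the test family for a pair of scales.

    ``levels_a``/``levels_b`` are the *observed* distinct-level counts, which
    decide Fisher vs chi-squared (Fisher exact for a 2×2 table) and rank-sum
    vs Kruskal-Wallis (rank-sum for exactly two groups).
    """
    cat_a, cat_b = scale_a.is_categorical, scale_b.is_categorical
    if cat_a and cat_b:
        return "fisher" if (levels_a == 2 and levels_b == 2) else "chisq"
    if not cat_a and not cat_b:
        return "correlation"
    cat_levels = levels_a if cat_a else levels_b
    return "ranksum2" if cat_levels == 2 else "kruskal"


@dataclass(frozen=True)
class TestResult:
    col_a: str
    col_b: str
    test: str
    statistic: float | None
    p_raw: float | None
    p_adjusted: float | None
    n_used: int
    effect: float | None = None  # correlation coefficient, or 2x2 odds ratio
    significant: bool = False
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


def _complete_pairs(values_a: Sequence, values_b: Sequence):
    a_out, b_out = [], []
    for va, vb in zip(values_a, values_b):
        if is_defined(va) and is_defined(vb):
            a_out.append(va)
            b_out.append(vb)
    return a_out, b_out


def _skip(col_a: str, col_b: str, test: str, n: int, reason: str) -> TestResult:
    return TestResult(
        col_a=col_a, col_b=col_b, test=test, statistic=None, p_raw=None,
        p_adjusted=None, n_used=n, skipped_reason=reason,
    )


def run_test(
    values_a: Sequence,
    values_b: Sequence,
    scale_a: Scale,
    scale_b: Scale,
    col_a: str = "a",
    col_b: str = "b",
    correlation_method: str = "auto",
) -> TestResult:
    """Run the scale-appropriate test on one aligned column pair.

    Inputs are aligned by feature; only complete pairs (both sides defined)
    are used.  The result carries no multiple-testing adjustment yet.  The
    result is symmetric: swapping the inputs changes no statistic or p-value
    (categorical × numeric pairs are orientation-normalized internally).
    """
    a, b = _complete_pairs(values_a, values_b)
    n = len(a)
    if n < MIN_COMPLETE_PAIRS:
        return _skip(col_a, col_b, "none", n,
                     f"fewer than {MIN_COMPLETE_PAIRS} complete pairs")
    # a meaningful comparison requires more than one value on each side
    if len(set(map(str, a))) < 2 or len(set(map(str, b))) < 2:
        return _skip(col_a, col_b, "none", n, "fewer than two distinct values")

    # normalize orientation: categorical side first for cat x num
    if scale_b.is_categorical and not scale_a.is_categorical:
        a, b = b, a
        scale_a, scale_b = scale_b, scale_a

    lev_a = len(set(map(str, a))) if scale_a.is_categorical else 0
    lev_b = len(set(map(str, b))) if scale_b.is_categorical else 0
    test = select_test(scale_a, scale_b, lev_a, lev_b)
    effect: float | None = None

    if test in ("fisher", "chisq"):
        # cross-tab over observed levels, in declared level order
        order_a = [l for l in scale_a.levels if l in set(map(str, a))]  # type: ignore[union-attr]
        order_b = [l for l in scale_b.levels if l in set(map(str, b))]  # type: ignore[union-attr]
        obs = np.zeros((len(order_a), len(order_b)), dtype=np.int64)
        ia = {l: i for i, l in enumerate(order_a)}
        ib = {l: i for i, l in enumerate(order_b)}
        for va, vb in zip(a, b):
            obs[ia[str(va)], ib[str(vb)]] += 1
        if test == "fisher":
            odds, p = stats.fisher_exact(obs, alternative="two-sided")
            statistic, effect = float(odds), float(odds)
        else:
            chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
            statistic = float(chi2)
    elif test in ("ranksum2", "kruskal"):
        groups: dict[str, list[float]] = {}
        for va, vb in zip(a, b):
            groups.setdefault(str(va), []).append(float(vb))
        samples = [groups[k] for k in sorted(groups)]
        if test == "ranksum2":
            stat_res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        else:
            stat_res = stats.kruskal(*samples)
        statistic, p = float(stat_res.statistic), float(stat_res.pvalue)
    elif test == "correlation":
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        if correlation_method == "spearman":
            r, p = stats.spearmanr(x, y)
            test = "correlation_spearman"
        else:
            if np.array_equal(x, y):
                r, p = 1.0, 0.0  # identical columns: trivially perfect
            else:
                r, p = stats.pearsonr(x, y)
        statistic, effect = float(r), float(r)
        p = float(p)
    else:  # pragma: no cover
        raise ValueError(f"unknown test kind {test!r}")

    return TestResult(
        col_a=col_a, col_b=col_b, test=test, statistic=statistic,
        p_raw=float(p), p_adjusted=None, n_used=n, effect=effect,
    )


def adjust_pvalues(p_raw: Sequence[float], method: str = "BH") -> list[float]:
    """Multiple-testing correction over one family of raw p-values.

    BH is the Benjamini-Hochberg step-up procedure (order-preserving with the
    input); bonferroni multiplies by the family size capped at 1; none is the
    identity.
    """
    p = np.asarray(list(p_raw), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return [float(v) for v in p]
    if method == "BH":
        adj = multipletests(p, method="fdr_bh")[1]
    elif method == "bonferroni":
        adj = multipletests(p, method="bonferroni")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return [float(v) for v in adj]


def format_pvalue(p: float, digits: int = 3) -> str:
    """Display rounding: half-up to `digits` decimals, so p < 0.0005 renders "0"."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value out of range: {p}")
    q = Decimal(repr(p)).quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP)
    if q == q.to_integral_value():
        return str(int(q))
    return f"{q:.{digits}f}"


@dataclass
class ComparisonMatrix:
    """One TestResult per unordered column pair, plus symmetric lookup."""

    column_names: list[str]
    results: list[TestResult]

    def __post_init__(self) -> None:
        n = len(self.column_names)
        assert len(self.results) == n * (n - 1) // 2
        self._index = {frozenset((r.col_a, r.col_b)): r for r in self.results}

    def get(self, col_a: str, col_b: str) -> TestResult:
        return self._index[frozenset((col_a, col_b))]

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.results)

    @property
    def n_skipped(self) -> int:
        return sum(r.skipped for r in self.results)

    def to_dataframe(self, p_round_digits: int | None = None) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "col_a": r.col_a,
                    "col_b": r.col_b,
                    "test": r.test,
                    "statistic": r.statistic,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "p_display": (
                        format_pvalue(r.p_adjusted, p_round_digits)
                        if p_round_digits is not None and r.p_adjusted is not None
                        else None
                    ),
                    "n_used": r.n_used,
                    "effect": r.effect,
                    "significant": r.significant,
                    "skipped_reason": r.skipped_reason or "",
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path, p_round_digits: int | None = None) -> None:
        self.to_dataframe(p_round_digits).to_csv(path, sep="\t", index=False, na_rep="NA")


def compare_all(table: AggregatedTable, config: Config | None = None) -> ComparisonMatrix:
    """Test every unordered pair of table columns and apply the family correction.

    Skipped pairs are excluded from the correction family; significance is
    ``p_adjusted <= config.significance_threshold``.  Column order never
    affects any (pair → p) mapping.
    """
    config = config or Config()
    if table.n_columns < 2:
        raise ValueError("pairwise comparison needs at least 2 columns")
    names = [c.name for c in table.columns]
    infos = {c.name: c for c in table.columns}
    raw_results: list[TestResult] = []
    for name_a, name_b in itertools.combinations(sorted(names), 2):
        res = run_test(
            list(table.data[name_a]),
            list(table.data[name_b]),
            infos[name_a].scale,
            infos[name_b].scale,
            col_a=name_a,
            col_b=name_b,
            correlation_method=config.correlation_method,
        )
        raw_results.append(res)

    tested = [r for r in raw_results if not r.skipped]
    adjusted = adjust_pvalues([r.p_raw for r in tested], config.adjust_method)
    adj_map = {frozenset((r.col_a, r.col_b)): p for r, p in zip(tested, adjusted)}
    final: list[TestResult] = []
    for r in raw_results:
        if r.skipped:
            final.append(r)
            continue
        p_adj = adj_map[frozenset((r.col_a, r.col_b))]
        final.append(
            replace(r, p_adjusted=p_adj, significant=p_adj <= config.significance_threshold)
        )
    return ComparisonMatrix(column_names=sorted(names), results=final)


def pair_plot_spec(result: TestResult, table: AggregatedTable) -> PlotSpec:
    """Figure spec for one (non-skipped) pairwise comparison.

    numeric × numeric → scatter; categorical × numeric → boxplots per level;
    categorical × categorical → feature-count heatmap over the level grid.
    """
    if result.skipped:
        raise ValueError("no plot for a skipped comparison")
    info_a = table.column_info(result.col_a)
    info_b = table.column_info(result.col_b)
    a_vals = list(table.data[result.col_a])
    b_vals = list(table.data[result.col_b])
    a, b = _complete_pairs(a_vals, b_vals)
    title = f"{result.col_a} vs {result.col_b}"

    if info_a.scale.is_numeric and info_b.scale.is_numeric:
        return PlotSpec(
            kind="scatter",
            title=title,
            series={"x": [float(v) for v in a], "y": [float(v) for v in b]},
            labels={"x": result.col_a, "y": result.col_b},
        )
    if info_a.scale.is_categorical and info_b.scale.is_categorical:
        la = list(info_a.scale.levels)  # type: ignore[arg-type]
        lb = list(info_b.scale.levels)  # type: ignore[arg-type]
        counts = np.zeros((len(la), len(lb)), dtype=int)
        for va, vb in zip(a, b):
            counts[la.index(str(va)), lb.index(str(vb))] += 1
        return PlotSpec(
            kind="count_heatmap",
            title=title,
            series={"rows": la, "cols": lb, "counts": counts.tolist()},
            labels={"x": result.col_b, "y": result.col_a},
        )
    # categorical x numeric, normalized so the categorical side labels the boxes
    if info_a.scale.is_categorical:
        cat_vals, num_vals, cat_info = a, b, info_a
        labels = {"x": result.col_a, "y": result.col_b}
    else:
        cat_vals, num_vals, cat_info = b, a, info_b
        labels = {"x": result.col_b, "y": result.col_a}
    groups: dict[str, list[float]] = {str(l): [] for l in cat_info.scale.levels}  # type: ignore[union-attr]
    for c, v in zip(cat_vals, num_vals):
        groups[str(c)].append(float(v))
    return PlotSpec(
        kind="boxplot_by_level",
        title=title,
        series={"groups": {k: v for k, v in groups.items() if v}},
        labels=labels,
    )
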