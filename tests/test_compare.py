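"""Scale-aware pairwise test dispatch, classical-test agreement and FDR gating."""

import itertools
import math

import numpy as np
import pytest

from trackwise.core import Scale, ScaleKind
from trackwise.compare import (
    adjust_pvalues,
    compare_all,
    format_pvalue,
    pair_plot_spec,
    run_test,
    select_test,
)
from trackwise.track_io import Config

RAT = Scale(ScaleKind.RATIONAL)
INT = Scale(ScaleKind.INTERVAL)
ORD = Scale(ScaleKind.ORDINAL, ("low", "medium", "high"))
BIN = Scale(ScaleKind.BINARY, ("no", "yes"))
NOM = Scale(ScaleKind.NOMINAL, ("a", "b", "c"))
ALL_SCALES = {"binary": BIN, "nominal": NOM, "ordinal": ORD, "interval": INT, "rational": RAT}


class TestSelectTest:
    def test_all_ordered_scale_pairs_map_to_the_right_family(self):
        for (ka, sa), (kb, sb) in itertools.product(ALL_SCALES.items(), repeat=2):
            lev_a = len(sa.levels) if sa.is_categorical else 0
            lev_b = len(sb.levels) if sb.is_categorical else 0
            test = select_test(sa, sb, lev_a, lev_b)
            if sa.is_categorical and sb.is_categorical:
                assert test in ("chisq", "fisher"), (ka, kb)
            elif sa.is_numeric and sb.is_numeric:
                assert test == "correlation", (ka, kb)
            else:
                assert test in ("ranksum2", "kruskal"), (ka, kb)

    def test_two_level_cross_tab_takes_fisher(self):
        assert select_test(BIN, BIN, 2, 2) == "fisher"
        assert select_test(BIN, NOM, 2, 3) == "chisq"

    def test_two_category_levels_take_rank_sum(self):
        assert select_test(BIN, RAT, 2, 0) == "ranksum2"
        assert select_test(ORD, RAT, 3, 0) == "kruskal"

    def test_numeric_pair_is_correlation(self):
        assert select_test(RAT, INT) == "correlation"


class TestRunTest:
    def test_fisher_perfect_separation_closed_form(self):
        # 2x2 table [[10,0],[0,10]]: two-sided p = 2 / C(20,10)
        a = ["no"] * 10 + ["yes"] * 10
        b = ["no"] * 10 + ["yes"] * 10
        r = run_test(a, b, BIN, BIN)
        assert r.test == "fisher"
        assert r.p_raw == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_chisq_matches_textbook_statistic(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            shape = (int(rng.integers(2, 4)), int(rng.integers(2, 4)))
            if shape == (2, 2):
                shape = (2, 3)  # 2x2 is dispatched to fisher
            obs = rng.integers(1, 30, size=shape)
            levels_a = [f"r{i}" for i in range(shape[0])]
            levels_b = [f"c{j}" for j in range(shape[1])]
            a, b = [], []
            for i, j in itertools.product(range(shape[0]), range(shape[1])):
                a += [levels_a[i]] * int(obs[i, j])
                b += [levels_b[j]] * int(obs[i, j])
            sa = Scale(ScaleKind.NOMINAL, tuple(levels_a)) if shape[0] > 2 else Scale(
                ScaleKind.BINARY, tuple(levels_a))
            sb = Scale(ScaleKind.NOMINAL, tuple(levels_b)) if shape[1] > 2 else Scale(
                ScaleKind.BINARY, tuple(levels_b))
            r = run_test(a, b, sa, sb)
            assert r.test == "chisq"
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            chi2 = float(((obs - expected) ** 2 / expected).sum())
            assert r.statistic == pytest.approx(chi2, rel=1e-10)

    def test_identical_numeric_columns_correlate_perfectly(self):
        x = [1.0, 2.0, 5.0, 9.0]
        r = run_test(x, x, RAT, RAT)
        assert r.statistic == 1.0 and r.p_raw == 0.0

    def test_constant_column_is_skipped_with_reason(self):
        r = run_test([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0], RAT, RAT)
        assert r.skipped and "distinct" in r.skipped_reason

    def test_too_few_complete_pairs_skipped(self):
        r = run_test([1.0, None, 2.0], [None, 1.0, 2.0], RAT, RAT)
        assert r.skipped and "complete pairs" in r.skipped_reason

    def test_only_complete_pairs_used(self):
        a = [1.0, 2.0, 3.0, 4.0, None]
        b = [2.0, 4.0, 6.0, None, 10.0]
        r = run_test(a, b, RAT, RAT)
        assert r.n_used == 3
        assert r.statistic == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "sa,sb,make",
        [
            (RAT, RAT, lambda rng, n: (rng.lognormal(size=n), rng.lognormal(size=n))),
            (BIN, RAT, lambda rng, n: (
                ["yes" if v else "no" for v in rng.integers(0, 2, n)], rng.lognormal(size=n))),
            (ORD, INT, lambda rng, n: (
                [["low", "medium", "high"][v] for v in rng.integers(0, 3, n)],
                rng.normal(size=n))),
            (BIN, NOM, lambda rng, n: (
                ["yes" if v else "no" for v in rng.integers(0, 2, n)],
                [["a", "b", "c"][v] for v in rng.integers(0, 3, n)])),
        ],
    )
    def test_symmetry_under_input_swap(self, sa, sb, make):
        rng = np.random.default_rng(9)
        a, b = make(rng, 60)
        fwd = run_test(list(a), list(b), sa, sb)
        rev = run_test(list(b), list(a), sb, sa)
        assert fwd.test == rev.test
        assert fwd.statistic == pytest.approx(rev.statistic)
        assert fwd.p_raw == pytest.approx(rev.p_raw)

    def test_p_invariant_under_positive_scaling(self):
        rng = np.random.default_rng(3)
        x, y = rng.lognormal(size=80), rng.lognormal(size=80)
        cats = [["low", "medium", "high"][v] for v in rng.integers(0, 3, 80)]
        base = run_test(list(x), list(y), RAT, RAT)
        scaled = run_test(list(x * 37.5), list(y), RAT, RAT)
        assert scaled.p_raw == pytest.approx(base.p_raw)
        base2 = run_test(cats, list(y), ORD, RAT)
        scaled2 = run_test(cats, list(y * 1e3), ORD, RAT)
        assert scaled2.p_raw == pytest.approx(base2.p_raw)


def bh_oracle(p):
    """Hand step-up: p_adj(i) = min over j >= i (sorted) of p(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestAdjustPvalues:
    def test_hand_bh_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "BH") == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_step_up_oracle_on_random_lists(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            p = list(rng.random(int(rng.integers(1, 40))))
            assert adjust_pvalues(p, "BH") == pytest.approx(bh_oracle(p), rel=1e-12)

    def test_none_is_identity_and_single_p_unchanged(self):
        assert adjust_pvalues([0.4, 0.01], "none") == [0.4, 0.01]
        assert adjust_pvalues([0.042], "BH") == pytest.approx([0.042])

    def test_bonferroni_caps_at_one(self):
        assert adjust_pvalues([0.3, 0.4], "bonferroni") == pytest.approx([0.6, 0.8])
        assert adjust_pvalues([0.9, 0.9], "bonferroni") == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "BH")


class TestFormatPvalue:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0004, "0"), (0.0005, "0.001"), (0.0506, "0.051"), (1.0, "1"),
         (0.1, "0.100"), (0.9996, "1"), (0.12345, "0.123")],
    )
    def test_three_digit_display(self, p, expected):
        assert format_pvalue(p, 3) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            format_pvalue(1.5)


class TestCompareAll:
    def test_pair_count_is_n_choose_2(self):
        from trackwise.simulate import null_spec, generate_dataset
        from trackwise.aggregate import build_aggregated_table

        tracks, ann, _ = generate_dataset(null_spec(n_columns=5, n_genes=50, seed=2))
        table = build_aggregated_table(tracks, ann)
        matrix = compare_all(table, Config())
        assert len(matrix.results) == 10

    def test_column_order_invariance(self, micro_table):
        m = compare_all(micro_table, Config())
        # symmetric lookup returns the same result object either way
        r1 = m.get("expr.fpkm", "peaks.score")
        r2 = m.get("peaks.score", "expr.fpkm")
        assert r1 is r2

    def test_significance_flag_follows_adjusted_threshold(self):
        from trackwise.simulate import planted_pair_spec, generate_dataset
        from trackwise.aggregate import build_aggregated_table

        tracks, ann, truth = generate_dataset(planted_pair_spec(rho=0.9, n_genes=200, seed=4))
        table = build_aggregated_table(tracks, ann)
        matrix = compare_all(table, Config())
        planted = truth["planted"][0]
        r = matrix.get(planted["col_a"], planted["col_b"])
        assert r.significant and r.p_adjusted <= 0.1

    def test_single_column_table_rejected(self, micro_annotation, peak_track):
        from trackwise.aggregate import build_aggregated_table

        table = build_aggregated_table([peak_track], micro_annotation)
        with pytest.raises(ValueError, match="at least 2"):
            compare_all(table, Config())

    def test_tsv_export_lists_every_pair(self, micro_table, tmp_path):
        m = compare_all(micro_table, Config())
        m.to_tsv(tmp_path / "cmp.tsv", 3)
        lines = (tmp_path / "cmp.tsv").read_text().splitlines()
        assert len(lines) == 1 + len(m.results)
        assert lines[0].split("\t")[:3] == ["col_a", "col_b", "test"]


class TestPairPlotSpec:
    def _matrix_and_table(self, seed=0):
        from trackwise.simulate import SyntheticSpec, TrackDef, generate_dataset
        from trackwise.aggregate import build_aggregated_table

        spec = SyntheticSpec(
            n_genes=120, seed=seed,
            tracks=[
                TrackDef(technology="RNA-seq", condition="a", id="x"),
                TrackDef(technology="RNA-seq", condition="b", id="y"),
                TrackDef(technology="RRBS", condition="a", id="m",
                         scale={"ordinal": ["low", "medium", "high"]}),
                TrackDef(technology="RRBS", condition="b", id="n",
                         scale={"ordinal": ["low", "medium", "high"]}),
            ],
        )
        tracks, ann, _ = generate_dataset(spec)
        table = build_aggregated_table(tracks, ann)
        return compare_all(table, Config()), table

    def test_plot_kind_per_scale_pair(self):
        matrix, table = self._matrix_and_table()
        assert pair_plot_spec(matrix.get("x.value", "y.value"), table).kind == "scatter"
        assert pair_plot_spec(matrix.get("m.value", "x.value"), table).kind == "boxplot_by_level"
        assert pair_plot_spec(matrix.get("m.value", "n.value"), table).kind == "count_heatmap"

    def test_skipped_pair_has_no_plot(self):
        r = run_test([1.0, None], [None, 2.0], RAT, RAT)
        with pytest.raises(ValueError, match="skipped"):
            pair_plot_spec(r, None)
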