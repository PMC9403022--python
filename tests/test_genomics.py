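"""Spearman correlation, top-fraction selection, hypergeometric ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epistroma.genomics import (
    RatioExpressionAnalysis,
    correlate_expression,
    ora_enrich,
    select_top_fraction,
    spearman_rho,
    top_terms,
)
from epistroma.synth import ExpressionSpec, generate_annotation, generate_expression


def _rank_pearson_oracle(x, y):
    """Average-rank then Pearson, written independently of scipy.spearmanr."""
    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        ranks[order] = np.arange(1, len(v) + 1)
        for val in np.unique(v):
            sel = v == val
            ranks[sel] = ranks[sel].mean()
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman_rho(x, y) == pytest.approx(_rank_pearson_oracle(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1, 2, 3])


@pytest.fixture(scope="module")
def planted_setup():
    rng = np.random.default_rng(0)
    ratios = rng.uniform(0.1, 0.9, 100)
    spec = ExpressionSpec(n_genes=2000, n_samples=100, n_planted_epi=10,
                          n_planted_stro=10, target_rho=0.8, seed=1)
    expr, planted = generate_expression(ratios, spec)
    rt = pd.DataFrame({"ratio_epi": ratios, "ratio_stro": 1 - ratios}, index=expr.columns)
    return expr, rt, planted


class TestCorrelateExpression:
    def test_gene_equal_to_ratio(self):
        ratios = np.array([0.2, 0.4, 0.1, 0.8, 0.6])
        samples = [f"S{i}" for i in range(5)]
        expr = pd.DataFrame([ratios], index=["g0"], columns=samples)
        rt = pd.DataFrame({"ratio_epi": ratios, "ratio_stro": 1 - ratios}, index=samples)
        tab = correlate_expression(expr, rt)
        assert tab.loc["g0", "rho_epi"] == pytest.approx(1.0)
        assert tab.loc["g0", "rho_stro"] == pytest.approx(-1.0)

    def test_invariant_to_consistent_sample_permutation(self, planted_setup):
        expr, rt, _ = planted_setup
        perm = np.random.default_rng(5).permutation(expr.columns)
        tab1 = correlate_expression(expr, rt)
        tab2 = correlate_expression(expr[perm], rt.loc[perm])
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_matches_rowwise_spearman(self, planted_setup):
        expr, rt, _ = planted_setup
        tab = correlate_expression(expr.iloc[:25], rt)
        for g in expr.index[:25]:
            expected = spearman_rho(expr.loc[g].to_numpy(), rt["ratio_epi"].to_numpy())
            assert tab.loc[g, "rho_epi"] == pytest.approx(expected, abs=1e-12)

    def test_sample_mismatch_rejected(self, planted_setup):
        expr, rt, _ = planted_setup
        with pytest.raises(ValueError):
            correlate_expression(expr, rt.iloc[:-1])

    def test_constant_gene_flagged(self):
        samples = [f"S{i}" for i in range(5)]
        expr = pd.DataFrame([[1.0] * 5, [1, 2, 3, 4, 5]], index=["flat", "ok"], columns=samples)
        rt = pd.DataFrame({"ratio_epi": [0.1, 0.2, 0.3, 0.4, 0.5],
                           "ratio_stro": [0.9, 0.8, 0.7, 0.6, 0.5]}, index=samples)
        tab = correlate_expression(expr, rt)
        assert not tab.loc["flat", "defined"]
        assert np.isnan(tab.loc["flat", "rho_epi"])
        assert tab.loc["ok", "defined"]


class TestSelection:
    def test_ceil_fraction_count(self, planted_setup):
        expr, rt, _ = planted_setup
        tab = correlate_expression(expr.iloc[:200], rt)
        assert len(select_top_fraction(tab, "epi", 0.01)) == 2

    def test_fraction_one_returns_all(self, planted_setup):
        expr, rt, _ = planted_setup
        tab = correlate_expression(expr.iloc[:50], rt)
        assert len(select_top_fraction(tab, "epi", 1.0)) == 50

    def test_planted_genes_recovered(self, planted_setup):
        expr, rt, planted = planted_setup
        tab = correlate_expression(expr, rt)
        sel_epi = select_top_fraction(tab, "epi", 0.01)
        sel_stro = select_top_fraction(tab, "stro", 0.01)
        assert len(sel_epi) == 20
        assert len(set(sel_epi) & set(planted["epi"])) >= 9
        assert len(set(sel_stro) & set(planted["stro"])) >= 9

    def test_ties_break_by_gene_id(self):
        samples = [f"S{i}" for i in range(4)]
        vals = [1.0, 2.0, 3.0, 4.0]
        expr = pd.DataFrame([vals, vals, vals[::-1]], index=["b", "a", "c"], columns=samples)
        rt = pd.DataFrame({"ratio_epi": vals, "ratio_stro": vals[::-1]}, index=samples)
        tab = correlate_expression(expr, rt)
        assert select_top_fraction(tab, "epi", 2 / 3) == ["a", "b"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction(pd.DataFrame(columns=["rho_epi", "rho_stro"]), "epi")


def _hypergeom_tail_oracle(k, N, K, n):
    """P[X >= k] by exhaustive enumeration of all C(N, n) selections."""
    universe = range(N)
    term = set(range(K))
    hits = total = 0
    for sel in itertools.combinations(universe, n):
        total += 1
        if len(term & set(sel)) >= k:
            hits += 1
    return hits / total


class TestOra:
    def test_exact_combinatorial_example(self):
        universe = [f"g{i}" for i in range(20)]
        ann = {"T": ("t", tuple(universe[:5]))}
        rows = ora_enrich(universe[:5], ann, universe, min_term_size=1)
        assert rows[0].k == 5 and rows[0].n == 5 and rows[0].K == 5 and rows[0].N == 20
        assert rows[0].p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_disjoint_selection(self):
        universe = [f"g{i}" for i in range(10)]
        ann = {"T": ("t", tuple(universe[:3]))}
        rows = ora_enrich(universe[5:8], ann, universe, min_term_size=1)
        assert rows[0].k == 0
        assert rows[0].p == pytest.approx(1.0)
        assert rows[0].enrichment_ratio == 0.0

    def test_bonferroni_definition(self):
        universe = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        ann = {f"T{i}": ("t", tuple(rng.choice(universe, 6, replace=False))) for i in range(10)}
        rows = ora_enrich(universe[:5], ann, universe, min_term_size=1)
        for r in rows:
            assert r.p_adj == pytest.approx(min(1.0, 10 * r.p))
            assert r.p <= r.p_adj <= 1.0

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 4, 5), (12, 5, 6)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        universe = [f"g{i}" for i in range(N)]
        ann = {"T": ("t", tuple(universe[:K]))}
        for k_planted in range(0, min(K, n) + 1):
            sel = universe[:k_planted] + universe[K : K + n - k_planted]
            rows = ora_enrich(sel, ann, universe, min_term_size=1)
            assert rows[0].p == pytest.approx(
                _hypergeom_tail_oracle(rows[0].k, N, K, n), rel=1e-9
            )

    def test_monotone_in_hits(self):
        ps = [float(stats.hypergeom.sf(k - 1, 50, 10, 8)) for k in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_selection_outside_reference_rejected(self):
        with pytest.raises(ValueError):
            ora_enrich(["x"], {"T": ("t", ("a",))}, ["a", "b"], min_term_size=1)


class TestTopTerms:
    def test_fewer_rows_than_k(self):
        universe = [f"g{i}" for i in range(10)]
        ann = {f"T{i}": ("t", tuple(universe[i : i + 5])) for i in range(3)}
        rows = ora_enrich(universe[:5], ann, universe, min_term_size=1)
        assert len(top_terms(rows, 10)) == 3

    def test_ordering_matches_p(self):
        universe = [f"g{i}" for i in range(30)]
        ann = {
            "A": ("t", tuple(universe[:5])),    # all 5 hits
            "B": ("t", tuple(universe[3:10])),  # partial
            "C": ("t", tuple(universe[20:26])),  # none
        }
        rows = ora_enrich(universe[:5], ann, universe, min_term_size=1)
        ranked = top_terms(rows, 3)
        assert [r.term for r in ranked] == ["A", "B", "C"]

    def test_planted_term_ranks_first_end_to_end(self, planted_setup):
        expr, rt, planted = planted_setup
        universe = list(expr.index.astype(str))
        ann = generate_annotation(universe, 50, (10, 100), planted["epi"], seed=2)
        analysis = RatioExpressionAnalysis(expr, rt, ann)
        res = analysis.fit(fraction=0.01, reference=set(universe))
        best = top_terms(res.enrichment["epi"], 1)[0]
        assert best.term == "T0000"
        assert best.p_adj < 0.05
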