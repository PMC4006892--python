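"""Probe collapsing and the minimum-hypergeometric rank-order set statistic."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mhgpipe.containers import GeneSet
from mhgpipe.enrichment import (
    RankedGeneList,
    collapse_probes,
    enrich_collection,
    enrichment_frame,
    gene_set_pvalue,
    order_statistic_tail,
)
from mhgpipe.errors import InputError


def brute_tail(N: int, n: int, k: int, r: int) -> float:
    """Exhaustive oracle: fraction of all C(N,n) rank subsets whose k-th
    smallest rank is <= r (i.e. at least k draws land in the top r)."""
    hits = sum(1 for sub in combinations(range(1, N + 1), n) if sorted(sub)[k - 1] <= r)
    return hits / math.comb(N, n)


def ranked(n_genes: int) -> RankedGeneList:
    genes = [f"G{i}" for i in range(1, n_genes + 1)]
    return RankedGeneList(ranks=pd.Series(range(1, n_genes + 1), index=genes))


class TestOrderStatisticTail:
    @pytest.mark.parametrize(
        "N,n,k,r,expected",
        [
            (10, 3, 1, 1, 3 / 10),       # P(any of 3 draws hits the single top rank)
            (10, 3, 1, 10, 1.0),         # all draws lie within the top 10 of 10
            (10, 3, 2, 4, 40 / 120),     # enumeration over all C(10,3) subsets
            (10, 3, 3, 3, 1 / 120),      # only one subset occupies the top block
        ],
    )
    def test_worked_values(self, N, n, k, r, expected):
        assert order_statistic_tail(N, n, k, r) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy_hypergeometric_tail(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 2000))
        n = int(rng.integers(1, min(N, 60) + 1))
        k = int(rng.integers(1, n + 1))
        r = int(rng.integers(1, N + 1))
        expected = stats.hypergeom.sf(k - 1, N, r, n)
        assert order_statistic_tail(N, n, k, r) == pytest.approx(expected, rel=1e-9)

    def test_matches_exhaustive_oracle_on_a_small_grid(self):
        for N in (5, 8):
            for n in range(1, min(4, N) + 1):
                for k in range(1, n + 1):
                    for r in range(1, N + 1):
                        assert order_statistic_tail(N, n, k, r) == pytest.approx(
                            brute_tail(N, n, k, r), abs=1e-12
                        )

    @given(st.integers(2, 30), st.data())
    def test_monotone_in_r_and_k(self, N, data):
        n = data.draw(st.integers(1, min(6, N)))
        k = data.draw(st.integers(1, n))
        tails_r = [order_statistic_tail(N, n, k, r) for r in range(1, N + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(tails_r, tails_r[1:]))
        r = data.draw(st.integers(1, N))
        tails_k = [order_statistic_tail(N, n, kk, r) for kk in range(1, n + 1)]
        assert all(b <= a + 1e-12 for a, b in zip(tails_k, tails_k[1:]))

    def test_literal_variant_scores_the_bottom(self):
        # P(at least one of 3 draws lands in position {10}) = 3/10
        assert order_statistic_tail(10, 3, 1, 10, variant="literal") == pytest.approx(0.3)
        assert order_statistic_tail(10, 3, 1, 1, variant="literal") == pytest.approx(1.0)

    @pytest.mark.parametrize("args", [(10, 3, 4, 5), (10, 11, 1, 5), (10, 3, 0, 5),
                                      (10, 3, 1, 0), (10, 3, 1, 11)])
    def test_bounds_enforced(self, args):
        with pytest.raises(InputError):
            order_statistic_tail(*args)


class TestCollapseProbes:
    @staticmethod
    def q_sorted(genes):
        return pd.DataFrame(
            {"gene": genes, "q": np.linspace(0, 1, len(genes))},
            index=[f"P{i}" for i in range(1, len(genes) + 1)],
        )

    def test_one_probe_per_gene_keeps_ranks(self):
        out = collapse_probes(self.q_sorted(["A", "B", "C"]))
        assert out.ranks.to_dict() == {"A": 1, "B": 2, "C": 3}

    def test_best_probe_wins_and_ranks_reclose(self):
        out = collapse_probes(self.q_sorted(["A", "B", "A", "C"]))
        assert out.ranks.to_dict() == {"A": 1, "B": 2, "C": 3}

    def test_empty_table_gives_empty_list(self):
        out = collapse_probes(self.q_sorted([]))
        assert out.n_genes == 0

    def test_unannotated_probes_dropped_with_logged_count(self, caplog):
        with caplog.at_level("WARNING", logger="mhgpipe.enrichment"):
            out = collapse_probes(self.q_sorted(["A", None, "B", ""]))
        assert out.ranks.to_dict() == {"A": 1, "B": 2}
        assert any("2 probe(s)" in rec.message for rec in caplog.records)

    def test_rank_list_must_be_a_permutation(self):
        with pytest.raises(InputError, match="permutation"):
            RankedGeneList(ranks=pd.Series({"A": 1, "B": 3}))
        with pytest.raises(InputError, match="duplicate"):
            RankedGeneList(ranks=pd.Series([1, 2], index=["A", "A"]))


class TestGeneSetPvalue:
    def test_worked_example_ranks_1_2_5(self):
        res = gene_set_pvalue(ranked(10), GeneSet("s", ("G1", "G2", "G5")))
        assert res.pk_values == pytest.approx((0.3, 8 / 120, 10 / 120), abs=1e-12)
        assert res.p_raw == pytest.approx(8 / 120, abs=1e-12)
        assert res.k_star == 2

    def test_top_block_ranks_1_2_3(self):
        res = gene_set_pvalue(ranked(10), GeneSet("s", ("G1", "G2", "G3")))
        assert res.p_raw == pytest.approx(1 / 120, abs=1e-12)

    def test_set_of_all_genes_is_uninformative(self):
        res = gene_set_pvalue(ranked(10), GeneSet("s", tuple(f"G{i}" for i in range(1, 11))))
        assert res.pk_values == pytest.approx(tuple([1.0] * 10))
        assert res.p_raw == 1.0

    def test_disjoint_set_flagged_not_testable(self):
        res = gene_set_pvalue(ranked(10), GeneSet("s", ("X1", "X2")))
        assert not res.testable and res.n == 0

    def test_invariant_under_relabeling_non_members(self):
        # p depends only on the member ranks, not on which other genes exist
        a = gene_set_pvalue(ranked(50), GeneSet("s", ("G3", "G17", "G40")))
        genes = [f"H{i}" for i in range(1, 51)]
        shuffled = RankedGeneList(
            ranks=pd.Series(range(1, 51), index=genes).rename(
                {"H3": "G3", "H17": "G17", "H40": "G40"}
            )
        )
        b = gene_set_pvalue(shuffled, GeneSet("s", ("G3", "G17", "G40")))
        assert a.p_raw == b.p_raw and a.pk_values == b.pk_values

    @given(st.data())
    def test_promoting_a_member_never_hurts(self, data):
        N = data.draw(st.integers(5, 40))
        n = data.draw(st.integers(1, min(6, N)))
        member_idx = sorted(data.draw(
            st.sets(st.integers(1, N), min_size=n, max_size=n)))
        rl = ranked(N)
        base = gene_set_pvalue(rl, GeneSet("s", tuple(f"G{i}" for i in member_idx)))
        worst = max(member_idx)
        better = data.draw(st.integers(1, worst))
        if better not in member_idx:
            promoted = sorted(member_idx[:-1] + [better])
            res = gene_set_pvalue(rl, GeneSet("s", tuple(f"G{i}" for i in promoted)))
            assert res.p_raw <= base.p_raw + 1e-15


class TestEnrichCollection:
    def test_single_set_unadjusted(self):
        sets = [GeneSet("only", ("G2", "G9"))]
        res = enrich_collection(ranked(10), sets)[0]
        assert res.p_adjusted == pytest.approx(res.p_raw)

    def test_bonferroni_cap_and_reporting_rule(self):
        # m testable sets multiply the raw p, capped at 1
        rl = ranked(200)
        sets = [GeneSet(f"s{i}", (f"G{i + 50}", f"G{i + 90}")) for i in range(40)]
        sets.append(GeneSet("top", ("G1", "G2", "G3")))
        results = enrich_collection(rl, sets, alpha=0.01)
        frame = enrichment_frame(results)
        assert (frame["p_adjusted"].dropna() <= 1.0).all()
        m = int(frame["testable"].sum())
        top = frame.loc["top"]
        assert top["p_adjusted"] == pytest.approx(min(1.0, top["p_raw"] * m))
        assert bool(top["reported"]) == (top["p_adjusted"] <= 0.01)

    def test_m_counts_only_testable_sets(self):
        sets = [GeneSet("in", ("G1", "G2")), GeneSet("out", ("X1", "X2"))]
        results = enrich_collection(ranked(10), sets)
        by_name = {r.name: r for r in results}
        assert by_name["in"].p_adjusted == pytest.approx(by_name["in"].p_raw)  # m == 1
        assert by_name["out"].p_adjusted is None and not by_name["out"].testable

    def test_sorted_by_adjusted_p_then_name(self):
        sets = [GeneSet("b", ("G8", "G9")), GeneSet("a", ("G8", "G9")),
                GeneSet("top", ("G1", "G2"))]
        names = [r.name for r in enrich_collection(ranked(10), sets)]
        assert names == ["top", "a", "b"]

    def test_all_sets_disjoint_is_an_error(self):
        with pytest.raises(InputError, match="no gene set"):
            enrich_collection(ranked(5), [GeneSet("s", ("X",))])
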