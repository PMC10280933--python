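"""GMT parsing, hypergeometric ORA, BH adjustment, GSEA statistics."""

from fractions import Fraction

import numpy as np
import pytest

from _oracles import (bh_stepup, gsea_running_sum_trace,
                      hypergeom_tail_enumeration, hypergeom_tail_exact)
from cernascope.enrichment import (bh_adjust, gsea_es, gsea_permutation_p,
                                   hypergeom_tail, ora, read_gmt, write_gmt)


class TestGmt:
    def test_parse_two_sets(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\tdesc\tA\tB\nS2\tdesc\tC\tD\tD\n")
        sets = read_gmt(p)
        assert list(sets) == ["S1", "S2"]
        assert sets["S2"] == ["C", "D"]  # duplicate member collapsed

    def test_round_trip(self, tmp_path):
        sets = {"S1": ["A", "B"], "S2": ["C"]}
        assert read_gmt(write_gmt(sets, tmp_path / "c.gmt")) == sets

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("S1\tdesc\tA\nS2\tonlydesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(p)

    def test_duplicate_set_name_rejected(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S1\td\tA\nS1\td\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)


class TestHypergeom:
    def test_worked_value_matches_enumeration(self):
        p = hypergeom_tail(10, 5, 4, 4)
        assert p == pytest.approx(5 / 210, abs=1e-12)
        assert hypergeom_tail_enumeration(10, 5, 4, 4) == Fraction(5, 210)

    def test_tail_at_zero_is_one(self):
        assert hypergeom_tail(20, 5, 4, 0) == pytest.approx(1.0)

    def test_exact_against_summation_oracle_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = float(hypergeom_tail_exact(N, K, n, k))
                        assert hypergeom_tail(N, K, n, k) == pytest.approx(
                            expected, abs=1e-12)


class TestOra:
    def test_full_query_overlap(self):
        universe = [f"g{i}" for i in range(10)]
        table = ora(universe[:4], universe, {"S": universe[:5]}, min_size=2)
        row = table.iloc[0]
        assert (row["N"], row["K"], row["n"], row["k"]) == (10, 5, 4, 4)
        assert row["p"] == pytest.approx(5 / 210, abs=1e-12)
        assert row["fold_enrichment"] == pytest.approx((4 / 4) / (5 / 10))

    def test_query_equals_universe_forces_p_one(self):
        universe = [f"g{i}" for i in range(12)]
        table = ora(universe, universe, {"S": universe[:6]}, min_size=2)
        assert table.iloc[0]["p"] == pytest.approx(1.0)
        assert float(hypergeom_tail_exact(12, 6, 12, 6)) == 1.0

    def test_size_bounds_skip_sets(self):
        universe = [f"g{i}" for i in range(20)]
        table = ora(universe[:5], universe,
                    {"tiny": universe[:2], "ok": universe[:8]}, min_size=5)
        assert list(table["set_name"]) == ["ok"]

    def test_stray_query_genes_dropped(self):
        universe = [f"g{i}" for i in range(10)]
        table = ora(universe[:3] + ["missing"], universe,
                    {"S": universe[:5]}, min_size=2)
        assert table.iloc[0]["n"] == 3

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora(["a"], [], {"S": ["a"]})

    def test_q_bh_consistent(self, default_dataset, default_de):
        universe = default_dataset.matrix.genes_of("mRNA")
        query = default_de.query("biotype == 'mRNA' and direction != 'ns'")[
            "gene_id"]
        table = ora(query, universe, default_dataset.gene_sets)
        assert (table["q"] + 1e-12 >= table["p"]).all()
        assert table.iloc[0]["set_name"] == "PLANTED_DE_SET"
        np.testing.assert_allclose(table["q"],
                                   bh_stepup(list(table["p"])), atol=1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepped_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal_and_idempotent(self):
        q = bh_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, 0.2)
        np.testing.assert_allclose(bh_adjust(q), q)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGseaEs:
    def test_single_top_gene(self):
        ranked = [f"g{i}" for i in range(10)]
        metric = np.linspace(3, -3, 10)
        assert gsea_es(ranked, metric, {"g0"}, exponent=0) == pytest.approx(1.0)

    def test_single_bottom_gene_matches_running_sum_trace(self):
        ranked = [f"g{i}" for i in range(10)]
        metric = np.linspace(3, -3, 10)
        trace = gsea_running_sum_trace(ranked, metric, {"g9"}, 0)
        expected = trace[int(np.argmax(np.abs(trace)))]
        assert gsea_es(ranked, metric, {"g9"}, exponent=0) == pytest.approx(expected)
        assert expected == pytest.approx(-1.0)

    def test_matches_trace_on_random_sets(self):
        rng = np.random.default_rng(8)
        ranked = [f"g{i}" for i in range(40)]
        metric = np.sort(rng.normal(size=40))[::-1]
        for _ in range(10):
            members = set(rng.choice(ranked, size=int(rng.integers(2, 15)),
                                     replace=False))
            trace = gsea_running_sum_trace(ranked, metric, members, 1.0)
            expected = trace[int(np.argmax(np.abs(trace)))]
            assert gsea_es(ranked, metric, members) == pytest.approx(expected)

    def test_reversed_ranking_flips_tail(self):
        ranked = [f"g{i}" for i in range(10)]
        metric = np.linspace(3, -3, 10)
        top = {"g0", "g1"}
        es_fwd = gsea_es(ranked, metric, top, exponent=0)
        es_rev = gsea_es(ranked[::-1], metric[::-1], top, exponent=0)
        assert es_fwd > 0 > es_rev

    def test_metric_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        ranked = [f"g{i}" for i in range(30)]
        metric = np.sort(rng.normal(size=30))[::-1]
        members = {"g1", "g5", "g20"}
        assert gsea_es(ranked, metric, members) == pytest.approx(
            gsea_es(ranked, 7.0 * metric, members))

    def test_empty_intersection_flagged(self):
        with pytest.raises(ValueError):
            gsea_es(["a", "b", "c"], [1.0, 0.5, 0.1], {"z"})


class TestGseaPermutation:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        ranked = [f"g{i}" for i in range(50)]
        metric = np.sort(rng.normal(size=50))[::-1]
        r1 = gsea_permutation_p(ranked, metric, {"g0", "g1", "g2"}, seed=5)
        r2 = gsea_permutation_p(ranked, metric, {"g0", "g1", "g2"}, seed=5)
        assert r1.p == r2.p and r1.es == r2.es

    def test_planted_top_concentration_detected(self):
        rng = np.random.default_rng(6)
        hits = 0
        for seed in range(20):
            ranked = [f"g{i}" for i in range(100)]
            metric = np.sort(rng.normal(size=100))[::-1]
            res = gsea_permutation_p(ranked, metric, set(ranked[:8]),
                                     n_perm=500, seed=seed)
            hits += res.p < 0.05
        assert hits >= 19

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError):
            gsea_permutation_p(["a", "b", "c"], [1, 0, -1], {"a"}, n_perm=10)
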