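"""The weighted bottom-up enrichment traversal."""

import math

import pytest

from dagenrich import (
    CLASSIC_PARAMS,
    AnnotationTable,
    EnrichmentParams,
    Term,
    WeightLedger,
    XMIN,
    build_graph,
    classic_ora,
    dynamic_weight,
    hypergeom_upper_tail,
    initial_weights,
    penalty,
    propagate_true_path,
    run_enrichment,
)


class TestInitialWeights:
    def test_decay_and_floor(self, worked_annotations):
        ledger = initial_weights(worked_annotations, EnrichmentParams())
        assert ledger.get("T:07", "G01") == 1.0  # direct
        assert ledger.get("T:05", "G01") == pytest.approx(0.8)  # 2 levels up
        assert ledger.get("T:01", "G01") == 0.5  # distance 5, floored

    def test_floor_at_distance_nine(self):
        terms = [Term(f"L:{i:02d}", parents=[f"L:{i-1:02d}"] if i else [])
                 for i in range(10)]
        graph = build_graph(terms, "L:00")
        table = propagate_true_path(AnnotationTable(direct={("g", "L:09")}), graph)
        ledger = initial_weights(table, EnrichmentParams())
        assert ledger.get("L:00", "g") == 0.5  # 1 - 0.9 floored at 0.5


class TestDynamicWeight:
    def test_log_ratio_of_powers(self):
        assert dynamic_weight(1e-6, 1e-3) == pytest.approx(2.0)
        assert dynamic_weight(1e-3, 1e-6) == pytest.approx(0.5)

    def test_equal_scores_give_one(self):
        assert dynamic_weight(1e-4, 1e-4) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dynamic_weight(0.0, 0.5)
        with pytest.raises(ValueError):
            dynamic_weight(0.5, -1.0)


class TestPenalty:
    def test_similar_weakly_significant_pair_penalized_hard(self):
        expected = 0.1 * math.log(XMIN) / (2 * math.log(1e-2))
        assert expected == pytest.approx(7.691, abs=1e-3)
        assert penalty(1e-2, 1e-2) == pytest.approx(expected, rel=1e-12)

    def test_very_significant_pair_clamps_to_one(self):
        assert penalty(1e-80, 1e-80) == 1.0
        assert penalty(1e-300, 1e-300) == 1.0

    def test_out_of_domain_rejected(self):
        for pair in [(0.0, 0.5), (0.5, 0.0), (1.0, 0.5), (0.5, 1.0)]:
            with pytest.raises(ValueError):
                penalty(*pair)

    def test_always_at_least_one(self):
        for p_t in (1e-2, 1e-10, 1e-100):
            for p_c in (1e-3, 1e-40, 1e-250):
                assert penalty(p_t, p_c) >= 1.0


class TestWeightLedger:
    def test_shrink_and_scale_guards(self):
        ledger = WeightLedger({"t": {"g": 0.8}})
        ledger.shrink("t", "g", 2.0)
        assert ledger.get("t", "g") == pytest.approx(0.4)
        ledger.scale("t", "g", 0.5)
        assert ledger.get("t", "g") == pytest.approx(0.2)
        with pytest.raises(ValueError):
            ledger.shrink("t", "g", 0.5)  # would increase
        with pytest.raises(ValueError):
            ledger.scale("t", "g", 1.5)  # would increase

    def test_weights_never_reach_zero(self):
        ledger = WeightLedger({"t": {"g": 1e-300}})
        ledger.shrink("t", "g", 1e100)
        assert ledger.get("t", "g") > 0.0


def _expand(terms, root, pairs):
    graph = build_graph(terms, root)
    return graph, propagate_true_path(AnnotationTable(direct=set(pairs)), graph)


class TestRunEnrichment:
    def test_single_node_degenerate(self):
        graph, table = _expand([Term("R")], "R", [("g1", "R"), ("g2", "R")])
        result = run_enrichment(graph, table, ["g1", "g2"])
        assert len(result.nodes) == 1
        assert result.nodes[0].p == 1.0

    def test_specific_child_worsens_parent(self):
        # child B carries all interesting genes directly; the decorrelated
        # parent p must exceed its plain term-for-term p
        terms = [Term("R"), Term("A", parents=["R"]), Term("B", parents=["A"])]
        pairs = [(f"s{i}", "B") for i in range(5)]
        pairs += [(f"a{i}", "A") for i in range(3)]
        pairs += [(f"r{i}", "R") for i in range(7)]
        graph, table = _expand(terms, "R", pairs)
        interest = [f"s{i}" for i in range(5)]
        weighted = run_enrichment(graph, table, interest)
        plain = classic_ora(graph, table, interest)
        assert weighted.pvalue("B") <= plain.pvalue("B")
        assert weighted.pvalue("A") > plain.pvalue("A")
        assert weighted.rank("B") == 1

    def test_reduction_to_classic_ora(self, worked_graph, worked_annotations, worked_interest):
        result = run_enrichment(worked_graph, worked_annotations, worked_interest, CLASSIC_PARAMS)
        N = result.background_size
        n = result.interest_size
        for nd in result.nodes:
            m = nd.bg_ratio[0]
            r = nd.gene_ratio[0]
            assert nd.p == pytest.approx(
                max(hypergeom_upper_tail(N, m, n, r), XMIN), abs=1e-12
            )

    def test_interest_outside_background_dropped(self, worked_graph, worked_annotations):
        result = run_enrichment(worked_graph, worked_annotations, ["G01", "G02", "NOT_A_GENE"])
        assert result.interest_size == 2

    def test_empty_interest_intersection_is_error(self, worked_graph, worked_annotations):
        with pytest.raises(ValueError, match="background"):
            run_enrichment(worked_graph, worked_annotations, ["nope"])

    def test_gene_count_bounds_skip_nodes(self, worked_graph, worked_annotations, worked_interest):
        bounded = EnrichmentParams(min_genes=2, max_genes=19)
        result = run_enrichment(worked_graph, worked_annotations, worked_interest, bounded)
        terms = {nd.term for nd in result.nodes}
        assert "T:01" not in terms  # 20 genes > max
        assert "T:03" in terms

    def test_results_sorted_and_adjusted(self, worked_graph, worked_annotations, worked_interest):
        result = run_enrichment(worked_graph, worked_annotations, worked_interest)
        ps = [nd.p for nd in result.nodes]
        assert ps == sorted(ps)
        for nd in result.nodes:
            assert XMIN <= nd.p <= 1.0
            assert nd.p <= nd.p_adjust <= 1.0

    def test_deterministic_repeat(self, worked_graph, worked_annotations, worked_interest):
        first = run_enrichment(worked_graph, worked_annotations, worked_interest)
        second = run_enrichment(worked_graph, worked_annotations, worked_interest)
        assert first.to_dataframe().equals(second.to_dataframe())

    def test_tsv_dialect(self, tmp_path, worked_graph, worked_annotations, worked_interest):
        result = run_enrichment(worked_graph, worked_annotations, worked_interest)
        out = tmp_path / "result.tsv"
        result.write_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == [
            "DOID", "DOTerm", "level", "p", "p_adjust", "geneRatio", "bgRatio", "genes"
        ]
        top = lines[1].split("\t")
        assert top[0] == "T:07"
        assert top[5] == "5/6"
        assert top[6] == "5/20"


class TestLedgerMonotonicityDuringRuns:
    def test_no_weight_increases_in_full_run(self, worked_graph, worked_annotations,
                                             worked_interest, monkeypatch):
        events = []
        orig_shrink = WeightLedger.shrink
        orig_scale = WeightLedger.scale

        def spy_shrink(self, term, gene, divisor):
            before = self.get(term, gene)
            orig_shrink(self, term, gene, divisor)
            events.append(self.get(term, gene) - before)

        def spy_scale(self, term, gene, factor):
            before = self.get(term, gene)
            orig_scale(self, term, gene, factor)
            events.append(self.get(term, gene) - before)

        monkeypatch.setattr(WeightLedger, "shrink", spy_shrink)
        monkeypatch.setattr(WeightLedger, "scale", spy_scale)
        run_enrichment(worked_graph, worked_annotations, worked_interest)
        assert all(delta <= 1e-15 for delta in events)
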