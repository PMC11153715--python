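"""Unit, oracle and property tests for enrichment and annotation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgradiate.enrichment import (
    AnnotationSet,
    Dictionary,
    EnrichmentTable,
    annotate_text,
    bh_adjust,
    entity_cloud,
    go_enrichment,
    semantic_expand,
)

from conftest import hypergeom_tail_oracle


def make_annotations(term_to_genes, background):
    g2t: dict[str, set[str]] = {}
    for term, genes in term_to_genes.items():
        for gene in genes:
            g2t.setdefault(gene, set()).add(term)
    return AnnotationSet(gene_to_terms=g2t, background=set(background))


class TestBHAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal(self):
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_single_p(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_empty(self):
        assert bh_adjust([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_capped_at_one(self):
        assert max(bh_adjust([0.9, 0.95, 1.0])) <= 1.0

    def test_direct_formula(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205]
        m = len(p)
        expected = [
            min(min(m * pj / (j + 1) for j, pj in enumerate(p) if j >= i), 1.0)
            for i in range(m)
        ]
        assert bh_adjust(p) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariant_and_order_preserving(self, p, rnd):
        q = bh_adjust(p)
        order = list(range(len(p)))
        rnd.shuffle(order)
        q_shuffled = bh_adjust([p[i] for i in order])
        for pos, i in enumerate(order):
            assert q_shuffled[pos] == pytest.approx(q[i])
        for i in range(len(p)):
            for j in range(len(p)):
                if p[i] < p[j]:
                    assert q[i] <= q[j] + 1e-15
        assert all(0 <= x <= 1 for x in q)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = list(rng.random(40))
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(list(q_sm))


class TestGoEnrichment:
    def test_small_worked_example(self):
        # N=10, K=5, n=2, k=2 → p = C(5,2)/C(10,2) = 10/45
        background = [f"g{i}" for i in range(10)]
        ann = make_annotations({"GO:1": background[:5]}, background)
        rows = go_enrichment(background[:2], ann)
        assert len(rows) == 1
        row = rows[0]
        assert (row.k, row.n, row.K, row.N) == (2, 2, 5, 10)
        assert row.p == pytest.approx(10 / 45, abs=1e-12)

    def test_zero_overlap_terms_excluded(self):
        background = [f"g{i}" for i in range(10)]
        ann = make_annotations(
            {"GO:1": background[:3], "GO:2": background[5:]}, background
        )
        rows = go_enrichment(background[:2], ann)
        assert [r.term_id for r in rows] == ["GO:1"]

    def test_significance_flag(self):
        background = [f"g{i}" for i in range(50)]
        ann = make_annotations({"GO:1": background[:5]}, background)
        rows = go_enrichment(background[:5], ann)
        assert rows[0].q < 0.05
        assert rows[0].significant

    def test_outside_background_dropped_with_warning(self, caplog):
        background = ["a", "b", "c", "d"]
        ann = make_annotations({"GO:1": ["a", "b"]}, background)
        with caplog.at_level("WARNING"):
            rows = go_enrichment(["a", "zzz"], ann)
        assert rows[0].n == 1
        assert any("outside background" in r.message for r in caplog.records)

    def test_empty_effective_query(self, caplog):
        ann = make_annotations({"GO:1": ["a"]}, ["a", "b"])
        with caplog.at_level("WARNING"):
            assert go_enrichment(["zzz"], ann) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_p_matches_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        background = [f"g{i}" for i in range(30)]
        terms = {
            f"GO:{t}": list(
                rng.choice(background, size=int(rng.integers(2, 15)), replace=False)
            )
            for t in range(6)
        }
        ann = make_annotations(terms, background)
        query = list(rng.choice(background, size=8, replace=False))
        for row in go_enrichment(query, ann):
            expected = hypergeom_tail_oracle(row.k, row.N, row.K, row.n)
            assert row.p == pytest.approx(expected, abs=1e-12)

    def test_rows_sorted_by_q_then_p_then_term(self):
        rng = np.random.default_rng(4)
        background = [f"g{i}" for i in range(40)]
        terms = {
            f"GO:{t}": list(
                rng.choice(background, size=int(rng.integers(2, 20)), replace=False)
            )
            for t in range(8)
        }
        ann = make_annotations(terms, background)
        rows = go_enrichment(list(background[:10]), ann)
        keys = [(r.q, r.p, r.term_id) for r in rows]
        assert keys == sorted(keys)

    def test_null_simulation_conservative(self):
        # uniform random queries: raw p<0.05 rate stays within the
        # conservative bound for the discrete test
        rng = np.random.default_rng(123)
        background = [f"g{i}" for i in range(60)]
        terms = {
            f"GO:{t}": list(
                rng.choice(background, size=int(rng.integers(3, 30)), replace=False)
            )
            for t in range(12)
        }
        ann = make_annotations(terms, background)
        n_hits = 0
        n_tests = 0
        reps = 300
        for _ in range(reps):
            query = list(rng.choice(background, size=10, replace=False))
            for row in go_enrichment(query, ann):
                n_tests += 1
                if row.p < 0.05:
                    n_hits += 1
        rate = n_hits / n_tests
        bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_tests)
        assert rate <= bound

    def test_annotated_genes_must_be_in_background(self):
        with pytest.raises(ValueError):
            AnnotationSet(gene_to_terms={"a": {"GO:1"}}, background={"b"})

    def test_from_tsv(self, tmp_path):
        (tmp_path / "ann.tsv").write_text("a\tGO:1\na\tGO:2\nb\tGO:1\n")
        (tmp_path / "names.tsv").write_text("GO:1\tthing one\nGO:2\tthing two\n")
        ann = AnnotationSet.from_tsv(tmp_path / "ann.tsv", tmp_path / "names.tsv")
        assert ann.gene_to_terms == {"a": {"GO:1", "GO:2"}, "b": {"GO:1"}}
        assert ann.term_to_genes["GO:1"] == {"a", "b"}
        assert ann.term_names["GO:2"] == "thing two"


GENE_DICT = Dictionary(
    entries=[
        ("SRC", "SRC", "gene"),
        ("IL6", "IL6", "gene"),
        ("STAT3", "STAT3", "gene"),
        ("interleukin 6", "IL6", "gene"),
        ("interleukin 6 receptor", "IL6R", "gene"),
        ("ATP", "CHEBI:15422", "chemical"),
    ]
)


class TestAnnotateText:
    def test_empty_text(self):
        assert annotate_text("", GENE_DICT) == []

    def test_two_gene_mentions_with_offsets(self):
        text = "SRC activates IL6"
        mentions = annotate_text(text, GENE_DICT)
        assert [(m.start, m.end, m.concept_id) for m in mentions] == [
            (0, 3, "SRC"),
            (14, 17, "IL6"),
        ]
        for m in mentions:
            assert m.surface == text[m.start : m.end]

    def test_leftmost_longest(self):
        text = "the interleukin 6 receptor signals"
        mentions = annotate_text(text, GENE_DICT)
        assert len(mentions) == 1
        assert mentions[0].concept_id == "IL6R"
        assert mentions[0].surface == "interleukin 6 receptor"

    def test_short_symbols_case_sensitive(self):
        assert annotate_text("src is lowercase", GENE_DICT) == []
        assert len(annotate_text("SRC is uppercase", GENE_DICT)) == 1

    def test_long_terms_case_insensitive(self):
        mentions = annotate_text("Interleukin 6 is elevated", GENE_DICT)
        assert [m.concept_id for m in mentions] == ["IL6"]

    def test_token_boundaries_respected(self):
        # SRC inside a longer token must not match
        assert annotate_text("OSRCA and ILSRC6", GENE_DICT) == []

    def test_no_overlaps_and_sorted(self):
        text = "STAT3 SRC interleukin 6 receptor IL6 SRC"
        mentions = annotate_text(text, GENE_DICT)
        starts = [m.start for m in mentions]
        assert starts == sorted(starts)
        for a, b in zip(mentions, mentions[1:]):
            assert a.end <= b.start

    def test_brute_force_scan_oracle(self):
        text = "IL6 and SRC and STAT3; also IL6."
        mentions = annotate_text(text, GENE_DICT)
        expected = []
        for term in ("IL6", "SRC", "STAT3"):
            start = 0
            while True:
                i = text.find(term, start)
                if i == -1:
                    break
                expected.append((i, i + len(term), term))
                start = i + 1
        assert sorted((m.start, m.end, m.concept_id) for m in mentions) == sorted(
            expected
        )


class TestEntityCloud:
    def test_counts(self):
        texts = ["IL6 IL6 and SRC", "IL6 again"]
        cloud = entity_cloud(texts, GENE_DICT, entity_type="gene")
        assert cloud == {"IL6": 3, "SRC": 1}
        assert list(cloud) == ["IL6", "SRC"]  # descending count order

    def test_type_filter(self):
        cloud = entity_cloud(["ATP and SRC"], GENE_DICT, entity_type="chemical")
        assert cloud == {"CHEBI:15422": 1}

    def test_empty_table(self):
        assert entity_cloud(EnrichmentTable(rows={}), GENE_DICT) == {}

    def test_additivity(self):
        texts = ["SRC IL6", "STAT3", "IL6 interleukin 6"]
        total = entity_cloud(texts, GENE_DICT, entity_type="gene")
        summed: dict[str, int] = {}
        for t in texts:
            for concept, count in entity_cloud([t], GENE_DICT, entity_type="gene").items():
                summed[concept] = summed.get(concept, 0) + count
        assert total == summed


class TestSemanticExpand:
    def make_table(self):
        return EnrichmentTable(
            rows={
                "SRC": {"ncbi": "SRC activates IL6 and STAT3 signaling."},
                "IL6": {"ncbi": "IL6 binds its receptor."},
                "STAT3": {"ncbi": "STAT3 is a transcription factor."},
            }
        )

    def test_fixed_point_when_no_new_genes(self):
        table = EnrichmentTable(rows={"IL6": {"ncbi": "IL6 binds its receptor."}})
        assert semantic_expand({"IL6"}, table, GENE_DICT) == {"IL6"}

    def test_one_step_closure(self):
        assert semantic_expand({"SRC"}, self.make_table(), GENE_DICT, 1) == {
            "SRC",
            "IL6",
            "STAT3",
        }

    def test_monotone_and_stable_at_closure(self):
        table = self.make_table()
        prev = {"SRC"}
        for i in range(1, 5):
            cur = semantic_expand({"SRC"}, table, GENE_DICT, i)
            assert prev <= cur
            prev = cur
        assert semantic_expand({"SRC"}, table, GENE_DICT, 50) == prev

    def test_iterations_validated(self):
        with pytest.raises(ValueError):
            semantic_expand({"SRC"}, self.make_table(), GENE_DICT, 0)


class TestEnrichmentTableIO:
    def test_round_trip(self, tmp_path):
        table = EnrichmentTable(
            rows={
                "SRC": {
                    "ncbi": "text",
                    "ncbi_url": "u",
                    "uniprot": "",
                    "uniprot_url": "",
                    "stringdb": "",
                    "stringdb_url": "",
                    "go": "",
                    "go_url": "",
                }
            }
        )
        table.to_tsv(tmp_path / "t.tsv")
        loaded = EnrichmentTable.from_tsv(tmp_path / "t.tsv")
        assert loaded.rows["SRC"]["ncbi"] == "text"
        assert loaded.rows["SRC"]["go"] == ""  # missing sources as empty strings

    def test_missing_gene_column(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("name\tncbi\nSRC\tx\n")
        with pytest.raises(ValueError, match="gene"):
            EnrichmentTable.from_tsv(tmp_path / "bad.tsv")
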