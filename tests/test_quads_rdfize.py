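"""N-Quads round trips, dataset statistics and the RDFization laws."""

import random

import pytest
from hypothesis import given, strategies as st
from rdflib import Literal, URIRef
from rdflib.namespace import XSD

from omicsfed.quads import (
    Quad,
    QuadError,
    dataset_stats,
    quad_multiset,
    read_nquads,
    write_nquads,
)
from omicsfed.rdfize import (
    MappingError,
    MintError,
    build_dataset,
    default_mapping,
    extract_rows,
    mint_iri,
    rdfize_table,
    record_roles,
)
from omicsfed.records import ExpressionRecord, Locus, MethylationRecord
from omicsfed.tables import TableSchema, read_table


def random_quads(n, seed=0):
    rng = random.Random(seed)
    quads = []
    for i in range(n):
        obj = (
            URIRef(f"http://ex/o/{rng.randrange(20)}")
            if rng.random() < 0.5
            else Literal(rng.randrange(100))
        )
        quads.append(
            Quad(
                URIRef(f"http://ex/s/{rng.randrange(15)}"),
                URIRef(f"http://ex/p/{rng.randrange(5)}"),
                obj,
                URIRef(f"http://ex/g/{rng.randrange(3)}"),
            )
        )
    return quads


class TestNQuadsRoundTrip:
    def test_empty_stream(self, tmp_path):
        p = tmp_path / "empty.nq"
        write_nquads([], p)
        assert read_nquads(p) == []

    def test_multiset_identity_random_quads(self, tmp_path):
        quads = random_quads(100)
        p = tmp_path / "q.nq"
        write_nquads(quads, p)
        # stores deduplicate, so compare distinct sets both ways
        assert set(read_nquads(p)) == set(quads)

    def test_typed_literal_preserved(self, tmp_path):
        q = Quad(
            URIRef("http://ex/s"), URIRef("http://ex/p"),
            Literal("23904678", datatype=XSD.integer), URIRef("http://ex/g"),
        )
        p = tmp_path / "t.nq"
        write_nquads([q], p)
        (back,) = read_nquads(p)
        assert back.object.datatype == XSD.integer
        assert back.object.toPython() == 23904678

    def test_malformed_iri_rejected(self, tmp_path):
        bad = Quad(URIRef("no-scheme"), URIRef("http://ex/p"),
                   Literal("x"), URIRef("http://ex/g"))
        with pytest.raises(QuadError):
            write_nquads([bad], tmp_path / "bad.nq")


class TestDatasetStats:
    def test_empty(self):
        st_ = dataset_stats([])
        assert (st_.n_triples, st_.n_subjects, st_.n_predicates, st_.n_objects) == (0, 0, 0, 0)

    def test_closed_layout(self):
        g = URIRef("http://ex/g")
        quads = [
            Quad(URIRef(f"http://ex/s{s}"), URIRef(f"http://ex/p{p}"),
                 Literal(f"{s}-{p}"), g)
            for s in range(2)
            for p in range(3)
        ]
        st_ = dataset_stats(quads)
        assert (st_.n_triples, st_.n_subjects, st_.n_predicates, st_.n_objects) == (6, 2, 3, 6)

    def test_duplicate_quads_counted_once(self):
        q = random_quads(1)[0]
        assert dataset_stats([q, q]).n_triples == 1

    @given(st.integers(0, 300), st.integers(0, 2**31 - 1))
    def test_equals_bruteforce_distinct_count(self, n, seed):
        quads = random_quads(n, seed)
        st_ = dataset_stats(quads)
        distinct = set(quads)
        assert st_.n_triples == len(distinct)
        assert st_.n_subjects == len({q.subject for q in distinct})
        assert st_.n_predicates == len({q.predicate for q in distinct})
        assert st_.n_objects == len({q.object for q in distinct})


class TestMintIri:
    def test_deterministic(self):
        a = mint_iri("http://ex/cosmic/", "gene", "MYH7")
        b = mint_iri("http://ex/cosmic/", "gene", "MYH7")
        assert a == b

    def test_distinct_keys_distinct_iris(self):
        assert mint_iri("http://ex/", "gene", "MYH7") != mint_iri("http://ex/", "gene", "MYH6")

    def test_unsafe_characters_percent_encoded(self):
        iri = str(mint_iri("http://ex/", "sample", "TCGA 13:0920/x"))
        assert " " not in iri and iri.count(":") == 1  # only the scheme colon
        assert iri.startswith("http://ex/sample/")

    def test_empty_key_rejected(self):
        with pytest.raises(MintError):
            mint_iri("http://ex/", "gene", "")


class TestRdfizeLaws:
    def _methyl_records(self, n=2):
        return [
            MethylationRecord(
                gene_symbol=f"G{i}", composite_element_ref=f"cg{i:08d}",
                locus=Locus("14", 100 + i, 200 + i), beta_value=0.1 * i,
            )
            for i in range(n)
        ]

    def test_zero_records_zero_quads(self):
        assert rdfize_table([], default_mapping("cosmic", "methylation")) == []

    def test_closed_form_quad_count(self):
        # 2 records x 3 populated roles -> 2 * (3 + 1) = 8 quads, 2 subjects
        recs = [ExpressionRecord(f"G{i}", "heart", 1.0) for i in range(2)]
        quads = rdfize_table(recs, default_mapping("cosmic", "expression"))
        assert len(quads) == 8
        assert len({q.subject for q in quads}) == 2
        # general law on a mixed table
        recs2 = self._methyl_records(5)
        quads2 = rdfize_table(recs2, default_mapping("tcga", "methylation", "OV"))
        assert len(quads2) == sum(1 + len(record_roles(r)) for r in recs2)

    def test_deterministic_across_runs(self):
        recs = self._methyl_records(4)
        m = default_mapping("cosmic", "methylation")
        assert quad_multiset(rdfize_table(recs, m)) == quad_multiset(rdfize_table(recs, m))

    def test_beta_value_emitted_as_typed_literal(self):
        rec = MethylationRecord(
            "MYH7", "cg05744229", Locus("14", 23435469, 23435669),
            beta_value=0.041999536,
        )
        quads = rdfize_table([rec], default_mapping("cosmic", "methylation"))
        betas = [q.object for q in quads if str(q.predicate).endswith("beta_value")]
        assert len(betas) == 1 and betas[0].toPython() == 0.041999536

    def test_unmapped_populated_role_raises(self):
        m = default_mapping("cosmic", "expression")
        pruned = type(m)(
            base_iri=m.base_iri, graph_iri=m.graph_iri, type_iri=m.type_iri,
            predicate_map={k: v for k, v in m.predicate_map.items() if k != "value"},
        )
        with pytest.raises(MappingError, match="value"):
            rdfize_table([ExpressionRecord("G", "heart", 1.0)], pruned)

    def test_losslessness_via_inverse_mapping(self):
        recs = self._methyl_records(3)
        m = default_mapping("cosmic", "methylation")
        rows = extract_rows(rdfize_table(recs, m), m)
        assert rows == [
            {k: (float(v) if k == "beta_value" else v)
             for k, v in record_roles(r).items()}
            for r in recs
        ]

    def test_tsv_records_quads_roundtrip(self, tmp_path):
        """TSV -> records -> quads -> rows preserves every mapped field."""
        p = tmp_path / "meth.tsv"
        p.write_text(
            "Gene Symbol\tComposite Element REF\tChromosome\tStart\tEnd\t"
            "Beta_Value\tTumour_Purity\n"
            "MYH7\tcg05744229\t14\t23435469\t23435669\t0.041999536\t773.555\n"
            "MYH6\tcg00000292\tchr14\t23861000\t23861200\t-0.12\t512\n"
        )
        schema = TableSchema(
            kind="methylation",
            columns={
                "Gene Symbol": "gene_symbol",
                "Composite Element REF": "composite_element_ref",
                "Chromosome": "chrom", "Start": "start", "End": "end",
                "Beta_Value": "beta_value", "Tumour_Purity": "tumour_purity",
            },
        )
        recs = read_table(p, schema).records
        m = default_mapping("cosmic", "methylation")
        rows = extract_rows(rdfize_table(recs, m), m)
        assert rows[0]["beta_value"] == 0.041999536
        assert rows[0]["gene_symbol"] == "MYH7"
        assert rows[1]["chrom"] == "14"  # normalized at the boundary
        assert rows[1]["start"] == 23861000


class TestBuildDataset:
    def test_single_table_stats_match(self):
        recs = [ExpressionRecord("G1", "heart", 2.0)]
        m = default_mapping("cosmic", "expression")
        graphs, stats = build_dataset([(recs, m)])
        from omicsfed.quads import dataset_stats as ds
        assert stats[m.graph_iri] == ds(graphs[m.graph_iri])

    def test_disjoint_graphs_are_additive(self):
        m1 = default_mapping("cosmic", "expression")
        m2 = default_mapping("tcga", "expression", "OV")
        r1 = [ExpressionRecord("G1", "heart", 2.0)]
        r2 = [ExpressionRecord("G2", "s-01A", 3.0), ExpressionRecord("G3", "s-01A", 4.0)]
        graphs, stats = build_dataset([(r1, m1), (r2, m2)])
        total = sum(len(q) for q in graphs.values())
        assert total == stats[m1.graph_iri].n_triples + stats[m2.graph_iri].n_triples

    def test_empty_table_list(self):
        assert build_dataset([]) == ({}, {})

    def test_duplicate_graph_iri_rejected(self):
        m = default_mapping("cosmic", "expression")
        with pytest.raises(MappingError, match="duplicate"):
            build_dataset([([], m), ([], m)])
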