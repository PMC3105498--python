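"""RDF backbone: parsing, serialization, SPARQL subset, isomorphism."""

import io

import numpy as np
import pytest

from chemrdf import vocabulary as voc
from chemrdf.rdf_core import (
    BlankNode,
    IRI,
    Literal,
    RdfParseError,
    SelectStarError,
    TripleStore,
    UnsupportedSparqlError,
    isomorphic,
    parse_rdf,
    query,
    select_variables,
    serialize_rdf,
)

from conftest import random_store, relabel_bnodes
from oracles import bgp_solutions, isomorphic_by_permutation


class TestParse:
    def test_molecule_fixture_is_typed_as_molecule(self, methoxymethane_store):
        """The fixture's resource is recognizable as a molecule by its type."""
        mols = methoxymethane_store.subjects(voc.RDF_TYPE, voc.CG_MOLECULE)
        assert mols == [IRI("http://example.com/mol1")]

    def test_empty_document(self):
        assert len(parse_rdf("")) == 0

    def test_prefixes_captured(self):
        store = parse_rdf("@prefix ex: <http://ex.org/> . ex:a ex:p ex:b .")
        assert store.prefixes["ex"] == "http://ex.org/"

    def test_syntax_error_reports_line(self):
        with pytest.raises(RdfParseError) as err:
            parse_rdf("@prefix ex: <http://ex.org/> .\nex:a ex:p .\n")
        assert err.value.line is not None

    def test_literal_forms_survive(self):
        store = parse_rdf(
            '@prefix ex: <http://ex.org/> . '
            'ex:a ex:p "plain", "5"^^<http://www.w3.org/2001/XMLSchema#integer>, '
            '"hej"@sv .')
        objs = set(store.objects(IRI("http://ex.org/a"), IRI("http://ex.org/p")))
        assert Literal("plain") in objs
        assert Literal("5", datatype=f"{voc.XSD_INTEGER[:-7]}integer") in objs \
            or any(o.datatype and o.datatype.endswith("integer") for o in objs)
        assert Literal("hej", lang="sv") in objs


class TestSerialize:
    def test_empty_store(self):
        text = serialize_rdf(TripleStore())
        assert parse_rdf(text).triples == set()

    def test_single_triple_single_statement(self):
        store = TripleStore(prefixes={"ex": "http://ex.org/"})
        store.add(IRI("http://ex.org/a"), IRI("http://ex.org/p"),
                  IRI("http://ex.org/b"))
        statements = [
            line for line in serialize_rdf(store).splitlines()
            if line and not line.startswith("@prefix")
        ]
        assert len(statements) == 1

    def test_prefix_lines_emitted(self):
        store = TripleStore(prefixes={"ex": "http://ex.org/"})
        assert "@prefix ex: <http://ex.org/> ." in serialize_rdf(store)

    @pytest.mark.parametrize("fixture_name", [
        "methoxymethane_store", "protonated_methanol_store",
        "tpsa_result_store", "nmr_spectrum_store",
    ])
    def test_fixture_round_trip_isomorphic(self, fixture_name, request):
        store = request.getfixturevalue(fixture_name)
        assert isomorphic(store, parse_rdf(serialize_rdf(store)))

    def test_random_store_round_trips(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            store = random_store(rng)
            again = parse_rdf(serialize_rdf(store))
            assert isomorphic(store, again)

    def test_serialization_is_deterministic(self):
        a = random_store(np.random.default_rng(3))
        b = random_store(np.random.default_rng(3))
        assert serialize_rdf(a) == serialize_rdf(b)


class TestQuery:
    def test_distinct_predicates(self):
        """The all-predicates survey query deduplicates repeated predicates."""
        store = TripleStore(prefixes={"ex": "http://ex.org/"})
        p, q = IRI("http://ex.org/p"), IRI("http://ex.org/q")
        store.add(IRI("http://ex.org/a"), p, IRI("http://ex.org/b"))
        store.add(IRI("http://ex.org/c"), p, IRI("http://ex.org/d"))
        store.add(IRI("http://ex.org/a"), q, IRI("http://ex.org/b"))
        result = query(
            store, "SELECT DISTINCT ?predicate WHERE { [] ?predicate [] }")
        assert len(result) == 2
        assert {row["predicate"] for row in result.rows} == {p, q}

    def test_empty_store_zero_rows(self):
        result = query(TripleStore(), "SELECT ?s WHERE { ?s ?p ?o }")
        assert len(result) == 0

    def test_bgp_join_matches_brute_force(self):
        """Two-pattern joins agree with exhaustive binding enumeration."""
        rng = np.random.default_rng(7)
        sparql = (
            "SELECT ?x ?y ?z WHERE { "
            "?x <http://ex.org/p0> ?y . ?y <http://ex.org/p1> ?z }")
        patterns = [
            ("?x", IRI("http://ex.org/p0"), "?y"),
            ("?y", IRI("http://ex.org/p1"), "?z"),
        ]
        checked_nonempty = 0
        for _ in range(20):
            store = random_store(rng, n_triples=10, n_bnodes=0)
            expected = bgp_solutions(store.triples, patterns)
            got = {
                frozenset(("?" + v, row[v]) for v in result.variables)
                for result in [query(store, sparql)]
                for row in result.rows
            }
            assert got == expected
            checked_nonempty += bool(expected)
        assert checked_nonempty > 0  # the oracle actually saw joins

    def test_results_independent_of_insertion_order(self):
        rng = np.random.default_rng(11)
        store = random_store(rng, n_triples=15, n_bnodes=0)
        triples = sorted(store.triples, key=repr)
        forward = TripleStore(triples, prefixes=store.prefixes)
        backward = TripleStore(reversed(triples), prefixes=store.prefixes)
        sparql = "SELECT ?s ?o WHERE { ?s <http://ex.org/p0> ?o }"

        def rows(st):
            return {tuple(r[v] for v in res.variables)
                    for res in [query(st, sparql)] for r in res.rows}

        assert rows(forward) == rows(backward)

    def test_distinct_never_increases_rows(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            store = random_store(rng, n_triples=12, n_bnodes=0)
            plain = query(store, "SELECT ?p WHERE { ?s ?p ?o }")
            distinct = query(store, "SELECT DISTINCT ?p WHERE { ?s ?p ?o }")
            assert len(distinct) <= len(plain)

    def test_filter_and_optional_and_limit(self):
        store = parse_rdf(
            '@prefix ex: <http://ex.org/> . '
            'ex:a ex:v "3"^^<http://www.w3.org/2001/XMLSchema#integer> . '
            'ex:b ex:v "9"^^<http://www.w3.org/2001/XMLSchema#integer> . '
            'ex:a ex:name "alpha" .')
        result = query(store, """
            SELECT ?s ?name WHERE {
                ?s <http://ex.org/v> ?v .
                OPTIONAL { ?s <http://ex.org/name> ?name }
                FILTER (?v > 5)
            }""")
        assert len(result) == 1
        assert result.rows[0]["s"] == IRI("http://ex.org/b")
        assert result.rows[0]["name"] is None
        limited = query(store, "SELECT ?s WHERE { ?s ?p ?o } LIMIT 1")
        assert len(limited) == 1

    def test_regex_filter(self):
        store = parse_rdf(
            '@prefix ex: <http://ex.org/> . '
            'ex:a ex:l6 "Sodium channel" . ex:b ex:l6 "Calcium channel" .')
        result = query(store, """
            SELECT ?s WHERE { ?s <http://ex.org/l6> ?x
                              FILTER regex(?x, "Sodium") }""")
        assert [row["s"] for row in result.rows] == [IRI("http://ex.org/a")]

    @pytest.mark.parametrize("bad", [
        "SELECT ?s WHERE { { ?s ?p ?o } UNION { ?o ?p ?s } }",
        "SELECT ?s WHERE { ?s ?p ?o } ORDER BY ?s",
        "SELECT (COUNT(?s) AS ?n) WHERE { ?s ?p ?o }",
        "SELECT ?s WHERE { GRAPH ?g { ?s ?p ?o } }",
        "ASK { ?s ?p ?o }",
        "this is not sparql",
    ])
    def test_unsupported_features_fail_loudly(self, bad):
        with pytest.raises(UnsupportedSparqlError):
            query(TripleStore(), bad)

    def test_csv_export_with_unbound_cells(self):
        store = parse_rdf(
            '@prefix ex: <http://ex.org/> . ex:a ex:v "1" .')
        result = query(store, """
            SELECT ?s ?name WHERE {
                ?s <http://ex.org/v> ?v .
                OPTIONAL { ?s <http://ex.org/name> ?name } }""")
        buf = io.StringIO()
        result.to_csv(buf)
        lines = buf.getvalue().strip().splitlines()
        assert lines[0] == "s,name"
        assert lines[1] == "http://ex.org/a,"


class TestSelectVariables:
    def test_trivial_projection(self):
        assert select_variables("SELECT ?x WHERE { ?x ?p ?o }") == ["x"]

    def test_order_preserved(self):
        sparql = "SELECT ?b ?a ?c WHERE { ?a ?b ?c }"
        assert select_variables(sparql) == ["b", "a", "c"]

    def test_star_rejected(self):
        with pytest.raises(SelectStarError):
            select_variables("SELECT * WHERE { ?s ?p ?o }")


class TestIsomorphism:
    def test_store_equals_itself(self, protonated_methanol_store):
        assert isomorphic(protonated_methanol_store, protonated_methanol_store)

    def test_literal_difference_detected(self):
        a = parse_rdf('@prefix ex: <http://ex.org/> . ex:a ex:p "1" .')
        b = parse_rdf('@prefix ex: <http://ex.org/> . ex:a ex:p "2" .')
        assert not isomorphic(a, b)

    def test_blank_node_relabelling_is_isomorphic(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            store = random_store(rng, n_triples=10, n_bnodes=4)
            assert isomorphic(store, relabel_bnodes(store))

    def test_agrees_with_permutation_oracle(self):
        """Backtracking search matches exhaustive permutation on small graphs."""
        rng = np.random.default_rng(19)
        for _ in range(20):
            a = random_store(rng, n_triples=8, n_bnodes=3)
            b = relabel_bnodes(a)
            if rng.random() < 0.5 and b.triples:
                # corrupt one triple to produce genuine negatives
                victim = sorted(b.triples, key=repr)[0]
                b.triples.discard(victim)
                b.add(victim[0], victim[1], Literal("corrupted"))
            assert isomorphic(a, b) == isomorphic_by_permutation(a, b)
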