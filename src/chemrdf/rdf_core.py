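"""Minimal RDF backbone: triple storage, Turtle/Notation3 I/O, SPARQL SELECT.

The in-memory :class:`TripleStore` is the exchange unit for every other module:
chemical graphs, descriptor provenance, synthetic bioactivity databases and NMR
spectra all serialize to and from it.  Parsing, Turtle writing and SPARQL
evaluation are delegated to rdflib behind this module's own types and error
contract; only a declared subset of SPARQL SELECT is accepted, and anything
outside it raises :class:`UnsupportedSparqlError` rather than risking a silent
wrong answer.  Blank-node graph isomorphism (the round-trip test oracle) is a
native backtracking bijection search.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

import rdflib
from rdflib.plugins.sparql import prepareQuery
from rdflib.plugins.sparql.parserutils import CompValue

__all__ = [
    "IRI",
    "BlankNode",
    "Literal",
    "Triple",
    "TripleStore",
    "ResultTable",
    "RdfParseError",
    "UnsupportedSparqlError",
    "SelectStarError",
    "parse_rdf",
    "serialize_rdf",
    "query",
    "select_variables",
    "isomorphic",
]

XSD = "http://www.w3.org/2001/XMLSchema#"


@dataclass(frozen=True, order=True)
class IRI:
    """An absolute IRI reference."""

    value: str

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True, order=True)
class BlankNode:
    """A blank node, identified by a store-local label."""

    label: str

    def __str__(self) -> str:
        return f"_:{self.label}"


@dataclass(frozen=True, order=True)
class Literal:
    """An RDF literal with optional datatype IRI or language tag."""

    value: str
    datatype: Optional[str] = None
    lang: Optional[str] = None

    def __str__(self) -> str:
        return self.value


Node = Union[IRI, BlankNode, Literal]
Triple = tuple  # (subject, predicate, object) of Node; predicate always IRI


class RdfParseError(ValueError):
    """Raised when a Turtle/Notation3 document is syntactically invalid."""

    def __init__(self, message: str, line: Optional[int] = None):
        super().__init__(message)
        self.line = line


class UnsupportedSparqlError(ValueError):
    """Raised for SPARQL features outside the supported SELECT subset."""


class SelectStarError(ValueError):
    """Raised when ``SELECT *`` is used where explicit projection is required."""


class TripleStore:
    """A duplicate-free set of triples plus a prefix map.

    Mirrors the contract of an in-memory RDF store: insertion order is
    irrelevant, duplicate assertions collapse, prefixes are remembered for
    round-trip serialization.
    """

    def __init__(
        self,
        triples: Iterable[Triple] = (),
        prefixes: Optional[dict[str, str]] = None,
    ):
        self.triples: set[Triple] = set()
        self.prefixes: dict[str, str] = dict(prefixes or {})
        for t in triples:
            self.add(*t)

    def add(self, subject: Node, predicate: IRI, obj: Node) -> None:
        if not isinstance(predicate, IRI):
            raise TypeError("predicate must be an IRI")
        if isinstance(subject, Literal):
            raise TypeError("literal may not appear in subject position")
        self.triples.add((subject, predicate, obj))

    def bind(self, prefix: str, namespace: str) -> None:
        self.prefixes[prefix] = namespace

    def update(self, other: "TripleStore") -> None:
        self.triples |= other.triples
        for p, ns in other.prefixes.items():
            self.prefixes.setdefault(p, ns)

    def matching(
        self,
        subject: Optional[Node] = None,
        predicate: Optional[IRI] = None,
        obj: Optional[Node] = None,
    ) -> Iterator[Triple]:
        """Iterate triples matching a (s, p, o) pattern; None is a wildcard."""
        for s, p, o in self.triples:
            if subject is not None and s != subject:
                continue
            if predicate is not None and p != predicate:
                continue
            if obj is not None and o != obj:
                continue
            yield (s, p, o)

    def objects(self, subject: Node, predicate: IRI) -> list[Node]:
        return [o for _, _, o in self.matching(subject, predicate)]

    def object(self, subject: Node, predicate: IRI) -> Optional[Node]:
        objs = self.objects(subject, predicate)
        return objs[0] if objs else None

    def subjects(self, predicate: IRI, obj: Node) -> list[Node]:
        return [s for s, _, _ in self.matching(None, predicate, obj)]

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.triples


@dataclass
class ResultTable:
    """SPARQL SELECT solutions: ordered variables and per-row bindings."""

    variables: list[str]
    rows: list[dict[str, Optional[Node]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, variable: str) -> list[Optional[Node]]:
        if variable not in self.variables:
            raise KeyError(variable)
        return [row.get(variable) for row in self.rows]

    def to_csv(self, path_or_buf) -> None:
        """Write one column per variable; unbound cells are left empty."""

        def cell(v: Optional[Node]) -> str:
            if v is None:
                return ""
            return str(v)

        close = False
        if isinstance(path_or_buf, (str, bytes)):
            handle = open(path_or_buf, "w", newline="")
            close = True
        else:
            handle = path_or_buf
        try:
            writer = csv.writer(handle)
            writer.writerow(self.variables)
            for row in self.rows:
                writer.writerow([cell(row.get(v)) for v in self.variables])
        finally:
            if close:
                handle.close()


# --- conversion between our node model and rdflib terms ---------------------


def _to_rdflib(node: Node) -> rdflib.term.Node:
    if isinstance(node, IRI):
        return rdflib.URIRef(node.value)
    if isinstance(node, BlankNode):
        return rdflib.BNode(node.label)
    if isinstance(node, Literal):
        return rdflib.Literal(
            node.value,
            datatype=rdflib.URIRef(node.datatype) if node.datatype else None,
            lang=node.lang,
        )
    raise TypeError(f"not an RDF node: {node!r}")


def _from_rdflib(term: rdflib.term.Node) -> Node:
    if isinstance(term, rdflib.URIRef):
        return IRI(str(term))
    if isinstance(term, rdflib.BNode):
        return BlankNode(str(term))
    if isinstance(term, rdflib.Literal):
        return Literal(
            str(term),
            datatype=str(term.datatype) if term.datatype else None,
            lang=term.language,
        )
    raise TypeError(f"unexpected rdflib term: {term!r}")


def _to_graph(store: TripleStore) -> rdflib.Graph:
    g = rdflib.Graph()
    for prefix, ns in store.prefixes.items():
        g.bind(prefix, ns, override=True, replace=True)
    for s, p, o in store.triples:
        g.add((_to_rdflib(s), _to_rdflib(p), _to_rdflib(o)))
    return g


def _from_graph(g: rdflib.Graph) -> TripleStore:
    store = TripleStore()
    for prefix, ns in g.namespaces():
        # rdflib pre-binds a handful of core namespaces; keep them, they are valid.
        store.prefixes[prefix] = str(ns)
    for s, p, o in g:
        store.add(_from_rdflib(s), _from_rdflib(p), _from_rdflib(o))
    return store


# --- parse / serialize -------------------------------------------------------


def parse_rdf(text: str, base: str = "http://example.org/") -> TripleStore:
    """Parse a Turtle/Notation3 document into a :class:`TripleStore`.

    Raises
    ------
    RdfParseError
        On syntax errors, carrying the offending line number when known.
    """
    g = rdflib.Graph()
    try:
        g.parse(data=text, format="n3", publicID=base)
    except Exception as exc:  # rdflib raises notation3.BadSyntax
        line = getattr(exc, "lines", None)
        line = line + 1 if isinstance(line, int) else None
        raise RdfParseError(f"RDF syntax error: {exc}", line=line) from exc
    return _from_graph(g)


_PN_LOCAL = __import__("re").compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")


def _turtle_term(node: Node, prefixes: dict[str, str]) -> str:
    if isinstance(node, IRI):
        # Longest-namespace match first; order fixed for determinism.
        for prefix, ns in sorted(prefixes.items(), key=lambda kv: (-len(kv[1]), kv[0])):
            if node.value.startswith(ns):
                local = node.value[len(ns):]
                if local and _PN_LOCAL.match(local) and not local.endswith("."):
                    return f"{prefix}:{local}"
        return f"<{node.value}>"
    if isinstance(node, BlankNode):
        return f"_:{node.label}"
    if isinstance(node, Literal):
        escaped = (
            node.value.replace("\\", "\\\\").replace('"', '\\"')
            .replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t")
        )
        out = f'"{escaped}"'
        if node.lang:
            out += f"@{node.lang}"
        elif node.datatype:
            out += "^^" + _turtle_term(IRI(node.datatype), prefixes)
        return out
    raise TypeError(f"not an RDF node: {node!r}")


def serialize_rdf(store: TripleStore) -> str:
    """Serialize to Turtle; output re-parses to an isomorphic store.

    The writer is deliberately deterministic (prefixes and triples in sorted
    order) so that equal stores serialize byte-identically — the synthetic
    generators rely on this for their reproducibility contract.
    """
    prefixes = dict(store.prefixes)
    lines = [
        f"@prefix {p}: <{ns}> ." for p, ns in sorted(prefixes.items())
    ]
    if lines:
        lines.append("")
    statements = sorted(
        (
            _turtle_term(s, prefixes),
            _turtle_term(p, prefixes),
            _turtle_term(o, prefixes),
        )
        for s, p, o in store.triples
    )
    lines += [f"{s} {p} {o} ." for s, p, o in statements]
    return "\n".join(lines) + "\n"


# --- SPARQL SELECT subset ----------------------------------------------------

_ALLOWED_ALGEBRA = {
    # query shells
    "SelectQuery",
    "Project",
    "Distinct",
    "Slice",  # LIMIT / OFFSET
    "ToMultiSet",
    # graph patterns
    "BGP",
    "Join",
    "Filter",
    "LeftJoin",  # OPTIONAL
    "TrueFilter",
    # filter expressions
    "RelationalExpression",
    "ConditionalAndExpression",
    "ConditionalOrExpression",
    "AdditiveExpression",
    "MultiplicativeExpression",
    "UnaryNot",
    "UnaryMinus",
    "UnaryPlus",
    "Builtin_REGEX",
    "Builtin_STR",
    "Builtin_BOUND",
}


def _check_supported(node) -> None:
    if isinstance(node, CompValue):
        if node.name not in _ALLOWED_ALGEBRA:
            raise UnsupportedSparqlError(
                f"SPARQL feature not supported by this store: {node.name}"
            )
        for value in node.values():
            _check_supported(value)
    elif isinstance(node, (list, tuple)):
        for value in node:
            _check_supported(value)
    # Variables, terms, sets of vars: fine.


def _prepare(sparql: str):
    try:
        return prepareQuery(sparql)
    except UnsupportedSparqlError:
        raise
    except Exception as exc:
        raise UnsupportedSparqlError(f"cannot parse SPARQL query: {exc}") from exc


def query(store: TripleStore, sparql: str) -> ResultTable:
    """Evaluate a SPARQL SELECT query over the store.

    Supported subset: basic graph patterns, DISTINCT, FILTER (comparisons,
    regex, boolean combinations), OPTIONAL, LIMIT.  Anything else raises
    :class:`UnsupportedSparqlError` — never a silently wrong answer.
    """
    prepared = _prepare(sparql)
    if prepared.algebra.name != "SelectQuery":
        raise UnsupportedSparqlError("only SELECT queries are supported")
    _check_supported(prepared.algebra)
    g = _to_graph(store)
    result = g.query(prepared)
    try:
        variables = select_variables(sparql)
    except SelectStarError:
        variables = [str(v) for v in (result.vars or [])]
    rows: list[dict[str, Optional[Node]]] = []
    for binding in result.bindings:
        row: dict[str, Optional[Node]] = {}
        for var in variables:
            term = binding.get(rdflib.term.Variable(var))
            row[var] = _from_rdflib(term) if term is not None else None
        rows.append(row)
    return ResultTable(variables=variables, rows=rows)


def select_variables(sparql: str) -> list[str]:
    """Return the projected variable names of a SELECT query, in order.

    ``SELECT *`` is rejected: this artifact requires explicit projection so
    that extracted dataset columns are predictable.
    """
    prepared = _prepare(sparql)
    if prepared.algebra.name != "SelectQuery":
        raise UnsupportedSparqlError("only SELECT queries are supported")
    # rdflib expands SELECT * into the pattern variables; detect the star
    # lexically (comments stripped) to honour the explicit-projection contract.
    lexical = "\n".join(
        line.split("#", 1)[0] for line in sparql.splitlines()
    )
    upper = lexical.upper()
    sel = upper.find("SELECT")
    brace = lexical.find("{", sel)
    head = lexical[sel:brace if brace != -1 else None]
    if "*" in head:
        raise SelectStarError("SELECT * requires implicit projection; "
                              "an explicit variable list is required")
    return [str(v) for v in prepared.algebra.PV]


# --- blank-node isomorphism --------------------------------------------------


def _bnode_signature(store_triples: set, bnode: BlankNode):
    """Order-invariant local signature used to prune the bijection search."""
    sig = []
    for s, p, o in store_triples:
        if s == bnode:
            other = o if not isinstance(o, BlankNode) else None
            sig.append(("s", p, other))
        if o == bnode:
            other = s if not isinstance(s, BlankNode) else None
            sig.append(("o", p, other))
    return tuple(sorted(sig, key=repr))


def isomorphic(a: TripleStore, b: TripleStore) -> bool:
    """True iff a blank-node bijection makes the two triple sets equal.

    Exhaustive backtracking search over candidate bijections, pruned by local
    blank-node signatures.  Intended for graphs with few blank nodes (the
    fixtures here have fewer than ten), where the search is instantaneous.
    """
    if len(a.triples) != len(b.triples):
        return False

    def split(store: TripleStore):
        ground, bnodey = set(), set()
        for t in store.triples:
            if isinstance(t[0], BlankNode) or isinstance(t[2], BlankNode):
                bnodey.add(t)
            else:
                ground.add(t)
        return ground, bnodey

    ground_a, bn_a = split(a)
    ground_b, bn_b = split(b)
    if ground_a != ground_b:
        return False

    def bnodes_of(triples) -> list[BlankNode]:
        seen: dict[BlankNode, None] = {}
        for s, _, o in sorted(triples, key=repr):
            for n in (s, o):
                if isinstance(n, BlankNode):
                    seen.setdefault(n)
        return list(seen)

    nodes_a = bnodes_of(bn_a)
    nodes_b = bnodes_of(bn_b)
    if len(nodes_a) != len(nodes_b):
        return False
    if not nodes_a:
        return bn_a == bn_b  # both empty

    sig_a = {n: _bnode_signature(bn_a, n) for n in nodes_a}
    sig_b = {n: _bnode_signature(bn_b, n) for n in nodes_b}
    candidates = {
        n: [m for m in nodes_b if sig_b[m] == sig_a[n]] for n in nodes_a
    }
    if any(not c for c in candidates.values()):
        return False
    # Assign scarcest-candidates first.
    order = sorted(nodes_a, key=lambda n: len(candidates[n]))

    def apply(mapping: dict[BlankNode, BlankNode]) -> set:
        def m(node):
            return mapping.get(node, node) if isinstance(node, BlankNode) else node

        return {(m(s), p, m(o)) for s, p, o in bn_a}

    used: set[BlankNode] = set()
    mapping: dict[BlankNode, BlankNode] = {}

    def backtrack(i: int) -> bool:
        if i == len(order):
            return apply(mapping) == bn_b
        n = order[i]
        for m in candidates[n]:
            if m in used:
                continue
            mapping[n] = m
            used.add(m)
            if backtrack(i + 1):
                return True
            used.discard(m)
            del mapping[n]
        return False

    return backtrack(0)
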