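"""Federated evaluation of SPARQL basic-graph-pattern SELECT queries.

The engine answers a query over several sources, each hosting one or more
named graphs, without ever merging them:

1. a *capability index* records, per predicate, exactly which
   (endpoint, graph) pairs hold at least one triple with that predicate;
2. *two-level source selection* assigns each triple pattern the set of
   (endpoint, graph) pairs that can contribute matches — endpoint first,
   named graph within the endpoint — never dropping a contributing source
   (recall-preserving) while pruning everything the index rules out;
3. *planning* groups patterns whose selection is a single source into
   maximal exclusive groups (one sub-query per source); patterns selected
   on several sources become union nodes; owl:sameAs patterns resolve on
   the dedicated links graph and act as the mediator's join relation;
4. *execution* evaluates each plan node against its own source(s) and
   merges node results with hash joins on shared variables,
   smallest-intermediate-result first, then applies filters and the
   projection.

``evaluate_union_oracle`` answers the same query by handing a single merged
graph to rdflib's SPARQL engine — an independent evaluation route used by
the tests to certify soundness and completeness of the federated one.

Supported fragment: SELECT [DISTINCT] over a BGP with bound or variable
predicates plus simple comparison FILTERs.  Anything else raises
:class:`UnsupportedQueryError`.
"""

from __future__ import annotations

import operator
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Optional

from rdflib import Graph, Literal, URIRef, Variable
from rdflib.plugins.sparql import prepareQuery

from .link import OWL_SAMEAS
from .quads import Quad

__all__ = [
    "Source",
    "Federation",
    "CapabilityIndex",
    "ParsedQuery",
    "FilterClause",
    "QueryPlan",
    "Solution",
    "UnsupportedQueryError",
    "FederationError",
    "parse_select",
    "build_capability_index",
    "select_sources",
    "plan_query",
    "execute_plan",
    "run_query",
    "evaluate_union_oracle",
    "solution_multiset",
]


class UnsupportedQueryError(ValueError):
    """The query uses a construct outside the supported fragment."""


class FederationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# sources


class Source:
    """One endpoint hosting a set of named graphs (in-memory access mode)."""

    def __init__(self, endpoint_id: str):
        self.endpoint_id = endpoint_id
        self.graphs: dict[URIRef, Graph] = {}

    @classmethod
    def from_quads(cls, endpoint_id: str, quads: Iterable[Quad]) -> "Source":
        src = cls(endpoint_id)
        for q in quads:
            src.graphs.setdefault(q.graph, Graph()).add(
                (q.subject, q.predicate, q.object)
            )
        return src

    def add_graph(self, graph_iri: URIRef, graph: Graph) -> None:
        self.graphs[graph_iri] = graph


class Federation:
    """A registry of sources; graph IRIs must be unique across endpoints."""

    def __init__(self, sources: Iterable[Source] = ()):
        self.sources: dict[str, Source] = {}
        for s in sources:
            self.add_source(s)

    def add_source(self, source: Source) -> None:
        hosted = {g for s in self.sources.values() for g in s.graphs}
        dup = hosted & set(source.graphs)
        if dup:
            raise FederationError(f"graph IRIs already hosted: {sorted(dup)}")
        self.sources[source.endpoint_id] = source

    def add_links(self, link_quads: Iterable[Quad], endpoint_id: str = "links") -> None:
        """Register materialized owl:sameAs links as their own source."""
        self.add_source(Source.from_quads(endpoint_id, link_quads))

    def pairs(self) -> list[tuple]:
        return [
            (eid, giri)
            for eid, src in sorted(self.sources.items())
            for giri in sorted(src.graphs)
        ]

    def graph(self, endpoint_id: str, graph_iri: URIRef) -> Graph:
        return self.sources[endpoint_id].graphs[graph_iri]

    def union_graph(self) -> Graph:
        merged = Graph()
        for _, src in sorted(self.sources.items()):
            for _, g in sorted(src.graphs.items()):
                for t in g:
                    merged.add(t)
        return merged


# ---------------------------------------------------------------------------
# query parsing (rdflib parser; own engine)


@dataclass(frozen=True)
class FilterClause:
    var: Variable
    op: str  # one of < <= > >= = !=
    value: Literal


@dataclass(frozen=True)
class ParsedQuery:
    projection: tuple
    patterns: tuple  # triple patterns (s, p, o) over terms/variables
    filters: tuple = ()
    distinct: bool = False
    text: Optional[str] = field(default=None, compare=False)


_REL_OPS = {"<", "<=", ">", ">=", "=", "!="}


def _parse_filter_expr(expr) -> list[FilterClause]:
    name = getattr(expr, "name", None)
    if name == "ConditionalAndExpression":
        clauses = _parse_filter_expr(expr.expr)
        for other in expr.other:
            clauses.extend(_parse_filter_expr(other))
        return clauses
    if name == "RelationalExpression" and expr.op in _REL_OPS:
        lhs, rhs = expr.expr, expr.other
        if isinstance(lhs, Variable) and isinstance(rhs, Literal):
            return [FilterClause(lhs, expr.op, rhs)]
        if isinstance(rhs, Variable) and isinstance(lhs, Literal):
            flip = {"<": ">", ">": "<", "<=": ">=", ">=": "<="}
            return [FilterClause(rhs, flip.get(expr.op, expr.op), lhs)]
    raise UnsupportedQueryError(
        "unsupported fragment: only simple comparisons between a variable "
        "and a literal are allowed in FILTER"
    )


def parse_select(query: str) -> ParsedQuery:
    """Parse a SPARQL SELECT over a basic graph pattern.

    Uses rdflib's SPARQL parser for syntax, then walks the algebra and
    rejects anything outside SELECT [DISTINCT] + BGP + comparison FILTERs
    (no OPTIONAL/UNION/paths/aggregates/subqueries).
    """
    algebra = prepareQuery(query).algebra
    if algebra.name != "SelectQuery":
        raise UnsupportedQueryError("only SELECT queries are supported")
    node = algebra.p
    distinct = False
    if node.name == "Distinct":
        distinct = True
        node = node.p
    if node.name != "Project":
        raise UnsupportedQueryError(f"unsupported fragment: {node.name}")
    projection = tuple(node.PV)
    node = node.p
    filters: list[FilterClause] = []
    while getattr(node, "name", None) == "Filter":
        filters.extend(_parse_filter_expr(node.expr))
        node = node.p
    if getattr(node, "name", None) != "BGP":
        raise UnsupportedQueryError(
            f"unsupported fragment: {getattr(node, 'name', type(node))}"
        )
    return ParsedQuery(
        projection=projection,
        patterns=tuple(tuple(t) for t in node.triples),
        filters=tuple(filters),
        distinct=distinct,
        text=query,
    )


# ---------------------------------------------------------------------------
# capability index + source selection


@dataclass(frozen=True)
class CapabilityIndex:
    """Exact predicate-level data summary of a federation.

    ``membership`` maps predicate IRI → frozenset of (endpoint, graph)
    pairs holding >=1 triple with it; ``counts`` carries per-(predicate,
    endpoint, graph) triple counts that drive join ordering.
    """

    membership: dict
    counts: dict
    all_pairs: tuple

    def pairs_for(self, predicate) -> frozenset:
        return self.membership.get(predicate, frozenset())


def build_capability_index(federation: Federation) -> CapabilityIndex:
    membership: dict = defaultdict(set)
    counts: dict = {}
    for eid, giri in federation.pairs():
        g = federation.graph(eid, giri)
        for pred in set(g.predicates()):
            membership[pred].add((eid, giri))
            counts[(pred, eid, giri)] = sum(
                1 for _ in g.triples((None, pred, None))
            )
    return CapabilityIndex(
        membership={p: frozenset(s) for p, s in membership.items()},
        counts=counts,
        all_pairs=tuple(federation.pairs()),
    )


def select_sources(patterns, index: CapabilityIndex) -> list:
    """Per-pattern relevant (endpoint, graph) pairs.

    Bound-predicate patterns select through the index (exact, hence
    recall-preserving and free of predicate-level false positives);
    variable-predicate patterns cannot be pruned and select every pair.
    """
    selection = []
    for s, p, o in patterns:
        if isinstance(p, Variable):
            selection.append(frozenset(index.all_pairs))
        else:
            selection.append(index.pairs_for(p))
    return selection


# ---------------------------------------------------------------------------
# planning


@dataclass(frozen=True)
class GroupNode:
    """Maximal set of patterns answerable by one (endpoint, graph): issued
    as a single sub-query."""

    endpoint: str
    graph: URIRef
    patterns: tuple

    @property
    def n_subqueries(self) -> int:
        return 1


@dataclass(frozen=True)
class UnionNode:
    """A pattern several sources can answer: one sub-query per source,
    results deduplicated."""

    pattern: tuple
    sources: tuple

    @property
    def n_subqueries(self) -> int:
        return len(self.sources)


@dataclass(frozen=True)
class EmptyNode:
    """A pattern no source can answer: the query result is empty."""

    pattern: tuple

    @property
    def n_subqueries(self) -> int:
        return 0


@dataclass(frozen=True)
class QueryPlan:
    nodes: tuple
    sameas_joins: tuple  # patterns that act as mediator joins
    query: ParsedQuery

    @property
    def n_subqueries(self) -> int:
        return sum(n.n_subqueries for n in self.nodes)

    @property
    def is_empty(self) -> bool:
        return any(isinstance(n, EmptyNode) for n in self.nodes)

    def explain(self) -> str:
        lines = [f"plan: {len(self.nodes)} nodes, {self.n_subqueries} sub-queries"]
        for n in self.nodes:
            if isinstance(n, GroupNode):
                lines.append(
                    f"  group @ {n.endpoint} {n.graph} "
                    f"({len(n.patterns)} patterns)"
                )
            elif isinstance(n, UnionNode):
                lines.append(
                    f"  union pattern {n.pattern} over {len(n.sources)} sources"
                )
            else:
                lines.append(f"  EMPTY pattern {n.pattern}")
        if self.sameas_joins:
            lines.append(f"  mediator sameAs joins: {len(self.sameas_joins)}")
        return "\n".join(lines)


def plan_query(query: ParsedQuery, selection) -> QueryPlan:
    """Build the decomposition: exclusive groups per single-source pattern
    set, union nodes for multi-source patterns, empty markers otherwise."""
    groups: dict[tuple, list] = defaultdict(list)
    nodes: list = []
    sameas: list = []
    for patt, sel in zip(query.patterns, selection):
        if patt[1] == OWL_SAMEAS:
            sameas.append(patt)
        if not sel:
            nodes.append(EmptyNode(patt))
        elif len(sel) == 1:
            groups[next(iter(sel))].append(patt)
        else:
            nodes.append(UnionNode(patt, tuple(sorted(sel))))
    for (eid, giri), patts in sorted(groups.items()):
        nodes.append(GroupNode(eid, giri, tuple(patts)))
    return QueryPlan(nodes=tuple(nodes), sameas_joins=tuple(sameas), query=query)


# ---------------------------------------------------------------------------
# execution


@dataclass(frozen=True)
class Solution:
    """One result row: projected terms plus contributing-source provenance."""

    values: tuple
    provenance: frozenset


def _substitute(pattern, binding):
    return tuple(
        binding.get(t, None) if isinstance(t, Variable) else t for t in pattern
    )


def _extend(binding, pattern, triple):
    out = dict(binding)
    for t, v in zip(pattern, triple):
        if isinstance(t, Variable):
            if t in out and out[t] != v:
                return None
            out[t] = v
    return out


def _eval_bgp_on_graph(graph: Graph, patterns, prov) -> list:
    """Evaluate a BGP on one graph by indexed nested-loop matching."""
    rows = [{}]
    for patt in patterns:
        nxt = []
        for binding in rows:
            s, p, o = _substitute(patt, binding)
            for triple in graph.triples((s, p, o)):
                ext = _extend(binding, patt, triple)
                if ext is not None:
                    nxt.append(ext)
        rows = nxt
        if not rows:
            break
    # graphs are triple sets, so rows are distinct already
    return [(r, prov) for r in rows]


def _eval_node(node, federation: Federation) -> list:
    if isinstance(node, EmptyNode):
        return []
    if isinstance(node, GroupNode):
        g = federation.graph(node.endpoint, node.graph)
        return _eval_bgp_on_graph(
            g, node.patterns, frozenset({(node.endpoint, node.graph)})
        )
    # union node: dedup bindings across sources, merging provenance
    merged: dict = {}
    for eid, giri in node.sources:
        g = federation.graph(eid, giri)
        for binding, prov in _eval_bgp_on_graph(
            g, (node.pattern,), frozenset({(eid, giri)})
        ):
            key = frozenset(binding.items())
            merged[key] = merged.get(key, frozenset()) | prov
    return [(dict(k), prov) for k, prov in merged.items()]


def _hash_join(left: list, right: list) -> list:
    if not left or not right:
        return []
    lvars = set().union(*(set(b) for b, _ in left))
    rvars = set().union(*(set(b) for b, _ in right))
    join_vars = sorted(lvars & rvars)
    if not join_vars:
        return [
            ({**lb, **rb}, lp | rp) for lb, lp in left for rb, rp in right
        ]
    table: dict = defaultdict(list)
    for rb, rp in right:
        table[tuple(rb.get(v) for v in join_vars)].append((rb, rp))
    out = []
    for lb, lp in left:
        key = tuple(lb.get(v) for v in join_vars)
        for rb, rp in table.get(key, ()):
            out.append(({**lb, **rb}, lp | rp))
    return out


def _numeric(value):
    if isinstance(value, Decimal):
        return float(value)
    return value


def _apply_filters(rows, filters) -> list:
    ops = {
        "<": operator.lt, "<=": operator.le, ">": operator.gt,
        ">=": operator.ge, "=": operator.eq, "!=": operator.ne,
    }
    for clause in filters:
        fn = ops[clause.op]
        target = _numeric(clause.value.toPython())
        kept = []
        for binding, prov in rows:
            term = binding.get(clause.var)
            if not isinstance(term, Literal):
                continue  # comparison error -> row dropped, as in SPARQL
            try:
                if fn(_numeric(term.toPython()), target):
                    kept.append((binding, prov))
            except TypeError:
                continue
        rows = kept
    return rows


def execute_plan(plan: QueryPlan, federation: Federation) -> list[Solution]:
    """Run the plan: per-node sub-queries, mediator hash joins, filters,
    projection.  Smallest intermediate results join first; ties keep the
    plan's deterministic node order."""
    if plan.is_empty:
        return []
    results = [_eval_node(n, federation) for n in plan.nodes]
    order = sorted(range(len(results)), key=lambda i: (len(results[i]), i))
    rows = None
    for i in order:
        rows = results[i] if rows is None else _hash_join(rows, results[i])
        if not rows:
            break
    rows = rows if rows is not None else [({}, frozenset())]
    rows = _apply_filters(rows, plan.query.filters)
    solutions = [
        Solution(
            values=tuple(b.get(v) for v in plan.query.projection),
            provenance=prov,
        )
        for b, prov in rows
    ]
    if plan.query.distinct:
        seen = set()
        unique = []
        for sol in solutions:
            if sol.values not in seen:
                seen.add(sol.values)
                unique.append(sol)
        solutions = unique
    return solutions


def run_query(query: str, federation: Federation, explain: bool = False):
    """Parse, select, plan and execute in one call."""
    parsed = parse_select(query)
    index = build_capability_index(federation)
    selection = select_sources(parsed.patterns, index)
    plan = plan_query(parsed, selection)
    solutions = execute_plan(plan, federation)
    if explain:
        return solutions, plan
    return solutions


# ---------------------------------------------------------------------------
# oracle


def evaluate_union_oracle(query: str, federation: Federation) -> Counter:
    """Answer the query over the set-union of every graph in the federation
    using rdflib's SPARQL engine: the independent reference route.

    Returns the multiset of projected rows (tuples of terms).
    """
    merged = federation.union_graph()
    res = merged.query(query)
    out = Counter()
    for row in res:
        out[tuple(row[v] if v in res.vars else None for v in res.vars)] += 1
    return out


def solution_multiset(solutions: Iterable[Solution]) -> Counter:
    return Counter(sol.values for sol in solutions)
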