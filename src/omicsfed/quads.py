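"""RDF quads: the Quad type, N-Quads serialization and dataset statistics.

Quads are plain named tuples over rdflib terms so they hash and compare as
values; stores are rdflib graphs built from quad iterables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Union

from rdflib import Dataset, Graph, Literal, URIRef

__all__ = [
    "Quad",
    "DatasetStats",
    "QuadError",
    "write_nquads",
    "read_nquads",
    "quads_to_dataset",
    "dataset_quads",
    "dataset_stats",
]


class QuadError(ValueError):
    """A quad violated the Quad invariants (e.g. a relative IRI)."""


class Quad(NamedTuple):
    subject: URIRef
    predicate: URIRef
    object: Union[URIRef, Literal]
    graph: URIRef


@dataclass(frozen=True)
class DatasetStats:
    """Exact distinct counts over a quad multiset (set semantics for
    n_triples, mirroring a deduplicated store)."""

    n_triples: int
    n_subjects: int
    n_predicates: int
    n_objects: int
    size_bytes: Optional[int] = None


def _check_iri(term, role: str, quad) -> None:
    if not isinstance(term, URIRef) or ":" not in str(term):
        raise QuadError(f"{role} of {quad!r} is not an absolute IRI: {term!r}")


def validate_quad(q: Quad) -> None:
    _check_iri(q.subject, "subject", q)
    _check_iri(q.predicate, "predicate", q)
    _check_iri(q.graph, "graph", q)
    if isinstance(q.object, URIRef):
        _check_iri(q.object, "object", q)
    elif not isinstance(q.object, Literal):
        raise QuadError(f"object of {q!r} is neither IRI nor literal")


def quads_to_dataset(quads: Iterable[Quad]) -> Dataset:
    """Load quads into an rdflib Dataset partitioned by named graph."""
    ds = Dataset()
    for q in quads:
        validate_quad(q)
        ds.add((q.subject, q.predicate, q.object, q.graph))
    return ds


def dataset_quads(ds: Dataset) -> list[Quad]:
    return [
        Quad(s, p, o, g.identifier if isinstance(g, Graph) else g)
        for s, p, o, g in ds.quads((None, None, None, None))
    ]


def write_nquads(quads: Iterable[Quad], path) -> None:
    """Serialize quads as standard N-Quads (UTF-8, one statement per line)."""
    ds = quads_to_dataset(quads)
    ds.serialize(destination=str(path), format="nquads", encoding="utf-8")


def read_nquads(path) -> list[Quad]:
    ds = Dataset()
    ds.parse(str(path), format="nquads")
    return dataset_quads(ds)


def dataset_stats(quads: Iterable[Quad]) -> DatasetStats:
    """Distinct triple/subject/predicate/object counts of a quad multiset."""
    distinct = set(quads)
    return DatasetStats(
        n_triples=len(distinct),
        n_subjects=len({q.subject for q in distinct}),
        n_predicates=len({q.predicate for q in distinct}),
        n_objects=len({q.object for q in distinct}),
    )


def quad_multiset(quads: Iterable[Quad]) -> Counter:
    """Multiset view used by round-trip identity checks."""
    return Counter(quads)
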