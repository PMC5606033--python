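"""owl:sameAs link discovery between sources.

Two rule families mirror how heterogeneous cancer exports can actually be
joined: *exact-key* rules equate key resources (gene symbols, ENSEMBL ids,
sample identifiers, CpG probe ids) after a named normalization policy, and
the *positional* rule equates copy-number segments by chromosome and
coordinates — CNV exports carry no gene symbol, so position is the only
shared key.  Discovered links are materialized into a dedicated links
named graph so federated queries can treat owl:sameAs as an explicit join
relation.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable
from urllib.parse import unquote

from rdflib import Literal, URIRef
from rdflib.namespace import OWL

from .quads import Quad
from .records import Locus, normalize_chrom

__all__ = [
    "OWL_SAMEAS",
    "LinkRule",
    "Link",
    "normalize_key",
    "discover_exact_links",
    "discover_positional_links",
    "map_region_to_genes",
    "link_stats",
    "links_to_quads",
    "LINKS_GRAPH",
]

OWL_SAMEAS = OWL.sameAs
LINKS_GRAPH = URIRef("http://omicsfed.example/graphs/links")

_POLICIES = ("verbatim", "case_fold", "tcga_patient_barcode")


def normalize_key(raw: str, policy: str = "verbatim") -> str:
    """Canonicalize a key string under a named policy (idempotent).

    ``tcga_patient_barcode`` truncates a TCGA barcode to its first three
    dash-separated fields — the patient level — so sample-level barcodes
    (``TCGA-13-0920-01A``) equate with patient-level sample ids
    (``TCGA-13-0920``).
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown normalization policy {policy!r}")
    if policy == "verbatim":
        return raw
    if policy == "case_fold":
        return raw.upper()
    return "-".join(raw.split("-")[:3])


@dataclass(frozen=True)
class LinkRule:
    rule_kind: str  # exact_key | positional
    left: tuple  # (graph IRI, key predicate IRI)  [positional: graph only]
    right: tuple
    normalizer: str = "verbatim"
    tolerance_bp: int = 0
    mode: str = "exact"  # positional only: exact | overlap
    name: str = ""

    def __post_init__(self) -> None:
        if self.rule_kind not in ("exact_key", "positional"):
            raise ValueError(f"unknown rule kind {self.rule_kind!r}")
        if self.mode not in ("exact", "overlap"):
            raise ValueError(f"unknown positional mode {self.mode!r}")
        if self.mode == "exact" and self.tolerance_bp != 0:
            raise ValueError("tolerance_bp must be 0 in exact mode")
        if self.tolerance_bp < 0:
            raise ValueError("tolerance_bp must be non-negative")


@dataclass(frozen=True)
class Link:
    """A single owl:sameAs assertion with rule provenance."""

    subject: URIRef
    object: URIRef
    rule: LinkRule


def _term_key_text(term) -> str:
    """Key text carried by a key term: literal value, or the percent-decoded
    final path segment of a minted key IRI."""
    if isinstance(term, Literal):
        return str(term)
    return unquote(str(term).rsplit("/", 1)[-1])


def _key_resources(quads: Iterable[Quad], graph: URIRef, predicate: URIRef):
    """Map normalized-ready key text -> key resources under ``predicate``."""
    out: dict[str, set] = defaultdict(set)
    seen_predicate = False
    for q in quads:
        if q.graph != graph or q.predicate != predicate:
            continue
        seen_predicate = True
        text = _term_key_text(q.object)
        if text:
            node = q.object if isinstance(q.object, URIRef) else q.subject
            out[text].add(node)
    return out, seen_predicate


def discover_exact_links(
    quads_a: Iterable[Quad], quads_b: Iterable[Quad], rule: LinkRule
) -> set[Link]:
    """All owl:sameAs links (a, b) with equal normalized non-empty keys.

    Equivalent to the exhaustive pairwise comparison of every key resource
    in the left graph against every key resource in the right graph.
    """
    if rule.rule_kind != "exact_key":
        raise ValueError("discover_exact_links requires an exact_key rule")
    graph_a, pred_a = rule.left
    graph_b, pred_b = rule.right
    keys_a, ok_a = _key_resources(quads_a, graph_a, pred_a)
    keys_b, ok_b = _key_resources(quads_b, graph_b, pred_b)
    if not ok_a or not ok_b:
        missing = pred_a if not ok_a else pred_b
        warnings.warn(
            f"key predicate {missing} absent from its graph; "
            f"rule {rule.name or rule.rule_kind} yields no links",
            stacklevel=2,
        )
        return set()
    norm_a: dict[str, set] = defaultdict(set)
    for text, nodes in keys_a.items():
        norm_a[normalize_key(text, rule.normalizer)].update(nodes)
    links: set[Link] = set()
    for text, nodes_b in keys_b.items():
        canon = normalize_key(text, rule.normalizer)
        if not canon:
            continue
        for a in norm_a.get(canon, ()):
            for b in nodes_b:
                links.add(Link(a, b, rule))
    return links


def _segments(quads: Iterable[Quad], graph: URIRef, chrom_pred, start_pred, end_pred):
    rows: dict[URIRef, dict] = defaultdict(dict)
    for q in quads:
        if q.graph != graph:
            continue
        if q.predicate == chrom_pred:
            rows[q.subject]["chrom"] = normalize_chrom(str(q.object))
        elif q.predicate == start_pred:
            rows[q.subject]["start"] = int(q.object)
        elif q.predicate == end_pred:
            rows[q.subject]["end"] = int(q.object)
    return [
        (s, d["chrom"], d["start"], d["end"])
        for s, d in rows.items()
        if {"chrom", "start", "end"} <= set(d)
    ]


def discover_positional_links(
    quads_a: Iterable[Quad],
    quads_b: Iterable[Quad],
    rule: LinkRule,
    chrom_start_end_a: tuple,
    chrom_start_end_b: tuple,
) -> set[Link]:
    """Link CNV row resources by genomic position.

    ``exact`` mode: same normalized chromosome and identical (start, end).
    ``overlap`` mode: same chromosome and interval overlap after symmetric
    extension of both intervals by ``tolerance_bp``.  Both equal the brute
    force all-pairs scan; ``chrom_start_end_*`` name each side's chromosome/
    start/end predicates.
    """
    if rule.rule_kind != "positional":
        raise ValueError("discover_positional_links requires a positional rule")
    graph_a = rule.left[0]
    graph_b = rule.right[0]
    segs_a = _segments(quads_a, graph_a, *chrom_start_end_a)
    segs_b = _segments(quads_b, graph_b, *chrom_start_end_b)
    links: set[Link] = set()
    if rule.mode == "exact":
        index: dict[tuple, set] = defaultdict(set)
        for s, c, st, en in segs_a:
            index[(c, st, en)].add(s)
        for s_b, c, st, en in segs_b:
            for s_a in index.get((c, st, en), ()):
                links.add(Link(s_a, s_b, rule))
    else:
        tol = rule.tolerance_bp
        by_chrom: dict[str, list] = defaultdict(list)
        for s, c, st, en in segs_a:
            by_chrom[c].append((s, st - tol, en + tol))
        for s_b, c, st, en in segs_b:
            lo, hi = st - tol, en + tol
            for s_a, a_lo, a_hi in by_chrom.get(c, ()):
                if a_lo <= hi and lo <= a_hi:
                    links.add(Link(s_a, s_b, rule))
    return links


def map_region_to_genes(
    locus: Locus, gene_annotation: Iterable[tuple]
) -> set[str]:
    """Gene symbols whose annotated interval overlaps the query locus by
    >=1 bp on the same chromosome (overlap, not containment, so genes
    spanning a segment boundary are retained)."""
    return {
        symbol for symbol, gl in gene_annotation if gl.overlaps(locus)
    }


def link_stats(link_sets: dict) -> dict:
    """Deduplicated link counts per source pair.

    ``link_sets`` maps ``(source_pair, rule_name)`` → iterable of links; a
    link emitted by several rules for the same pair counts once.
    """
    per_pair: dict[object, set] = defaultdict(set)
    for (pair, _rule_name), links in link_sets.items():
        per_pair[pair].update((lk.subject, lk.object) for lk in links)
    return {pair: len(pairs) for pair, pairs in per_pair.items()}


def links_to_quads(
    links: Iterable[Link], graph: URIRef = LINKS_GRAPH
) -> list[Quad]:
    """Materialize links as owl:sameAs quads in the dedicated links graph,
    deduplicated and deterministically ordered."""
    pairs = sorted({(lk.subject, lk.object) for lk in links})
    return [Quad(s, OWL_SAMEAS, o, graph) for s, o in pairs]
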