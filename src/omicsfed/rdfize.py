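"""Deterministic conversion of typed omics records into named-graph quads.

Every record becomes one row resource in its dataset's named graph: one
``rdf:type`` quad plus exactly one quad per non-null mapped field, so the
triple count of a converted table has the closed form
``sum over records of (1 + number of non-null fields)``.

Shared-key fields (gene symbol, ENSEMBL id, sample id, composite element
REF) are emitted as *resource-valued* quads whose IRI percent-encodes the
key text — link discovery and owl:sameAs joins operate on these key
resources.  All other fields are typed literals (coordinates as integers,
beta/RPKM/purity as doubles, the rest plain strings).  The encoding is
lossless: ``extract_rows`` inverts it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional
from urllib.parse import quote, unquote

from rdflib import RDF, Literal, URIRef
from rdflib.namespace import XSD

from .quads import Quad, dataset_stats
from .records import (
    AnnotationRecord,
    CNVRecord,
    ExpressionRecord,
    MethylationRecord,
    MutationRecord,
)

__all__ = [
    "MappingConfig",
    "MappingError",
    "MintError",
    "mint_iri",
    "rdfize_table",
    "build_dataset",
    "extract_rows",
    "default_mapping",
    "record_roles",
    "vocab",
    "graph_iri_for",
    "BASE",
]

#: Root IRI under which all minted resources, vocabularies and graphs live.
BASE = "http://omicsfed.example/"

#: Roles emitted as key resources rather than literals, and the resource
#: class segment used when minting their IRIs.
KEY_ROLES = {
    "gene_symbol": "gene",
    "ensembl_id": "ensembl",
    "sample_id": "sample",
    "composite_element_ref": "cer",
}
INT_ROLES = {"start", "end"}
FLOAT_ROLES = {"value", "beta_value", "tumour_purity"}


class MappingError(ValueError):
    """A populated role has no predicate in the mapping."""


class MintError(ValueError):
    """IRI minting was asked to encode an empty key."""


def mint_iri(base_iri: str, kind: str, *keys: str) -> URIRef:
    """Mint a deterministic, IRI-safe resource identifier.

    Same inputs always yield the same IRI; key text is percent-encoded so
    any printable key (spaces, colons, slashes) round-trips.
    """
    if not keys or any(k == "" for k in keys):
        raise MintError(f"empty key while minting {kind} IRI")
    encoded = "/".join(quote(str(k), safe="") for k in keys)
    return URIRef(f"{base_iri}{kind}/{encoded}")


def vocab(source: str, local: str) -> URIRef:
    """Predicate IRI in a source's vocabulary (e.g. cosmic:, tcga:)."""
    return URIRef(f"{BASE}{source}/vocab#{local}")


def graph_iri_for(source: str, datatype: str, cancer_type: Optional[str] = None) -> URIRef:
    """One named graph per (source, data-type, cancer-type)."""
    parts = [source, datatype] + ([cancer_type] if cancer_type else [])
    return URIRef(BASE + "graphs/" + "/".join(quote(p, safe="") for p in parts))


@dataclass(frozen=True)
class MappingConfig:
    base_iri: str
    graph_iri: URIRef
    type_iri: URIRef
    predicate_map: dict = field(default_factory=dict)  # role -> predicate IRI

    def __post_init__(self) -> None:
        preds = list(self.predicate_map.values())
        if len(set(preds)) != len(preds):
            raise MappingError("predicate_map must be injective")


_RECORD_KIND = {
    MutationRecord: "mutation",
    CNVRecord: "cnv",
    ExpressionRecord: "expression",
    MethylationRecord: "methylation",
    AnnotationRecord: "annotation",
}

_KIND_CLASS_LOCAL = {
    "mutation": "Mutation",
    "cnv": "CNV",
    "expression": "GeneExpression",
    "methylation": "Methylation",
    "annotation": "Annotation",
}


def record_roles(rec) -> dict:
    """Flatten a record into its non-null role → value mapping."""
    kind = _RECORD_KIND[type(rec)]
    roles: dict = {}
    if kind == "mutation":
        roles = {
            "sample_id": rec.sample_id,
            "gene_symbol": rec.gene_symbol,
            "ensembl_id": rec.ensembl_id,
            "chrom": rec.locus.chrom,
            "start": rec.locus.start,
            "end": rec.locus.end,
            "mutation_type": rec.mutation_type,
            "pmid": rec.pmid,
        }
    elif kind == "cnv":
        roles = {
            "sample_id": rec.sample_id,
            "chrom": rec.locus.chrom,
            "start": rec.locus.start,
            "end": rec.locus.end,
            "cnv_type": rec.cnv_type,
        }
    elif kind == "expression":
        roles = {
            "gene_symbol": rec.gene_symbol,
            "sample_id": rec.sample_id,
            "value": rec.value,
            "regulation": rec.regulation,
        }
    elif kind == "methylation":
        roles = {
            "gene_symbol": rec.gene_symbol,
            "composite_element_ref": rec.composite_element_ref,
            "sample_id": rec.sample_id,
            "chrom": rec.locus.chrom,
            "start": rec.locus.start,
            "end": rec.locus.end,
            "beta_value": rec.beta_value,
            "tumour_purity": rec.tumour_purity,
        }
    else:
        roles = {
            "gene_symbol": rec.gene_symbol,
            "ensembl_id": rec.ensembl_id,
            "go_id": rec.go_id,
            "go_process": rec.go_process,
            "kegg_id": rec.kegg_id,
            "reactome_id": rec.reactome_id,
        }
    return {k: v for k, v in roles.items() if v is not None and v != ""}


def _object_term(base_iri: str, role: str, value) -> object:
    if role in KEY_ROLES:
        return mint_iri(base_iri, KEY_ROLES[role], str(value))
    if role in INT_ROLES:
        return Literal(int(value), datatype=XSD.integer)
    if role in FLOAT_ROLES:
        return Literal(float(value), datatype=XSD.double)
    return Literal(str(value))


def rdfize_table(records: Iterable, mapping: MappingConfig) -> list[Quad]:
    """Convert records into quads in ``mapping.graph_iri``.

    Deterministic: row resources are numbered in input order, key IRIs are
    minted from key text alone, and no timestamps or randomness enter.
    """
    quads: list[Quad] = []
    g = mapping.graph_iri
    for i, rec in enumerate(records):
        subject = URIRef(f"{g}/row/{i}")
        quads.append(Quad(subject, RDF.type, mapping.type_iri, g))
        for role, value in record_roles(rec).items():
            pred = mapping.predicate_map.get(role)
            if pred is None:
                raise MappingError(
                    f"role {role!r} is populated but has no predicate in the "
                    f"mapping for graph {g}"
                )
            quads.append(Quad(subject, pred, _object_term(mapping.base_iri, role, value), g))
    return quads


def extract_rows(quads: Iterable[Quad], mapping: MappingConfig) -> list[dict]:
    """Inverse of :func:`rdfize_table`: recover role → value per row resource.

    Key-resource IRIs are percent-decoded back to their key text; typed
    literals come back as Python ints/floats/strings.
    """
    inverse = {pred: role for role, pred in mapping.predicate_map.items()}
    rows: dict[URIRef, dict] = {}
    for q in quads:
        if q.graph != mapping.graph_iri:
            continue
        if q.predicate == RDF.type:
            rows.setdefault(q.subject, {})
            continue
        role = inverse.get(q.predicate)
        if role is None:
            continue
        if isinstance(q.object, URIRef):
            value = unquote(str(q.object).rsplit("/", 1)[-1])
        else:
            value = q.object.toPython()
        rows.setdefault(q.subject, {})[role] = value
    # row order follows the deterministic /row/<i> numbering
    def row_index(s: URIRef) -> int:
        return int(str(s).rsplit("/", 1)[-1])

    return [rows[s] for s in sorted(rows, key=row_index)]


#: Per-source local predicate names that differ between dialects: the TCGA
#: tables identify the measured sample by hybridization ref, COSMIC by
#: sample id; everything else shares local names.
_SAMPLE_LOCAL = {"tcga": "hybrid_ref"}

_KIND_ROLE_SET = {
    "mutation": ["sample_id", "gene_symbol", "ensembl_id", "chrom", "start",
                 "end", "mutation_type", "pmid"],
    "cnv": ["sample_id", "chrom", "start", "end", "cnv_type"],
    "expression": ["gene_symbol", "sample_id", "value", "regulation"],
    "methylation": ["gene_symbol", "composite_element_ref", "sample_id",
                    "chrom", "start", "end", "beta_value", "tumour_purity"],
    "annotation": ["gene_symbol", "ensembl_id", "go_id", "go_process",
                   "kegg_id", "reactome_id"],
}


def default_mapping(source: str, kind: str, cancer_type: Optional[str] = None) -> MappingConfig:
    """The default predicate vocabulary for a (source, data-type) dataset.

    Predicates live under ``<BASE><source>/vocab#``; the expression value
    predicate is named ``rpkm`` and the sample predicate follows the
    source's dialect (``hybrid_ref`` for TCGA, ``sample`` otherwise).
    """
    locals_ = {}
    for role in _KIND_ROLE_SET[kind]:
        if role == "sample_id":
            local = _SAMPLE_LOCAL.get(source, "sample")
        elif role == "value":
            local = "rpkm"
        elif role == "gene_symbol":
            local = "gene"
        elif role == "composite_element_ref":
            local = "composite_element_ref"
        else:
            local = role
        locals_[role] = vocab(source, local)
    return MappingConfig(
        base_iri=f"{BASE}{source}/",
        graph_iri=graph_iri_for(source, kind, cancer_type),
        type_iri=vocab(source, _KIND_CLASS_LOCAL[kind]),
        predicate_map=locals_,
    )


def build_dataset(tables: list) -> tuple[dict, dict]:
    """Convert ``[(records, mapping), ...]`` into a per-graph quad store.

    Returns ``(graphs, stats)`` where ``graphs`` maps graph IRI → quad list
    and ``stats`` maps graph IRI → :class:`DatasetStats`.
    """
    graphs: dict[URIRef, list[Quad]] = {}
    for records, mapping in tables:
        if mapping.graph_iri in graphs:
            raise MappingError(
                f"duplicate graph IRI across tables: {mapping.graph_iri}"
            )
        graphs[mapping.graph_iri] = rdfize_table(records, mapping)
    stats = {g: dataset_stats(qs) for g, qs in graphs.items()}
    return graphs, stats
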