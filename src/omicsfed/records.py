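"""Typed in-memory model of the omics tables.

Coordinates are 1-based inclusive throughout (COSMIC convention); any
conversion from 0-based/half-open inputs happens at the reading boundary,
never inside comparisons.  Chromosome labels are normalized once at
construction: a leading ``chr`` prefix is stripped and X/Y/MT are uppercased.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Locus",
    "MutationRecord",
    "CNVRecord",
    "ExpressionRecord",
    "MethylationRecord",
    "AnnotationRecord",
    "RecordError",
    "normalize_chrom",
    "DEFAULT_NS_VOCABULARY",
    "DEFAULT_MUTATION_VOCABULARY",
    "CNV_TYPES",
    "filter_nonsynonymous",
]


class RecordError(ValueError):
    """A record violated a field invariant at construction."""


_CG_RE = re.compile(r"^cg\d+$")

#: Mutation-type labels treated as non-synonymous by default.  The restriction
#: to non-synonymous events is the standard driver-gene filter; the exact
#: label set is configurable because export dialects differ.
DEFAULT_NS_VOCABULARY = frozenset(
    {"missense", "nonsense", "frameshift", "splice-site"}
)

#: Full controlled vocabulary accepted for MutationRecord.mutation_type.
DEFAULT_MUTATION_VOCABULARY = frozenset(
    {"missense", "nonsense", "frameshift", "splice-site", "silent",
     "GAIN", "LOSS"}
)

CNV_TYPES = frozenset({"GAIN", "LOSS"})


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip ``chr`` prefix, uppercase X/Y/MT."""
    c = label.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in ("x", "y", "mt", "m"):
        c = "MT" if c.lower() in ("mt", "m") else c.upper()
    return c


@dataclass(frozen=True)
class Locus:
    """A genomic interval: chromosome, 1-based inclusive start and end."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.chrom:
            raise RecordError("empty chromosome label")
        if self.start < 1:
            raise RecordError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise RecordError(
                f"end {self.end} precedes start {self.start}"
            )

    def overlaps(self, other: "Locus") -> bool:
        """>=1 bp overlap on the same (normalized) chromosome."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_symbol: str
    locus: Locus
    mutation_type: str
    ensembl_id: Optional[str] = None
    pmid: Optional[str] = None
    vocabulary: frozenset = field(
        default=DEFAULT_MUTATION_VOCABULARY, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise RecordError("mutation record with empty sample_id")
        if not self.gene_symbol:
            raise RecordError("mutation record with empty gene_symbol")
        if self.mutation_type not in self.vocabulary:
            raise RecordError(
                f"mutation_type {self.mutation_type!r} not in vocabulary"
            )


@dataclass(frozen=True)
class CNVRecord:
    """A copy-number segment.  Deliberately carries no gene symbol: CNV
    exports identify segments by position only, which is why region-to-gene
    mapping and the positional link rule exist."""

    sample_id: str
    locus: Locus
    cnv_type: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise RecordError("CNV record with empty sample_id")
        if self.cnv_type not in CNV_TYPES:
            raise RecordError(f"cnv_type must be GAIN or LOSS, got {self.cnv_type!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_symbol: str
    sample_id: str  # sample barcode or tissue label, depending on the table
    value: float  # RPKM (or comparable non-negative expression level)
    regulation: Optional[str] = None  # over / under / normal

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise RecordError("expression record with empty gene_symbol")
        if self.value < 0:
            raise RecordError(f"negative expression value {self.value}")
        if self.regulation is not None and self.regulation not in (
            "over", "under", "normal"
        ):
            raise RecordError(f"unknown regulation {self.regulation!r}")


@dataclass(frozen=True)
class MethylationRecord:
    """A CpG-site methylation measurement in a gene promoter region.

    ``beta_value`` is either a raw beta level in [0, 1] or a beta *change*
    in [-1, 1]; which one is a per-table schema flag, the record only
    enforces ``|beta| <= 1``.
    """

    gene_symbol: str
    composite_element_ref: str
    locus: Locus
    beta_value: float
    tumour_purity: Optional[float] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise RecordError("methylation record with empty gene_symbol")
        if abs(self.beta_value) > 1:
            raise RecordError(f"|beta_value| > 1: {self.beta_value}")
        if self.composite_element_ref and not _CG_RE.match(
            self.composite_element_ref
        ):
            raise RecordError(
                f"composite element REF {self.composite_element_ref!r} "
                "does not match the cg-identifier pattern"
            )
        if self.tumour_purity is not None and self.tumour_purity < 0:
            raise RecordError("negative tumour purity")


@dataclass(frozen=True)
class AnnotationRecord:
    """A gene-to-process/pathway annotation row (GOA/KEGG/REACTOME shaped)."""

    gene_symbol: Optional[str] = None
    ensembl_id: Optional[str] = None
    go_id: Optional[str] = None
    go_process: Optional[str] = None
    kegg_id: Optional[str] = None
    reactome_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not any(
            (self.gene_symbol, self.ensembl_id, self.go_id,
             self.kegg_id, self.reactome_id)
        ):
            raise RecordError("annotation record with no identifier set")


def filter_nonsynonymous(records, ns_vocabulary=DEFAULT_NS_VOCABULARY):
    """Keep mutation records whose type is in the non-synonymous vocabulary.

    Returns ``(kept, unknown_report)`` where ``unknown_report`` maps
    mutation-type labels that belong to no declared vocabulary to their
    occurrence counts (such rows are excluded, not silently dropped).
    """
    if not ns_vocabulary:
        raise ValueError("ns_vocabulary must be non-empty")
    kept = []
    unknown: dict[str, int] = {}
    for rec in records:
        if rec.mutation_type in ns_vocabulary:
            kept.append(rec)
        elif rec.mutation_type not in rec.vocabulary:
            unknown[rec.mutation_type] = unknown.get(rec.mutation_type, 0) + 1
    return kept, unknown
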