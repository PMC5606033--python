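"""The federated query templates and gene-prioritization filters.

Five templates cover the recurring questions over a COSMIC/TCGA/annotation
federation: mutation loci across both mutation sources, promoter
methylation change, methylation joined to GO processes, gene→pathway→
process associations across four sources, and promoter location for a
(gene, CpG probe, chromosome) triple.  Each template substitutes the
gene's minted key IRIs into a fixed basic graph pattern and runs it
through the federation engine; owl:sameAs patterns join entities across
sources via the links graph.

Gene symbols are plain HGNC-style strings at this surface; IRI minting is
internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .federate import Federation, Solution, run_query
from .rdfize import BASE, mint_iri, vocab

__all__ = [
    "q_mutation_loci",
    "q_promoter_methylation",
    "q_methylation_go",
    "q_gene_pathway_process",
    "q_promoter_location",
    "mutation_loci_query",
    "promoter_methylation_query",
    "methylation_go_query",
    "gene_pathway_process_query",
    "promoter_location_query",
    "filter_genes_by_rpkm",
    "RpkmFilterResult",
    "rank_genes_by_mutation_frequency",
    "run_panel",
    "TEMPLATES",
]

_OWL_SAMEAS = "<http://www.w3.org/2002/07/owl#sameAs>"


def _gene_iri(source: str, gene_symbol: str) -> str:
    return f"<{mint_iri(f'{BASE}{source}/', 'gene', gene_symbol)}>"


def _cer_iri(source: str, cer: str) -> str:
    return f"<{mint_iri(f'{BASE}{source}/', 'cer', cer)}>"


def _p(source: str, local: str) -> str:
    return f"<{vocab(source, local)}>"


def mutation_loci_query(gene_symbol: str) -> str:
    """Genomic loci of a mutated gene from both mutation-bearing sources,
    merged on the gene sameAs link."""
    g_c = _gene_iri("cosmic", gene_symbol)
    return f"""SELECT ?sample ?start_c ?mtype ?hybrid ?start_t WHERE {{
  ?m {_p('cosmic', 'sample')} ?sample .
  ?m {_p('cosmic', 'gene')} {g_c} .
  ?m {_p('cosmic', 'start')} ?start_c .
  ?m {_p('cosmic', 'mutation_type')} ?mtype .
  {g_c} {_OWL_SAMEAS} ?gene_t .
  ?mt {_p('tcga', 'gene')} ?gene_t .
  ?mt {_p('tcga', 'hybrid_ref')} ?hybrid .
  ?mt {_p('tcga', 'start')} ?start_t .
}}"""


def promoter_methylation_query(gene_symbol: str) -> str:
    """Promoter-level methylation change for a gene from both sources
    (inner join: the gene must be measured in both)."""
    g_c = _gene_iri("cosmic", gene_symbol)
    return f"""SELECT ?cer_c ?beta_c ?cer_t ?beta_t WHERE {{
  ?mc {_p('cosmic', 'gene')} {g_c} .
  ?mc {_p('cosmic', 'composite_element_ref')} ?cer_c .
  ?mc {_p('cosmic', 'beta_value')} ?beta_c .
  {g_c} {_OWL_SAMEAS} ?gene_t .
  ?mt {_p('tcga', 'gene')} ?gene_t .
  ?mt {_p('tcga', 'composite_element_ref')} ?cer_t .
  ?mt {_p('tcga', 'beta_value')} ?beta_t .
}}"""


def methylation_go_query(gene_symbol: str) -> str:
    """Methylation from both sources joined with GO processes (three-source
    plan: COSMIC + TCGA methylation + GOA annotations)."""
    g_c = _gene_iri("cosmic", gene_symbol)
    return f"""SELECT ?cer_c ?beta_c ?beta_t ?process WHERE {{
  ?mc {_p('cosmic', 'gene')} {g_c} .
  ?mc {_p('cosmic', 'composite_element_ref')} ?cer_c .
  ?mc {_p('cosmic', 'beta_value')} ?beta_c .
  {g_c} {_OWL_SAMEAS} ?gene_t .
  ?mt {_p('tcga', 'gene')} ?gene_t .
  ?mt {_p('tcga', 'composite_element_ref')} ?cer_t .
  ?mt {_p('tcga', 'beta_value')} ?beta_t .
  ?gene_t {_OWL_SAMEAS} ?gene_a .
  ?a {_p('goa', 'gene')} ?gene_a .
  ?a {_p('goa', 'go_process')} ?process .
}}"""


def gene_pathway_process_query(gene_symbol: str) -> str:
    """Gene → GO process → REACTOME and KEGG pathway associations (four
    sources: TCGA methylation, GOA, REACTOME, KEGG)."""
    g_t = _gene_iri("tcga", gene_symbol)
    return f"""SELECT ?process ?reactome ?kegg WHERE {{
  ?mt {_p('tcga', 'gene')} {g_t} .
  ?mt {_p('tcga', 'composite_element_ref')} ?cer .
  ?mt {_p('tcga', 'beta_value')} ?beta .
  {g_t} {_OWL_SAMEAS} ?gene_a .
  ?a {_p('goa', 'gene')} ?gene_a .
  ?a {_p('goa', 'go_id')} ?go .
  ?a {_p('goa', 'go_process')} ?process .
  ?r {_p('reactome', 'go_id')} ?go .
  ?r {_p('reactome', 'reactome_id')} ?reactome .
  ?k {_p('kegg', 'go_id')} ?go .
  ?k {_p('kegg', 'kegg_id')} ?kegg .
}}"""


def promoter_location_query(source: str, gene_symbol: str, cer: str, chrom: str) -> str:
    """Start of the methylated promoter region for (gene, probe, chromosome)
    within one source."""
    return f"""SELECT ?start WHERE {{
  ?m {_p(source, 'gene')} {_gene_iri(source, gene_symbol)} .
  ?m {_p(source, 'composite_element_ref')} {_cer_iri(source, cer)} .
  ?m {_p(source, 'chrom')} "{chrom}" .
  ?m {_p(source, 'start')} ?start .
}}"""


def q_mutation_loci(federation: Federation, gene_symbol: str) -> list[Solution]:
    return run_query(mutation_loci_query(gene_symbol), federation)


def q_promoter_methylation(federation: Federation, gene_symbol: str) -> list[Solution]:
    return run_query(promoter_methylation_query(gene_symbol), federation)


def q_methylation_go(federation: Federation, gene_symbol: str) -> list[Solution]:
    return run_query(methylation_go_query(gene_symbol), federation)


def q_gene_pathway_process(federation: Federation, gene_symbol: str) -> list[Solution]:
    return run_query(gene_pathway_process_query(gene_symbol), federation)


def q_promoter_location(
    federation: Federation, gene_symbol: str, cer: str, chrom: str,
    sources: tuple = ("cosmic", "tcga"),
) -> list[tuple]:
    """Promoter start per source: ``[(source, start_value), ...]``.

    One per-source basic graph pattern is executed for each source that can
    host the probe; a source without the (gene, probe, chromosome) row
    simply contributes no solutions.
    """
    out = []
    for source in sources:
        for sol in run_query(
            promoter_location_query(source, gene_symbol, cer, chrom), federation
        ):
            out.append((source, sol.values[0].toPython()))
    return out


TEMPLATES = {
    "loci": q_mutation_loci,
    "meth": q_promoter_methylation,
    "go": q_methylation_go,
    "pathway": q_gene_pathway_process,
}


@dataclass
class RpkmFilterResult:
    """Genes passing the expression filter, ordered by descending
    minimum-across-tissues RPKM (ties broken lexicographically)."""

    genes: list
    excluded_missing_tissue: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)


def filter_genes_by_rpkm(
    expression: Iterable, cutoff: float, require_all_tissues: Iterable[str] = ()
) -> RpkmFilterResult:
    """Keep genes whose RPKM is *strictly* above ``cutoff`` in every
    required tissue.

    A gene lacking a measurement for a required tissue is excluded and
    recorded in ``excluded_missing_tissue``.  With an empty tissue
    requirement a gene is kept if any of its values exceeds the cutoff.
    Output order: descending minimum value across the gene's (required, or
    all observed) tissues, then lexicographic — so it is invariant to the
    input row order.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    required = set(require_all_tissues)
    by_gene: dict[str, dict[str, float]] = {}
    for rec in expression:
        # keep the maximum per (gene, tissue) if a table repeats the pair
        tissues = by_gene.setdefault(rec.gene_symbol, {})
        prev = tissues.get(rec.sample_id)
        if prev is None or rec.value > prev:
            tissues[rec.sample_id] = rec.value
    kept: list[tuple] = []
    excluded: dict[str, list] = {}
    for gene, tissues in by_gene.items():
        if required:
            missing = sorted(required - set(tissues))
            if missing:
                excluded[gene] = missing
                continue
            scores = [tissues[t] for t in required]
            if all(v > cutoff for v in scores):
                kept.append((gene, min(scores)))
        else:
            values = list(tissues.values())
            if any(v > cutoff for v in values):
                kept.append((gene, min(values)))
    kept.sort(key=lambda gv: (-gv[1], gv[0]))
    return RpkmFilterResult(
        genes=[g for g, _ in kept], excluded_missing_tissue=excluded
    )


def rank_genes_by_mutation_frequency(
    mutation_records: Iterable, top_k: int,
    ns_vocabulary: Optional[frozenset] = None,
) -> list[str]:
    """Rank genes by descending mutation-record count (the frequency-based
    driver-gene heuristic); ties lexicographic; first ``top_k`` returned.

    With ``ns_vocabulary`` given, only records whose type is in it count.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    counts: dict[str, int] = {}
    for rec in mutation_records:
        if ns_vocabulary is not None and rec.mutation_type not in ns_vocabulary:
            continue
        counts[rec.gene_symbol] = counts.get(rec.gene_symbol, 0) + 1
    ranked = sorted(counts, key=lambda g: (-counts[g], g))
    return ranked[:top_k]


def run_panel(
    federation: Federation, genes: Iterable[str], template: str
) -> dict:
    """Run one template for each gene of a panel.

    Genes absent from a source yield empty solution lists, never errors —
    the sweep over a filtered gene panel must not abort midway.
    """
    fn = TEMPLATES[template]
    return {gene: fn(federation, gene) for gene in genes}
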