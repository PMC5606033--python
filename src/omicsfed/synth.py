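"""Synthetic multi-source federations with planted links and known answers.

The generator emulates the key structure of COSMIC/TCGA-shaped exports and
Bio2RDF-shaped annotation sets: a COSMIC-shaped source (gene expression,
somatic mutation, CNV, methylation graphs), a TCGA-shaped source (CNV,
expression, methylation graphs, identified by hybridization-ref barcodes)
and an annotation source (GOA, KEGG, REACTOME graphs).  Key overlap
between sources is planted exactly: ``floor(fraction * count)`` shared
gene symbols / patients / CNV positions, with unique keys and disjoint
coordinate ranges elsewhere so the planted link sets equal the exhaustive
pairwise comparison.

Ground truth (planted links) is computed here by explicit brute-force
comparison of the generated tables — never by the link-discovery code
under test — and expected query answers come from the union-store oracle.

Numeric values only need to exercise filters and joins: RPKM is
log-uniform in [0.01, 100], beta uniform in [-1, 1], coordinates uniform
within fixed per-population ranges, tumour purity uniform in [0, 1000].
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, fields
from typing import Iterable, Optional

import numpy as np
from rdflib import URIRef

from .federate import Federation, Source, evaluate_union_oracle
from .link import Link, LinkRule, discover_exact_links, discover_positional_links, links_to_quads
from .quads import Quad
from .rdfize import BASE, build_dataset, default_mapping, mint_iri, vocab
from .records import (
    AnnotationRecord,
    CNVRecord,
    ExpressionRecord,
    Locus,
    MethylationRecord,
    MutationRecord,
)

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "FederationBundle",
    "generate_federation",
    "reference_fixture",
    "expected_answers",
    "SpecError",
]


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic federation."""

    n_genes: int = 30
    n_samples: int = 12
    n_cnv_segments: int = 25
    n_methyl_sites: int = 40
    n_mutations: int = 60
    shared_gene_fraction: float = 0.5
    shared_sample_fraction: float = 0.5
    shared_position_fraction: float = 0.4
    go_per_gene: int = 2
    pathway_per_go: int = 1
    tissues: tuple = ("heart", "ovary", "liver", "lung")
    cancer_type: str = "OV"
    key_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("n_") and v < 0:
                raise SpecError(f"{f.name} must be >= 0, got {v}")
            if f.name.endswith("_fraction") and not (0.0 <= v <= 1.0):
                raise SpecError(f"{f.name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted links per rule, from brute-force table comparison."""

    gene_links: frozenset  # (cosmic gene IRI, tcga gene IRI)
    sample_links: frozenset  # (cosmic sample IRI, tcga sample IRI)
    goa_gene_links: frozenset  # (tcga gene IRI, goa gene IRI)
    cnv_links: frozenset  # (cosmic CNV row IRI, tcga CNV row IRI)
    shared_genes: tuple
    shared_patients: tuple


@dataclass
class FederationBundle:
    """A federation plus its source tables, link rules and ground truth."""

    federation: Federation
    tables: dict
    graphs: dict  # graph IRI -> quad list
    link_rules: dict  # rule name -> (LinkRule, side predicate info)
    ground_truth: Optional[GroundTruth] = None

    def all_quads(self) -> list[Quad]:
        return [q for qs in self.graphs.values() for q in qs]

    def discover_links(self) -> dict:
        """Apply every configured link rule; rule name -> set of links."""
        quads = self.all_quads()
        out = {}
        for name, (rule, extra) in self.link_rules.items():
            if rule.rule_kind == "exact_key":
                out[name] = discover_exact_links(quads, quads, rule)
            else:
                out[name] = discover_positional_links(
                    quads, quads, rule, extra["left_cse"], extra["right_cse"]
                )
        return out

    def link_quads(self) -> list[Quad]:
        links: set[Link] = set()
        for found in self.discover_links().values():
            links |= found
        return links_to_quads(links)

    def linked_federation(self) -> Federation:
        """The federation with discovered owl:sameAs links registered as
        the mediator's links source."""
        fed = Federation(self.federation.sources.values())
        fed.add_links(self.link_quads())
        return fed


def _cse(source: str) -> tuple:
    """(chrom, start, end) predicate triple for a source's CNV rows."""
    return (vocab(source, "chrom"), vocab(source, "start"), vocab(source, "end"))


def _default_rules(cancer_type: Optional[str]) -> dict:
    from .rdfize import graph_iri_for

    g = graph_iri_for
    rules = {
        "gene": (
            LinkRule(
                "exact_key",
                left=(g("cosmic", "expression"), vocab("cosmic", "gene")),
                right=(g("tcga", "expression", cancer_type), vocab("tcga", "gene")),
                normalizer="case_fold",
                name="gene",
            ),
            {},
        ),
        "sample": (
            LinkRule(
                "exact_key",
                left=(g("cosmic", "mutation"), vocab("cosmic", "sample")),
                right=(g("tcga", "methylation", cancer_type), vocab("tcga", "hybrid_ref")),
                normalizer="tcga_patient_barcode",
                name="sample",
            ),
            {},
        ),
        "gene_goa": (
            LinkRule(
                "exact_key",
                left=(g("tcga", "expression", cancer_type), vocab("tcga", "gene")),
                right=(g("goa", "annotation"), vocab("goa", "gene")),
                normalizer="case_fold",
                name="gene_goa",
            ),
            {},
        ),
        "cnv_pos": (
            LinkRule(
                "positional",
                left=(g("cosmic", "cnv"),),
                right=(g("tcga", "cnv", cancer_type),),
                mode="exact",
                name="cnv_pos",
            ),
            {"left_cse": _cse("cosmic"), "right_cse": _cse("tcga")},
        ),
    }
    return rules


def _assemble(tables_with_mappings: dict, endpoints: dict) -> tuple:
    """(Federation, graphs dict) from named tables and endpoint layout."""
    graphs, _stats = build_dataset(list(tables_with_mappings.values()))
    fed = Federation()
    for endpoint_id, table_names in endpoints.items():
        quads: list[Quad] = []
        for name in table_names:
            _, mapping = tables_with_mappings[name]
            quads.extend(graphs[mapping.graph_iri])
        fed.add_source(Source.from_quads(endpoint_id, quads))
    return fed, graphs


_ENDPOINT_LAYOUT = {
    "cosmic": ["cosmic_expression", "cosmic_mutation", "cosmic_cnv",
               "cosmic_methylation"],
    "tcga": ["tcga_cnv", "tcga_expression", "tcga_methylation"],
    "bio2rdf": ["goa", "kegg", "reactome"],
}


def generate_federation(spec: SynthSpec) -> FederationBundle:
    """Generate one federation under the spec's study conditions.

    Deterministic: identical spec (including seed) yields identical tables,
    quads and ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    ct = spec.cancer_type

    # --- key populations with exact planted overlap -----------------------
    n_shared_g = math.floor(spec.shared_gene_fraction * spec.n_genes)
    if n_shared_g > spec.n_genes:
        raise SpecError("gene overlap exceeds population")
    pool = [f"GENE{i:04d}" for i in range(2 * spec.n_genes)]
    cosmic_genes = pool[: spec.n_genes]
    tcga_genes = pool[:n_shared_g] + pool[spec.n_genes: 2 * spec.n_genes - n_shared_g]

    def _noise(g: str) -> str:
        return g.capitalize() if spec.key_noise else g

    n_shared_s = math.floor(spec.shared_sample_fraction * spec.n_samples)
    patients = [f"TCGA-{i // 90 + 10:02d}-{1000 + i % 90:04d}"
                for i in range(2 * spec.n_samples)]
    cosmic_samples = patients[: spec.n_samples]
    tcga_barcodes = [
        p + "-01A"
        for p in patients[:n_shared_s]
        + patients[spec.n_samples: 2 * spec.n_samples - n_shared_s]
    ]

    # --- tables ------------------------------------------------------------
    def draw_locus(lo: int, hi: int) -> Locus:
        chrom = str(rng.integers(1, 23))
        start = int(rng.integers(lo, hi))
        return Locus(chrom, start, start + int(rng.integers(1_000, 50_000)))

    n_shared_p = math.floor(spec.shared_position_fraction * spec.n_cnv_segments)
    shared_loci = [draw_locus(1_000_000, 2_000_000) for _ in range(n_shared_p)]
    cosmic_cnv = [
        CNVRecord(
            sample_id=cosmic_samples[i % max(1, len(cosmic_samples))],
            locus=loc,
            cnv_type=("GAIN", "LOSS")[int(rng.integers(2))],
        )
        for i, loc in enumerate(
            shared_loci
            + [draw_locus(3_000_000, 4_000_000)
               for _ in range(spec.n_cnv_segments - n_shared_p)]
        )
    ]
    tcga_cnv = [
        CNVRecord(
            sample_id=tcga_barcodes[i % max(1, len(tcga_barcodes))],
            locus=loc,
            cnv_type=("GAIN", "LOSS")[int(rng.integers(2))],
        )
        for i, loc in enumerate(
            shared_loci
            + [draw_locus(5_000_000, 6_000_000)
               for _ in range(spec.n_cnv_segments - n_shared_p)]
        )
    ]

    def rpkm() -> float:
        return float(np.exp(rng.uniform(np.log(0.01), np.log(100.0))))

    cosmic_expr = [
        ExpressionRecord(gene_symbol=g, sample_id=t, value=rpkm())
        for g in cosmic_genes
        for t in spec.tissues
    ]
    tcga_expr = [
        ExpressionRecord(
            gene_symbol=_noise(g),
            sample_id=tcga_barcodes[i % max(1, len(tcga_barcodes))],
            value=rpkm(),
        )
        for i, g in enumerate(tcga_genes)
    ]

    mut_types = ["missense", "nonsense", "silent", "frameshift"]
    cosmic_mut = [
        MutationRecord(
            sample_id=cosmic_samples[i % max(1, len(cosmic_samples))],
            gene_symbol=cosmic_genes[i % max(1, len(cosmic_genes))],
            locus=draw_locus(1_000_000, 6_000_000),
            mutation_type=mut_types[int(rng.integers(len(mut_types)))],
            pmid=str(int(rng.integers(10_000_000, 30_000_000))),
        )
        for i in range(spec.n_mutations)
    ]

    sites = [f"cg{i:08d}" for i in range(2 * spec.n_methyl_sites)]

    def methyl(genes, samples, site_offset, noise=False):
        rows = []
        for i in range(spec.n_methyl_sites):
            g = genes[i % max(1, len(genes))]
            rows.append(
                MethylationRecord(
                    gene_symbol=_noise(g) if noise else g,
                    composite_element_ref=sites[site_offset + i],
                    locus=draw_locus(1_000_000, 6_000_000),
                    beta_value=float(rng.uniform(-1.0, 1.0)),
                    tumour_purity=float(rng.uniform(0.0, 1000.0)),
                    sample_id=samples[i % max(1, len(samples))] if samples else None,
                )
            )
        return rows

    cosmic_meth = methyl(cosmic_genes, cosmic_samples, 0)
    tcga_meth = methyl(tcga_genes, tcga_barcodes, spec.n_methyl_sites, noise=True)

    goa_genes = [_noise(g) for g in tcga_genes]
    goa_rows, kegg_rows, reactome_rows = [], [], []
    go_serial = 0
    for g in goa_genes:
        for _ in range(spec.go_per_gene):
            go_serial += 1
            go = f"GO:{go_serial:07d}"
            goa_rows.append(
                AnnotationRecord(gene_symbol=g, go_id=go,
                                 go_process=f"process {go_serial}")
            )
            for k in range(spec.pathway_per_go):
                kegg_rows.append(
                    AnnotationRecord(go_id=go, kegg_id=f"hsa{go_serial:05d}")
                )
                reactome_rows.append(
                    AnnotationRecord(go_id=go, reactome_id=f"R-HSA-{go_serial}")
                )

    tables = {
        "cosmic_expression": (cosmic_expr, default_mapping("cosmic", "expression")),
        "cosmic_mutation": (cosmic_mut, default_mapping("cosmic", "mutation")),
        "cosmic_cnv": (cosmic_cnv, default_mapping("cosmic", "cnv")),
        "cosmic_methylation": (cosmic_meth, default_mapping("cosmic", "methylation")),
        "tcga_cnv": (tcga_cnv, default_mapping("tcga", "cnv", ct)),
        "tcga_expression": (tcga_expr, default_mapping("tcga", "expression", ct)),
        "tcga_methylation": (tcga_meth, default_mapping("tcga", "methylation", ct)),
        "goa": (goa_rows, default_mapping("goa", "annotation")),
        "kegg": (kegg_rows, default_mapping("kegg", "annotation")),
        "reactome": (reactome_rows, default_mapping("reactome", "annotation")),
    }
    fed, graphs = _assemble(tables, _ENDPOINT_LAYOUT)

    # --- brute-force ground truth ------------------------------------------
    def gene_iri(source, symbol):
        return mint_iri(f"{BASE}{source}/", "gene", symbol)

    def sample_iri(source, sid):
        return mint_iri(f"{BASE}{source}/", "sample", sid)

    gene_links = frozenset(
        (gene_iri("cosmic", a), gene_iri("tcga", _noise(b)))
        for a in set(cosmic_genes)
        for b in set(tcga_genes)
        if a.upper() == _noise(b).upper()
    )
    mut_samples = {r.sample_id for r in cosmic_mut}
    meth_barcodes = {r.sample_id for r in tcga_meth}
    sample_links = frozenset(
        (sample_iri("cosmic", a), sample_iri("tcga", b))
        for a in mut_samples
        for b in meth_barcodes
        if "-".join(a.split("-")[:3]) == "-".join(b.split("-")[:3])
    )
    goa_gene_links = frozenset(
        (gene_iri("tcga", _noise(a)), gene_iri("goa", b))
        for a in set(tcga_genes)
        for b in set(goa_genes)
        if _noise(a).upper() == b.upper()
    )
    cnv_graph_c = tables["cosmic_cnv"][1].graph_iri
    cnv_graph_t = tables["tcga_cnv"][1].graph_iri
    cnv_links = frozenset(
        (URIRef(f"{cnv_graph_c}/row/{i}"), URIRef(f"{cnv_graph_t}/row/{j}"))
        for i, a in enumerate(cosmic_cnv)
        for j, b in enumerate(tcga_cnv)
        if (a.locus.chrom, a.locus.start, a.locus.end)
        == (b.locus.chrom, b.locus.start, b.locus.end)
    )
    truth = GroundTruth(
        gene_links=gene_links,
        sample_links=sample_links,
        goa_gene_links=goa_gene_links,
        cnv_links=cnv_links,
        shared_genes=tuple(pool[:n_shared_g]),
        shared_patients=tuple(patients[:n_shared_s]),
    )
    return FederationBundle(
        federation=fed,
        tables={k: v[0] for k, v in tables.items()},
        graphs=graphs,
        link_rules=_default_rules(ct),
        ground_truth=truth,
    )


def reference_fixture() -> FederationBundle:
    """The curated two-source-plus-annotations fixture behind the worked
    examples: the MYH7 promoter-methylation records (probe cg05744229 on
    chromosome 14, promoter starts 23904678 in the TCGA-shaped source and
    23435469 in the COSMIC-shaped source, beta 0.041999536 with tumour
    purity 773.555 on the COSMIC side and beta change -0.773 on the TCGA
    side), the two sample identities shared between COSMIC sample ids and
    TCGA barcodes (patients TCGA-13-0920 and TCGA-24-1850), the recurrent
    ovarian-cancer CNV loci (including chr14:23857092-23886486, LOSS, in
    both sources), and muscle/inflammation GO-process and pathway
    annotations for the fixture genes."""
    ct = "OV"
    cosmic_meth = [
        MethylationRecord(
            gene_symbol="MYH7", composite_element_ref="cg05744229",
            locus=Locus("14", 23_435_469, 23_435_669),
            beta_value=0.041999536, tumour_purity=773.555,
            sample_id="TCGA-13-0920",
        ),
        MethylationRecord(
            gene_symbol="MYH6", composite_element_ref="cg00000292",
            locus=Locus("14", 23_861_000, 23_861_200),
            beta_value=-0.12, tumour_purity=512.0,
            sample_id="TCGA-24-1850",
        ),
        MethylationRecord(
            gene_symbol="TG", composite_element_ref="cg26670875",
            locus=Locus("8", 133_880_000, 133_880_200),
            beta_value=0.33, tumour_purity=640.25,
            sample_id="TCGA-09-0366",
        ),
    ]
    tcga_meth = [
        MethylationRecord(
            gene_symbol="MYH7", composite_element_ref="cg05744229",
            locus=Locus("14", 23_904_678, 23_904_878),
            beta_value=-0.773, tumour_purity=601.5,
            sample_id="TCGA-13-0920-01A",
        ),
        MethylationRecord(
            gene_symbol="MYH6", composite_element_ref="cg00000292",
            locus=Locus("14", 23_861_010, 23_861_210),
            beta_value=-0.41, tumour_purity=455.0,
            sample_id="TCGA-24-1850-01B",
        ),
        MethylationRecord(
            gene_symbol="ACTA1", composite_element_ref="cg18205205",
            locus=Locus("1", 229_431_000, 229_431_200),
            beta_value=0.27, tumour_purity=700.0,
            sample_id="TCGA-25-1313-01A",
        ),
    ]
    cosmic_mut = [
        MutationRecord(sample_id="TCGA-13-0920", gene_symbol="MYH7",
                       locus=Locus("14", 23_857_092, 23_886_486),
                       mutation_type="missense", pmid="1398522"),
        MutationRecord(sample_id="TCGA-24-1850", gene_symbol="MYH7",
                       locus=Locus("14", 23_857_082, 23_886_607),
                       mutation_type="nonsense", pmid="18559093"),
        MutationRecord(sample_id="TCGA-09-0366", gene_symbol="TG",
                       locus=Locus("6", 149_661, 384_546),
                       mutation_type="missense", pmid="21062161"),
    ]
    # recurrent CNV loci; the chr14 MYH6/MYH7 segments occur in both sources
    cosmic_cnv = [
        CNVRecord("TCGA-13-0920", Locus("14", 23_857_092, 23_886_486), "LOSS"),
        CNVRecord("TCGA-24-1850", Locus("14", 23_857_082, 23_886_607), "LOSS"),
        CNVRecord("TCGA-09-0366", Locus("6", 149_661, 384_546), "LOSS"),
        CNVRecord("TCGA-13-0920", Locus("5", 15_532, 24_132), "GAIN"),
        CNVRecord("TCGA-24-1850", Locus("19", 90_910, 715_430), "GAIN"),
    ]
    tcga_cnv = [
        CNVRecord("TCGA-13-0920-01A", Locus("14", 23_857_092, 23_886_486), "LOSS"),
        CNVRecord("TCGA-13-0920-01A", Locus("14", 23_857_082, 23_886_607), "LOSS"),
        CNVRecord("TCGA-25-1313-01A", Locus("9", 4_069_657, 4_684_967), "LOSS"),
    ]
    genes = ["MYH7", "MYH6", "TG", "ACTA1"]
    cosmic_expr = [
        ExpressionRecord(g, tissue, value)
        for g, tissue, value in [
            ("MYH7", "heart", 91.7), ("MYH7", "ovary", 0.52),
            ("MYH6", "heart", 64.3), ("MYH6", "ovary", 0.41),
            ("TG", "thyroid", 120.9), ("TG", "ovary", 0.38),
            ("ACTA1", "skeletal muscle", 210.4), ("ACTA1", "ovary", 0.61),
        ]
    ]
    tcga_expr = [
        ExpressionRecord(g, "TCGA-13-0920-01A", v)
        for g, v in [("MYH7", 1.8), ("MYH6", 1.1), ("TG", 3.6), ("ACTA1", 2.2)]
    ]
    goa_rows = [
        AnnotationRecord(gene_symbol="MYH7", go_id="GO:0030049",
                         go_process="muscle filament sliding"),
        AnnotationRecord(gene_symbol="MYH7", go_id="GO:0018119",
                         go_process="peptidyl-cysteine S-nitrosylation"),
        AnnotationRecord(gene_symbol="ACTA1", go_id="GO:0030049",
                         go_process="muscle filament sliding"),
        AnnotationRecord(gene_symbol="TG", go_id="GO:0002526",
                         go_process="acute inflammatory response"),
    ]
    kegg_rows = [
        AnnotationRecord(go_id="GO:0030049", kegg_id="hsa04260"),
        AnnotationRecord(go_id="GO:0002526", kegg_id="hsa04610"),
    ]
    reactome_rows = [
        AnnotationRecord(go_id="GO:0030049", reactome_id="R-HSA-390522"),
        AnnotationRecord(go_id="GO:0018119", reactome_id="R-HSA-3000170"),
    ]
    tables = {
        "cosmic_expression": (cosmic_expr, default_mapping("cosmic", "expression")),
        "cosmic_mutation": (cosmic_mut, default_mapping("cosmic", "mutation")),
        "cosmic_cnv": (cosmic_cnv, default_mapping("cosmic", "cnv")),
        "cosmic_methylation": (cosmic_meth, default_mapping("cosmic", "methylation")),
        "tcga_cnv": (tcga_cnv, default_mapping("tcga", "cnv", ct)),
        "tcga_expression": (tcga_expr, default_mapping("tcga", "expression", ct)),
        "tcga_methylation": (tcga_meth, default_mapping("tcga", "methylation", ct)),
        "goa": (goa_rows, default_mapping("goa", "annotation")),
        "kegg": (kegg_rows, default_mapping("kegg", "annotation")),
        "reactome": (reactome_rows, default_mapping("reactome", "annotation")),
    }
    fed, graphs = _assemble(tables, _ENDPOINT_LAYOUT)
    return FederationBundle(
        federation=fed,
        tables={k: v[0] for k, v in tables.items()},
        graphs=graphs,
        link_rules=_default_rules(ct),
        ground_truth=None,
    )


def expected_answers(
    federation: Federation, link_quads: Iterable[Quad], query: str
) -> Counter:
    """Oracle-computed answer multiset for a query over stores + links."""
    fed = Federation(federation.sources.values())
    fed.add_links(list(link_quads))
    return evaluate_union_oracle(query, fed)
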