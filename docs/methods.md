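# Methods

## Data model and conventions

Five record families model the relational side: mutation (sample, gene,
locus, type, optional ENSEMBL id and PMID), CNV (sample, locus, GAIN/LOSS
— deliberately no gene symbol, mirroring real segment exports), expression
(gene, sample-or-tissue, RPKM ≥ 0, optional over/under/normal regulation),
methylation (gene, cg-probe, promoter locus, beta, optional tumour purity)
and annotation (gene/ENSEMBL → GO id, GO process, KEGG id, REACTOME id; at
least one identifier required).

Genomic coordinates are **1-based inclusive** everywhere internally (the
COSMIC convention); conversion from other conventions belongs at the
reading boundary. Chromosome labels are normalized once at construction
(`chr` prefix stripped, X/Y/MT uppercased), so positional comparisons never
see dialect differences. Beta values are constrained to |β| ≤ 1 but may be
negative: a table can carry either raw beta levels or beta *changes*, and
which one is a per-table schema flag (`beta_is_delta`) carried for
provenance — both dialects share the same range.

Record invariants are enforced at construction; the TSV reader reports
every failing row with its 1-based row number and reason rather than
dropping it silently. Strict mode (fail on first bad row) is available;
skip-and-report is the default.

The non-synonymous mutation vocabulary defaults to
`{missense, nonsense, frameshift, splice-site}` and is configurable,
because export dialects disagree on labels; unknown labels are counted and
reported, never silently discarded.

## RDFization

Each (source, data-type[, cancer-type]) table becomes one named graph. Per
record the converter emits exactly one row resource, one `rdf:type` quad
and one quad per non-null field, so the triple count obeys the closed form
`n_triples = Σ_records (1 + #non-null fields)` — a law the tests check on
every fixture. Conversion is fully deterministic: row resources are
numbered in input order, key IRIs are minted from key text alone, and
nothing time- or randomness-dependent enters.

Shared-key fields (gene symbol, ENSEMBL id, sample id, composite element
REF) are emitted as **resource-valued** objects whose IRI percent-encodes
the key text (e.g. `…/cosmic/gene/MYH7`), because link discovery and
`owl:sameAs` joins operate on resources; the encoding is lossless and
`extract_rows` inverts the whole mapping. Coordinates are `xsd:integer`
literals; beta/RPKM/purity are `xsd:double`; remaining fields are plain
strings. Output is N-Quads rather than a triples-only format so the named-
graph partition the federator depends on survives serialization.

The predicate vocabulary is configuration with defaults under per-source
namespaces (`cosmic:`, `tcga:`, `goa:`, `kegg:`, `reactome:`). One dialect
difference is modelled deliberately: TCGA tables identify the measured
sample by hybridization ref (`tcga:hybrid_ref`) where COSMIC uses
`cosmic:sample`.

## Link discovery

Exact-key rules link key resources whose **normalized** key text is equal;
policies are `verbatim`, `case_fold`, and `tcga_patient_barcode`
(truncation to the first three dash-separated fields, i.e. patient level —
chosen because COSMIC sample ids align with TCGA barcodes only at patient
granularity). All policies are idempotent (property-tested). Discovery is
hash-based but defined — and verified — as equal to the exhaustive
pairwise comparison.

The positional rule links CNV row resources: `exact` mode requires the
same normalized chromosome and identical (start, end) and is the default,
since segment-position linking is stated without tolerance; `overlap` mode
with a symmetric `tolerance_bp` extension exists because real segment
boundaries differ between pipelines. Region→gene mapping uses ≥ 1 bp
overlap rather than containment so boundary-spanning genes are retained.

Discovered links are deduplicated, stored once in the rule's left→right
direction, and materialized into a dedicated links named graph
(`…/graphs/links`) instead of being merged into the sources: federation
then treats `owl:sameAs` as an explicit join relation with no rewriting or
transitive-closure semantics. Link statistics count deduplicated pairs per
source pair.

## Query federation

**Supported fragment.** `SELECT` (optionally `DISTINCT`) over a basic
graph pattern with bound or variable predicates plus simple comparison
`FILTER`s (`< <= > >= = !=` between a variable and a literal). Parsing
uses rdflib's SPARQL parser; any other construct raises
`UnsupportedQueryError`. The fragment is exactly what the query templates
need; rejecting the rest keeps the engine's semantics fully testable.

**Capability index.** The data summary is an exact predicate-level index:
predicate → set of (endpoint, graph) pairs holding ≥ 1 triple with it,
plus per-(predicate, endpoint, graph) triple counts. Exactness gives both
recall preservation (no contributing source is missed) and no
predicate-level false positives.

**Selection and planning.** Level 1 picks endpoints, level 2 named graphs,
both per triple pattern through the index; variable-predicate patterns
select everything (no pruning is sound there). Patterns whose selection is
a single (endpoint, graph) are grouped maximally per source into exclusive
groups — one sub-query each; multi-source patterns become union nodes
(one sub-query per source, bindings deduplicated so a triple replicated in
two graphs cannot double a solution, matching set-union semantics);
a pattern with empty selection marks the whole answer empty without
erroring. `owl:sameAs` patterns resolve on the links graph and act as the
mediator joins.

**Execution.** Each group is evaluated against its own graph by indexed
nested-loop matching; node results are then merged by hash joins on shared
variables, smallest intermediate result first (the count heuristic), ties
broken by deterministic plan order; filters apply after the joins and the
projection last (`DISTINCT` deduplicates projected rows). Solutions carry
provenance: the set of (endpoint, graph) pairs that contributed.

**Oracle.** `evaluate_union_oracle` merges every graph (sources + links)
into one rdflib `Graph` and evaluates the query with rdflib's own SPARQL
engine — a code path the federator never uses. The central correctness
property, asserted across many seeded synthetic federations, is multiset
equality of projected bindings between the two routes. Access mode is
in-memory only; the source registry keeps the seam where HTTP endpoints
would plug in, but client-mode HTTP execution is out of scope.

## Query templates and gene filters

The five templates substitute a gene's minted key IRIs into fixed BGPs:
mutation loci (COSMIC mutation rows × TCGA rows joined through the gene
sameAs link), promoter methylation (inner join of both sources' beta
values), methylation + GO process (three sources), gene → GO → REACTOME +
KEGG pathways (four sources), and promoter location for a (gene, probe,
chromosome) triple. Promoter location is executed as one per-source BGP
with provenance tagging, since the supported fragment has no `UNION`; each
per-source BGP is itself oracle-checked. Absent genes yield empty results,
never errors, so sweeping a whole gene panel cannot abort midway.

`filter_genes_by_rpkm` keeps genes **strictly** above the cutoff in every
required tissue (the boundary case at exactly the cutoff is excluded);
genes missing a required tissue are excluded and reported. Output order is
descending minimum-across-required-tissues, ties lexicographic, making the
result invariant to input row order. The cutoff (0.3747 in the worked
analyses) is an input parameter, not a derived constant. With no required
tissues, any value above the cutoff keeps the gene and the ordering score
is the gene's minimum observed value.

`rank_genes_by_mutation_frequency` orders genes by descending record count
(optionally restricted to a non-synonymous vocabulary), ties lexicographic
— the standard frequency-based driver-gene heuristic, deliberately simple.

## Synthetic federations

The generator emulates the *key structure* of the real federation: a
COSMIC-shaped endpoint (expression, mutation, CNV, methylation), a
TCGA-shaped endpoint (CNV, expression, methylation, hybrid-ref barcodes)
and a Bio2RDF-shaped annotation endpoint (GOA, KEGG, REACTOME). Defaults:
30 genes, 12 patients, 25 CNV segments, 40 methylation sites, 60 mutation
rows, 4 tissues, shared fractions 0.5 (genes), 0.5 (patients), 0.4 (CNV
positions), 2 GO terms per gene and 1 pathway per GO term — small enough
to brute-force, rich enough that every template joins non-trivially.

Overlap is planted exactly (`floor(fraction × count)` shared keys); unique
gene/sample keys are unique by construction and the shared/unique CNV
populations draw coordinates from disjoint ranges, so the planted link
sets provably equal the exhaustive pairwise comparison, which is how the
ground truth is computed (explicit double loops over the generated tables,
independent of the linker). Numeric values are simple declared
distributions — coordinates uniform within fixed ranges, beta uniform in
[−1, 1], RPKM log-uniform in [0.01, 100], purity uniform in [0, 1000].
Optional key noise (case-varied gene labels) exercises the normalization
policies and is off by default. Generation is deterministic per
(spec, seed): repeated runs serialize to byte-identical N-Quads.

What the generator does **not** emulate: realistic mutation spectra,
methylation profiles, linkage disequilibrium between data types, real
vocabulary quirks of COSMIC/TCGA exports, or full Bio2RDF vocabularies.
Passing tests therefore certify the *integration machinery* — linking,
selection, planning, join correctness — not biological fidelity, and say
nothing about headline counts from the full public repositories.

The curated `reference_fixture` complements the generator with the small
hand-assembled federation used by the worked examples: the MYH7
promoter-methylation records (probe cg05744229, chromosome 14, promoter
starts 23904678/23435469, beta 0.041999536 with purity 773.555, beta
change −0.773), the two shared patient identities, recurrent ovarian-
cancer CNV loci, and muscle/inflammation GO and pathway annotations.

## Numerical and engineering choices

- Floating-point literals are emitted as `xsd:double` from Python floats;
  equality checks in tests compare the decoded values, which round-trip
  exactly through N-Quads.
- Determinism throughout: minting has no randomness, plan node order and
  link serialization are sorted, join tie-breaks are positional; result
  *ordering* is otherwise unspecified (compare multisets).
- Degenerate inputs: empty tables, header-only TSVs, empty federations,
  empty link sets and absent predicates all produce empty results rather
  than errors; genuinely malformed inputs (bad IRIs, schema/column
  mismatches, invalid rule configurations) raise typed exceptions.
- Test problem sizes: the oracle-equivalence suite runs 50 seeded
  federations at a reduced spec (8 genes, 6 patients, 10 segments, 12
  sites); linker oracles use up to 200×200-segment and 100×100-key random
  fixtures. These sizes were chosen so every property is still checked
  against exhaustive brute force.

## Known limitations

- SPARQL coverage is intentionally narrow (no OPTIONAL/UNION/paths/
  aggregates/subqueries); the mediator has no cost model beyond triple
  counts and no bindings-passing to sources.
- sameAs handling is explicit-join only: no transitive closure across
  more than two sources, no equality inference inside sources.
- HTTP endpoints are not executed against; sources are in-memory graphs
  loaded from N-Quads.
- The TSV readers target well-formed exports with a header row; they are
  not byte-for-byte parsers of any specific repository dialect, and
  VCF/MAF ingestion is out of scope.
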