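# omicsfed

Linked-data integration and federated SPARQL querying of multi-omics
cancer tables.

## The problem

Cancer genomics evidence for a single gene is scattered across repositories
that do not share a schema: somatic-mutation and expression exports keyed by
gene symbol and sample id, CNV segment tables keyed only by genomic position
(`chr:start-end`), promoter-methylation tables keyed by CpG probe
(composite element REF) and beta value, and pathway/process annotation sets
(GO, KEGG, REACTOME) keyed by gene or GO id. Answering a question like
*"what promoter-level methylation change accompanies the mutations of MYH7,
and which biological processes and pathways are involved?"* requires joining
several such sources without first copying them into one warehouse.

`omicsfed` is a desk-scale toolkit for that workflow:

1. **RDFization** — convert each TSV export into RDF quads in its own named
   graph, with a deterministic IRI-minting scheme. Shared-key fields
   (gene symbol, ENSEMBL id, sample id, CpG probe) become *key resources*
   so cross-source joins operate on IRIs.
2. **Link discovery** — find `owl:sameAs` correspondences between sources:
   *exact-key* rules (after a normalization policy, e.g. truncating a TCGA
   barcode `TCGA-13-0920-01A` to its patient prefix `TCGA-13-0920`) and the
   *positional* rule for CNV segments, which carry no gene symbol and can
   only be equated by chromosome and coordinates.
3. **Query federation** — answer `SELECT` queries over basic graph patterns
   by *two-level source selection*: per triple pattern, first the relevant
   endpoints, then the relevant named graphs within them, via an exact
   predicate-level capability index (recall-preserving: no contributing
   source is ever dropped). Single-source pattern sets become exclusive
   groups (one sub-query each); results are merged with hash joins on
   shared variables, with `owl:sameAs` patterns acting as the mediator's
   join relation.

Every federated answer is verifiable against an independent oracle that
evaluates the same query over the set-union of all graphs in a single
store, and a synthetic-federation generator plants known key overlaps so
that link recall/precision and query soundness/completeness can be measured
exactly.

## Worked example

The curated fixture contains linked COSMIC-shaped and TCGA-shaped sources
with methylation, mutation, CNV, expression and annotation graphs for the
MYH7/MYH6/TG/ACTA1 gene neighbourhood:

```python
>>> from omicsfed import reference_fixture, q_promoter_location, q_promoter_methylation
>>> bundle = reference_fixture()
>>> fed = bundle.linked_federation()          # discovers the sameAs links
>>> q_promoter_location(fed, "MYH7", "cg05744229", "14")
[('cosmic', 23435469), ('tcga', 23904678)]
```

The federated promoter-location query finds the methylated promoter region
of MYH7 at probe cg05744229 on chromosome 14 in *both* sources — start
coordinate 23435469 in the COSMIC-shaped graph and 23904678 in the
TCGA-shaped graph — one solution per source, with provenance.

```python
>>> sols = q_promoter_methylation(fed, "MYH7")
>>> [str(v) for v in sols[0].values]
['http://omicsfed.example/cosmic/cer/cg05744229', '0.041999536',
 'http://omicsfed.example/tcga/cer/cg05744229', '-0.773']
```

One joined solution: the COSMIC-side beta value 0.041999536 and the
TCGA-side beta change −0.773 for the same probe, merged through the
`MYH7 owl:sameAs MYH7` gene link. Sample-identity linking on the same
fixture finds exactly the two shared patients (TCGA-13-0920, TCGA-24-1850).

The same pipeline runs from the shell:

```
omicsfed synth --seed 7 --out fed/          # synthetic federation + ground truth
omicsfed rdfize --schema meth.yaml --in meth.tsv --source cosmic --out meth.nq
omicsfed query --federation fed.yaml --query q.rq --links fed/links.nq \
               --out out.json --explain
omicsfed panel --federation fed.yaml --links fed/links.nq \
               --genes genes.txt --template meth --out panels/
```

## Layout

- `omicsfed.records` / `omicsfed.tables` — typed omics records and
  schema-driven TSV reading with row-level reject reporting
- `omicsfed.quads` / `omicsfed.rdfize` — quads, N-Quads IO, dataset
  statistics and the deterministic record→quad conversion
- `omicsfed.link` — normalization policies, exact-key and positional
  `owl:sameAs` discovery, region→gene mapping, link statistics
- `omicsfed.federate` — capability index, two-level source selection,
  query planning, execution and the union-store oracle
- `omicsfed.bank` — the five federated query templates and the RPKM /
  mutation-frequency gene filters
- `omicsfed.synth` — synthetic federations with planted ground truth and
  the curated worked-example fixture

See `docs/methods.md` for the data model, algorithms and design choices.
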