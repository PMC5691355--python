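# annokb

Integrate heterogeneous biomedical text-mining annotations into a unified,
SPARQL-queryable RDF knowledge base.

## The problem

Biomedical NER and relation-extraction tools emit their results in
incompatible formats — BioNLP shared-task standoff files, BioC XML, and
assorted dialects of both. Combining the output of several annotators over
the same literature (to raise confidence where tools agree, and coverage
where they differ) requires a common model and a queryable store. `annokb`
provides that ETL path:

1. **Read** BioNLP standoff (`T`/`R`/`E`/`N` lines) and BioC XML into one
   in-memory annotation model (documents, concept mentions with character
   spans, binary relations, trigger+argument events), validating span
   fidelity against the source text.
2. **Enrich** via a JSON mapping configuration: raw category tags map to
   ontology term URIs, relation types to ontology properties, and concepts
   lacking a semantic identifier are normalized by POSTing their covered
   text to a configurable service and extracting identifiers from the
   response with a path or regex selector (e.g. `[*].annotatedClass.@id`
   for a BioPortal-Annotator-style reply).
3. **Merge** multi-annotator output, keeping every annotation with its
   provenance and recording, per (document, span, topic identifier), which
   annotators agree on the attribution.
4. **Emit** RDF following the Annotation Ontology (AO) concept model. Each
   concept mention becomes an `ao:Annotation` node with `ao:exact` (the
   covered string), `ao:offset` / `ao:range` (character span), `ao:body`
   (the mapped category term), `ao:hasTopic` (one triple per semantic
   identifier, e.g. an OMIM or UMLS URI), `ao:onSourceDocument` (the
   source, e.g. a PubMed URI) and an annotator-provenance triple. Relations
   and events are *reified*: a fresh annotation node carries the typed link
   between member annotations — no direct edge between concept nodes is
   ever asserted.
5. **Query** the result with SPARQL 1.1 SELECT or with built-in templates,
   e.g. "which documents mention this concept":

   ```sparql
   SELECT DISTINCT ?source {
     ?annotation a ao:Annotation .
     ?annotation ao:hasTopic umls:C0234958 .
     ?annotation ao:onSourceDocument ?source .
   }
   ```

A seeded synthetic-corpus generator simulates two annotators with partially
overlapping attributions (one exporting BioC, one standoff), so the whole
pipeline is testable offline with gold-standard agreement records.

## Worked example

```sh
# generate a 20-document two-annotator corpus (BioC + standoff + gold)
annokb gen-fixtures --out fx --n-docs 20 --seed 42

# integrate both annotators into one knowledge base
annokb convert \
  --input fx/bioc.xml  --format bioc     --annotator toolA \
  --input fx/standoff  --format standoff --annotator toolB \
  --normalize mock --out kb.nt --serialization ntriples

# explore it
annokb stats --graph kb.nt
annokb query --graph kb.nt --topic umls:C0234958
```

The convert step logs per-stage counts, e.g.:

```
INFO annokb: annotator toolA: 20 documents, 58 concepts, 0 relations, 0 events
INFO annokb: annotator toolB: 20 documents, 62 concepts, 20 relations, 20 events
INFO annokb: merged: 20 documents, 120 concepts, 80 agreement records (40 with >1 supporter)
INFO annokb: graph: 1180 triples
```

120 concept mentions survive the merge intact (nothing is dropped); 40 of
the 80 distinct (document, span, topic) attributions are asserted by both
simulated annotators. The 1180 triples follow closed forms: 7 + *k* triples
per concept with *k* topics, 5 per reified relation, 4 + |args| per event,
plus one identifier triple per document. `annokb stats` then reports

```
triples 1180
concepts        120
relations       20
events  20
documents       20
topics  6
```

and the topic query lists the PubMed-style URIs of every document where
`umls:C0234958` (skeletal muscle atrophy) was attributed.

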