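# Methods

## The annotation model

`annokb` treats an *annotation* as a recorded assertion that a text span
denotes a concept, or that annotations stand in a typed relation or event.
The in-memory model has four annotation kinds:

* **Concept annotation** — one or more character-span fragments over a
  document, the covered string (`exact`), a raw category tag from the
  producing tool, and zero or more namespaced semantic identifiers
  (`topic_ids`, e.g. `OMIM:104300`, `umls:C0027061`).
* **Relation annotation** — a typed binary link between two concept
  annotations of the same document and annotator.
* **Event annotation** — a trigger concept plus one or more role-labelled
  member concepts (the n-ary generalization of a relation).
* **Agreement record** — a distinct (document, span, topic identifier)
  attribution together with the set of annotators asserting it.

All offsets are 0-based, half-open, counted in Unicode code points; `range`
in the RDF layer is fragment length (end − start). This matches the BioNLP
standoff convention and makes span fidelity an exact substring test:
validation checks, character for character, that `exact` equals the
document text sliced at each single-fragment span. Discontinuous standoff
spans (`0 5;10 15`) are kept as multiple fragments; `exact` is the
fragment texts joined by single spaces; the RDF layer publishes the
envelope (first offset, last end − first offset) because the published
concept model carries a single offset/range pair.

## Merging and agreement

Merging multi-annotator sets is conservative: every annotation is retained
with its annotator provenance; nothing is deduplicated or dropped. What
*is* aggregated is agreement: one record per distinct (document, span,
topic) triple observed, supported by the set of annotators asserting it.
Agreement is keyed on the semantic identifier, not the raw category tag —
two tools that tag the same span `Disease` and `DiseaseOrSyndrome` but
both attribute `umls:C0027061` count as agreeing. Matching is on exact
span equality; overlap-tolerant matching would be a natural extension but
is not implemented. Concepts with no identifier after normalization are
retained (they still produce category-level RDF) but contribute no
agreement record. Merge output ordering is deterministic
(document id, annotator, local id) and invariant to input order.

## Formats

The standoff reader accepts `T`/`R`/`E`/`N` lines; `A`/`M`/`*`/`#` lines
are skipped with a warning so partially supported exports still load, and
the `.ann` single-file and `.a1`/`.a2` split conventions are both handled
by concatenating annotation streams before parsing. A `T` line whose
covered text disagrees with the document substring at its span is a hard
parse error (offsets and text are out of sync; continuing would corrupt
every downstream span).

The BioC reader treats annotation offsets as document-level per the BioC
specification; when an annotation's text only matches after adding its
passage offset, the passage-relative offset is corrected and a warning
logged, so dialect drift is observable rather than silent. Identifier
infons become topics: `identifier`/`identifiers` values are split on `|`
or `;` and kept verbatim when already namespaced; a bare value under a
resource-named infon key (`<infon key="OMIM">104300</infon>`) is
namespaced by that key. Readers never invent namespaces beyond this rule.
A BioC relation with a `trigger`-role node, or with more than two nodes,
is read as an event (first node as trigger when no role says so);
otherwise two nodes make a binary relation. The trigger-role rule is what
lets one-argument events (two nodes) round-trip through BioC.

Both writers preserve local ids, so read∘write is the identity on valid
sets, and both are deterministic (sorted emission, no timestamps), so
repeated runs are byte-identical.

## Mapping and normalization

A JSON configuration drives enrichment: `tag_map` (category tag →
ontology term URI), `property_map` (relation/event type → property URI),
`services` (normalization endpoints), `default_namespace` and `prefixes`.
Category mapping is total: unmapped tags are minted under the default
namespace, so conversion never fails on unknown vocabulary. Unmapped
relation types fall back to one generic `relatedTo` property rather than
minting ad-hoc predicates per type; the raw type is preserved when the
configuration maps it.

Normalization posts the *annotation's exact string* — not the whole
document — as `text/plain` to each configured service, which makes
identifier-to-annotation attribution unambiguous. Identifiers are
extracted from the response with the service's selector: either a minimal
JSONPath-like path dialect (array wildcard `[*]`, object wildcard `*`,
dotted descent, literal keys including `@`-prefixed ones; leaf lists are
flattened one level) or a regular expression (all capture-group or
whole-match occurrences). Anything beyond the path dialect must be a
regex. Concepts that already carry identifiers are skipped: their
identifiers came with the annotation data and take precedence; whether a
second normalization pass should *add* cross-references is a policy
question we answer conservatively (no). Failures on individual concepts
are logged and do not abort the batch. The default test-time client is an
offline mock (exact string → identifiers lookup, replying in
BioPortal-Annotator shape); live HTTP sits behind the same one-method
contract.

## RDF emission

Annotation node URIs are minted deterministically from
(annotator, document id, local id), each part percent-encoded and joined
with `/` — injective by construction (no hashing, no counters), so two
runs over the same input build identical graphs and shared minting inputs
make graphs from different serializations of the same set isomorphic.

Concept emission is exactly 7 + *k* triples for *k* topics: type, exact,
offset, range, body, source document, provenance, plus one `ao:hasTopic`
per identifier. `exact` is a plain string literal; offset and range are
`xsd:integer` literals. `ao:body` carries the mapped category term (the
annotated resource); `ao:hasTopic` carries the semantic identifier — the
two are deliberately distinct. Topic identifiers expand through a prefix
table (UMLS → linkedlifedata, OMIM → BioPortal stems, both overridable;
unknown prefixes fall under the artifact namespace so every identifier
still yields a node).

Relations are reified: 5 triples (type, body, provenance, first-argument,
second-argument) on a fresh node; events are 4 + |args| (type, body,
provenance, trigger, one minted role property per argument). The member
concepts are never linked directly, which keeps relation semantics
uniform regardless of the specificity of the relation type, and makes
"no concept-to-concept triple" a checkable graph invariant. Provenance is
one literal-valued triple per annotation naming the tool; a
named-graph-per-annotator layout would also work but serializes
differently across stores, so the single-triple form is the default.

Serialization: Turtle for humans, N-Triples for diffing — N-Triples lines
are sorted lexicographically so equal graphs serialize byte-identically.

## Querying

Query templates and result normalization live in `annokb.query`; SPARQL
evaluation itself is delegated to rdflib's SPARQL 1.1 engine (query
execution is standard machinery, not this package's contribution). One
normalization quirk: results are read from the engine's binding list
because row iteration drops the empty solution of an empty group pattern,
which the SPARQL algebra defines as one (empty) solution. Inference rules
and federation are out of scope; statistics are computed on asserted
triples only.

## Synthetic corpora

The generator emulates the *shape* of a multi-tool annotation workflow,
not its language: deterministic filler sentences with known biomedical
surface strings planted at recorded offsets; two annotators, one
exporting BioC and one standoff (mirroring the common literature-NER vs
clinical-NLP format split); `round(overlap_fraction × mentions)` of each
document's attributions asserted by both, the rest randomly by one. The
standoff-side annotator additionally emits `degree_of`/`location_of`
relations and one-argument events. Defaults: 20 documents, 4 mentions per
document, overlap 0.5, one relation and one event per document, seed 42 —
a desk-scale corpus in which every vocabulary entry occurs many times,
chosen so each topic appears in multiple documents and in shared
attributions. The vocabulary carries real identifiers (OMIM 104300 for
Alzheimer disease, UMLS C0234958 for skeletal muscle atrophy, UMLS
C0027061) so worked examples use genuine terminology.

Because filler text never contains vocabulary surfaces, gold offsets are
unique and exact by construction; the generator's own attribution
bookkeeping is the oracle for merge-time agreement. What passing tests on
these fixtures do **not** show: robustness to real NER noise (boundary
errors, overlapping and nested mentions, identifier disambiguation
failures), passage-heavy BioC exports, or corpus scale — the triple-count
arithmetic is exact at any size, but performance beyond desk scale is
unmeasured.

## Numerical and degenerate-input choices

* Empty annotation files and empty collections parse to empty sets; an
  empty merge input is an error (there is nothing to merge), but a single
  set merges fine (all agreement counts 1).
* `round()` (banker's rounding at .5) decides the shared-mention count;
  it is applied per document to a small integer so the choice is visible
  and deterministic.
* Relation/event generation silently degrades when a document's
  standoff-side annotator has fewer than two concepts (no valid member
  pair exists).
* Validation is reporting by default; `--strict` raises on the first
  violation. Parse errors always carry line numbers (standoff) or element
  ids (BioC).

## Known limitations

Agreement requires exact span equality; nested/overlapping mention
structures are preserved but not specially analyzed; inter-annotator
statistics (kappa) are out of scope; the BioC writer emits one passage
per document; no OWL reasoning, free-text indexing, or federated query —
the emitted Turtle/N-Triples load into any store that provides those.
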