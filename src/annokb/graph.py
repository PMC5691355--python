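"""Annotation-Ontology RDF emission.

Every concept annotation becomes one annotation node carrying:

* ``rdf:type ao:Annotation``;
* ``ao:exact`` — the covered character sequence (plain string literal);
* ``ao:offset`` — distance in characters from the start of the document
  (integer literal);
* ``ao:range`` — number of characters starting from the offset (integer
  literal); for discontinuous mentions, offset/range publish the envelope
  (first fragment start to last fragment end);
* ``ao:body`` — the mapped ontology term for the annotated resource
  (the category);
* ``ao:hasTopic`` — one triple per semantic identifier, expanded to a
  resolvable URI (e.g. OMIM, UMLS);
* ``ao:onSourceDocument`` — the source document URI (provenance link);
* one provenance triple naming the annotator tool.

Relations are reified: the relationship is never asserted directly
between the two member annotation URIs. Instead a new annotation node is
created whose ``ao:body`` carries the mapped relation type and which
links to its members through first-/second-argument properties. Events
follow the same reified shape with a trigger link plus one role-labelled
membership triple per argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from urllib.parse import quote

from rdflib import RDF, Graph, Literal, Namespace, URIRef
from rdflib.namespace import DCTERMS, XSD

from .mapping import MappingConfig, map_category, map_relation_type
from .model import (
    ConceptAnnotation,
    Document,
    EventAnnotation,
    MergedCorpus,
    RelationAnnotation,
)

AO = Namespace("http://purl.org/ao/")
ANNOKB = Namespace("https://w3id.org/annokb/vocab/")

#: default URI namespace under which annotation nodes are minted
ANNOTATION_NS = "https://w3id.org/annokb/annotation/"

#: built-in expansion table for namespaced topic identifiers
TOPIC_PREFIXES: dict[str, str] = {
    "umls": "http://linkedlifedata.com/resource/umls/id/",
    "UMLS": "http://linkedlifedata.com/resource/umls/id/",
    "OMIM": "http://purl.bioontology.org/ontology/OMIM/",
    "omim": "http://purl.bioontology.org/ontology/OMIM/",
}

#: fallback namespace for topic identifiers with unknown prefixes
UNKNOWN_TOPIC_NS = "https://w3id.org/annokb/topic/"


@dataclass(frozen=True)
class AOVocabulary:
    """The seven Annotation Ontology URIs the emitters use.

    Defaults follow the Annotation Ontology naming; all are overridable
    for stores that deploy a different annotation vocabulary.
    """

    annotation_class: URIRef = AO.Annotation
    exact_prop: URIRef = AO.exact
    offset_prop: URIRef = AO.offset
    range_prop: URIRef = AO.range
    body_prop: URIRef = AO.body
    topic_prop: URIRef = AO.hasTopic
    source_doc_prop: URIRef = AO.onSourceDocument

    def __post_init__(self) -> None:
        uris = (
            self.annotation_class, self.exact_prop, self.offset_prop,
            self.range_prop, self.body_prop, self.topic_prop,
            self.source_doc_prop,
        )
        if len(set(uris)) != len(uris):
            raise ValueError("AOVocabulary URIs must be pairwise distinct")


DEFAULT_VOCAB = AOVocabulary()

#: provenance property: annotation node -> annotator tool name (literal)
ANNOTATED_BY = ANNOKB.annotatedBy
#: reified relation membership properties
FIRST_ARG = ANNOKB.firstArgument
SECOND_ARG = ANNOKB.secondArgument
TRIGGER = ANNOKB.trigger
#: namespace under which event role properties are minted
ROLE_NS = "https://w3id.org/annokb/role/"


def mint_uri(
    namespace: str, doc_id: str, annotator: str, local_id: str
) -> URIRef:
    """Mint the deterministic URI of one annotation node.

    Injective over distinct (doc_id, annotator, local_id) triples: each
    part is percent-encoded (no unescaped separators survive) and joined
    with ``/``. Stable across runs — no hashing, no counters.
    """
    for name, part in (("namespace", namespace), ("doc_id", doc_id),
                       ("annotator", annotator), ("local_id", local_id)):
        if not part:
            raise ValueError(f"mint_uri: empty {name}")
    enc = lambda s: quote(s, safe="")
    return URIRef(f"{namespace}{enc(annotator)}/{enc(doc_id)}/{enc(local_id)}")


def expand_topic(topic_id: str, cfg: MappingConfig | None = None) -> URIRef:
    """Expand a namespaced identifier (``OMIM:104300``) to a full URI.

    Already-absolute URIs pass through. Known prefixes (built-in table
    plus any configured ones) expand to their resource stems; unknown
    prefixes expand under the artifact topic namespace so every
    identifier still yields a dereferenceable node.
    """
    if "://" in topic_id:
        return URIRef(topic_id)
    table = dict(TOPIC_PREFIXES)
    if cfg is not None:
        table.update(cfg.prefixes)
    if ":" in topic_id:
        prefix, ident = topic_id.split(":", 1)
        if prefix in table:
            return URIRef(table[prefix] + quote(ident, safe=""))
    return URIRef(UNKNOWN_TOPIC_NS + quote(topic_id, safe=""))


def emit_concept(
    ann: ConceptAnnotation,
    doc: Document,
    vocab: AOVocabulary = DEFAULT_VOCAB,
    cfg: MappingConfig | None = None,
    namespace: str = ANNOTATION_NS,
) -> set[tuple]:
    """Emit the triples of one concept annotation: exactly ``7 + k`` for
    ``k`` topic identifiers (type, exact, offset, range, body, source
    document, provenance, plus one topic triple per identifier)."""
    cfg = cfg or MappingConfig()
    node = mint_uri(namespace, ann.doc_id, ann.annotator, ann.local_id)
    offset, length = ann.envelope()
    triples = {
        (node, RDF.type, vocab.annotation_class),
        (node, vocab.exact_prop, Literal(ann.exact)),
        (node, vocab.offset_prop, Literal(offset, datatype=XSD.integer)),
        (node, vocab.range_prop, Literal(length, datatype=XSD.integer)),
        (node, vocab.body_prop, URIRef(map_category(cfg, ann.category_tag))),
        (node, vocab.source_doc_prop, URIRef(doc.source_uri)),
        (node, ANNOTATED_BY, Literal(ann.annotator)),
    }
    for topic in ann.topic_ids:
        triples.add((node, vocab.topic_prop, expand_topic(topic, cfg)))
    return triples


def emit_relation(
    rel: RelationAnnotation,
    vocab: AOVocabulary = DEFAULT_VOCAB,
    cfg: MappingConfig | None = None,
    namespace: str = ANNOTATION_NS,
) -> set[tuple]:
    """Emit the reified form of a binary relation: exactly 5 triples.

    A fresh annotation node carries the relation; no triple directly
    links the two member annotation URIs.
    """
    cfg = cfg or MappingConfig()
    node = mint_uri(namespace, rel.doc_id, rel.annotator, rel.local_id)
    arg1 = mint_uri(namespace, rel.doc_id, rel.annotator, rel.arg1_ref)
    arg2 = mint_uri(namespace, rel.doc_id, rel.annotator, rel.arg2_ref)
    return {
        (node, RDF.type, vocab.annotation_class),
        (node, vocab.body_prop, URIRef(map_relation_type(cfg, rel.type_tag))),
        (node, FIRST_ARG, arg1),
        (node, SECOND_ARG, arg2),
        (node, ANNOTATED_BY, Literal(rel.annotator)),
    }


def emit_event(
    ev: EventAnnotation,
    vocab: AOVocabulary = DEFAULT_VOCAB,
    cfg: MappingConfig | None = None,
    namespace: str = ANNOTATION_NS,
) -> set[tuple]:
    """Emit the reified form of an event: exactly ``4 + |args|`` triples
    (type, body, provenance, trigger link, one role-labelled membership
    triple per argument)."""
    cfg = cfg or MappingConfig()
    node = mint_uri(namespace, ev.doc_id, ev.annotator, ev.local_id)
    trigger = mint_uri(namespace, ev.doc_id, ev.annotator, ev.trigger_ref)
    triples = {
        (node, RDF.type, vocab.annotation_class),
        (node, vocab.body_prop, URIRef(map_relation_type(cfg, ev.type_tag))),
        (node, ANNOTATED_BY, Literal(ev.annotator)),
        (node, TRIGGER, trigger),
    }
    for role, ref in ev.args:
        member = mint_uri(namespace, ev.doc_id, ev.annotator, ref)
        role_prop = URIRef(ROLE_NS + quote(role, safe=""))
        triples.add((node, role_prop, member))
    return triples


def build_graph(
    merged: MergedCorpus,
    vocab: AOVocabulary = DEFAULT_VOCAB,
    cfg: MappingConfig | None = None,
    namespace: str = ANNOTATION_NS,
) -> Graph:
    """Build the knowledge-base graph from merged multi-annotator output.

    The graph is the union of all per-annotation emissions plus one
    ``dcterms:identifier`` triple per document linking its source URI to
    its document identifier. Set semantics: exact duplicate triples
    collapse.
    """
    cfg = cfg or MappingConfig()
    g = Graph()
    g.bind("ao", AO)
    g.bind("annokb", ANNOKB)
    g.bind("dcterms", DCTERMS)
    for doc in merged.documents.values():
        g.add((URIRef(doc.source_uri), DCTERMS.identifier, Literal(doc.doc_id)))
    for c in merged.concepts:
        doc = merged.documents[c.doc_id]
        for t in emit_concept(c, doc, vocab, cfg, namespace):
            g.add(t)
    for r in merged.relations:
        for t in emit_relation(r, vocab, cfg, namespace):
            g.add(t)
    for e in merged.events:
        for t in emit_event(e, vocab, cfg, namespace):
            g.add(t)
    return g


def serialize(graph: Graph, format: str = "turtle") -> str:
    """Serialize a graph as Turtle or N-Triples.

    N-Triples output is sorted lexicographically, so equal graphs always
    serialize to byte-identical documents.
    """
    if format in ("ntriples", "nt", "nt11"):
        lines = sorted(
            line
            for line in graph.serialize(format="nt11").splitlines()
            if line.strip()
        )
        return "\n".join(lines) + ("\n" if lines else "")
    if format in ("turtle", "ttl"):
        return graph.serialize(format="turtle")
    raise ValueError(f"unknown serialization format {format!r}")
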