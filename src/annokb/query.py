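"""Exploration queries over the emitted knowledge base.

The canonical exploration task — "in which documents was this concept
identified?" — is the three-pattern SPARQL query

.. code-block:: sparql

    SELECT DISTINCT ?source {
      ?annotation a ao:Annotation .
      ?annotation ao:hasTopic <topic> .
      ?annotation ao:onSourceDocument ?source .
    }

:func:`documents_with_topic` evaluates exactly that pattern;
:func:`run_sparql` accepts arbitrary SPARQL 1.1 SELECT text (execution
is delegated to rdflib's engine — the templates and result
normalization live here). Results are deterministically ordered.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdflib import RDF, Graph, URIRef

from .graph import ANNOTATED_BY, DEFAULT_VOCAB, AOVocabulary, expand_topic
from .mapping import MappingConfig

#: prefix declarations prepended to user queries that omit them
STANDARD_PREFIXES = """\
PREFIX ao: <http://purl.org/ao/>
PREFIX annokb: <https://w3id.org/annokb/vocab/>
PREFIX dcterms: <http://purl.org/dc/terms/>
PREFIX umls: <http://linkedlifedata.com/resource/umls/id/>
PREFIX OMIM: <http://purl.bioontology.org/ontology/OMIM/>
"""


@dataclass
class QueryResult:
    """Ordered SELECT results: variable names plus binding rows."""

    variables: list[str]
    rows: list[dict[str, str]]

    def as_tsv(self) -> str:
        header = "\t".join(self.variables)
        lines = [header] + [
            "\t".join(row.get(v, "") for v in self.variables) for row in self.rows
        ]
        return "\n".join(lines) + "\n"


def _topic_uri(topic, cfg: MappingConfig | None) -> URIRef:
    if isinstance(topic, URIRef):
        return topic
    return expand_topic(str(topic), cfg)


def documents_with_topic(
    graph: Graph,
    topic: str | URIRef,
    vocab: AOVocabulary = DEFAULT_VOCAB,
    cfg: MappingConfig | None = None,
) -> list[str]:
    """Distinct source documents carrying annotations with this topic.

    ``topic`` may be a full URI or a namespaced identifier such as
    ``umls:C0234958``. Operationally identical to the three-pattern
    SPARQL query above; the result is sorted.
    """
    target = _topic_uri(topic, cfg)
    sources = set()
    for ann in graph.subjects(RDF.type, vocab.annotation_class):
        if (ann, vocab.topic_prop, target) in graph:
            for source in graph.objects(ann, vocab.source_doc_prop):
                sources.add(str(source))
    return sorted(sources)


def agreement_for_topic(
    graph: Graph,
    topic: str | URIRef,
    vocab: AOVocabulary = DEFAULT_VOCAB,
    cfg: MappingConfig | None = None,
) -> list[tuple[str, tuple[int, int], int]]:
    """Annotator agreement per span for one topic.

    Returns ``(source document URI, (offset, range), distinct annotator
    count)`` for every span at which the topic was asserted, sorted. The
    counts match the merge-time agreement records for the same corpus:
    spans where several tools assert the same identifier are the
    attributions most likely to be correct.
    """
    target = _topic_uri(topic, cfg)
    supporters: dict[tuple[str, int, int], set[str]] = {}
    for ann in graph.subjects(vocab.topic_prop, target):
        if (ann, RDF.type, vocab.annotation_class) not in graph:
            continue
        sources = list(graph.objects(ann, vocab.source_doc_prop))
        offsets = list(graph.objects(ann, vocab.offset_prop))
        ranges = list(graph.objects(ann, vocab.range_prop))
        annotators = list(graph.objects(ann, ANNOTATED_BY))
        if not (sources and offsets and ranges):
            continue
        key = (str(sources[0]), int(offsets[0]), int(ranges[0]))
        supporters.setdefault(key, set()).update(str(a) for a in annotators)
    return [
        (source, (offset, length), len(names))
        for (source, offset, length), names in sorted(supporters.items())
    ]


def run_sparql(graph: Graph, query_text: str) -> QueryResult:
    """Execute a SPARQL SELECT query and normalize its results.

    Standard prefixes (ao:, umls:, OMIM:, dcterms:) are prepended when
    the query does not declare its own. Rows are sorted by their binding
    values for deterministic output.
    """
    text = query_text
    if "PREFIX" not in text and "prefix" not in text:
        text = STANDARD_PREFIXES + text
    result = graph.query(text)
    variables = [str(v) for v in (result.vars or [])]
    rows = []
    # iterate .bindings, not the result rows: row iteration silently drops
    # the empty solution of an empty group pattern
    for binding in result.bindings:
        rows.append({str(var): str(value) for var, value in binding.items()})
    rows.sort(key=lambda r: tuple(r.get(v, "") for v in variables))
    return QueryResult(variables, rows)


@dataclass
class GraphStats:
    """Headline counts of a knowledge-base graph."""

    triples: int
    concepts: int
    relations: int
    events: int
    documents: int
    topics: int


def graph_stats(graph: Graph, vocab: AOVocabulary = DEFAULT_VOCAB) -> GraphStats:
    """Count annotations by structural pattern.

    Concept nodes carry ``ao:exact``; reified relation nodes carry a
    first-argument link; event nodes a trigger link. Documents are
    counted from their identifier triples; topics are distinct
    ``ao:hasTopic`` objects.
    """
    from rdflib.namespace import DCTERMS

    from .graph import FIRST_ARG, TRIGGER

    annotations = set(graph.subjects(RDF.type, vocab.annotation_class))
    concepts = sum(
        1 for a in annotations if (a, vocab.exact_prop, None) in graph
    )
    relations = sum(1 for a in annotations if (a, FIRST_ARG, None) in graph)
    events = sum(1 for a in annotations if (a, TRIGGER, None) in graph)
    documents = len(set(graph.subjects(DCTERMS.identifier, None)))
    topics = len(set(graph.objects(None, vocab.topic_prop)))
    return GraphStats(
        triples=len(graph),
        concepts=concepts,
        relations=relations,
        events=events,
        documents=documents,
        topics=topics,
    )
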