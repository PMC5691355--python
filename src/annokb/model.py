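"""Unified in-memory annotation model.

All format readers populate these containers and all RDF emitters consume
them. An annotation records that a text span denotes a concept (a
:class:`ConceptAnnotation`), or that concept annotations stand in a typed
binary relation (:class:`RelationAnnotation`) or an n-ary event
(:class:`EventAnnotation`). Each annotation keeps the name of the tool that
produced it, so multi-annotator corpora can be merged without losing
provenance and shared concept attributions can be counted.

Coordinate convention: offsets are 0-based character (Unicode code point)
indices from the start of the document; spans are half-open, so a fragment
covers ``text[offset : offset + length]``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union


class AnnotationError(Exception):
    """Base class for annotation-layer errors."""


class DanglingReferenceError(AnnotationError):
    """A relation or event refers to a local_id that does not resolve."""


class ValidationError(AnnotationError):
    """Strict validation found an inconsistent annotation set."""


class DocumentConflictError(AnnotationError):
    """Two annotation sets disagree on the text of the same document."""


@dataclass(frozen=True)
class Fragment:
    """A contiguous text span: ``offset`` code points in, ``length`` long."""

    offset: int
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class Document:
    """Source text plus a stable identifier (e.g. a PubMed ID)."""

    doc_id: str
    text: str
    source_uri: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise AnnotationError("doc_id must be non-empty")
        if not self.source_uri:
            self.source_uri = default_source_uri(self.doc_id)


def default_source_uri(doc_id: str) -> str:
    """Mint a resolvable source URI for a document identifier.

    All-digit identifiers are treated as PubMed IDs; anything else falls
    under the artifact document namespace.
    """
    if doc_id.isdigit():
        return f"https://pubmed.ncbi.nlm.nih.gov/{doc_id}"
    from urllib.parse import quote

    return f"https://w3id.org/annokb/document/{quote(doc_id, safe='')}"


@dataclass
class ConceptAnnotation:
    """A text-bound annotation: span(s), covered text, category, topics.

    ``category_tag`` is the raw label assigned by the annotator (e.g.
    ``Disease``); ``topic_ids`` holds namespaced semantic identifiers
    (e.g. ``OMIM:104300``, ``umls:C0027061``), possibly empty before
    normalization. Discontinuous mentions keep one :class:`Fragment` per
    piece; ``exact`` is then the fragment texts joined by single spaces.
    """

    local_id: str
    annotator: str
    doc_id: str
    fragments: Sequence[Fragment]
    exact: str
    category_tag: str
    topic_ids: list[str] = field(default_factory=list)

    def envelope(self) -> tuple[int, int]:
        """(offset, length) covering all fragments: first start to last end."""
        first = self.fragments[0].offset
        last = max(f.end for f in self.fragments)
        return first, last - first


@dataclass
class RelationAnnotation:
    """A typed binary link between two concept annotations."""

    local_id: str
    annotator: str
    doc_id: str
    type_tag: str
    arg1_ref: str
    arg2_ref: str


@dataclass
class EventAnnotation:
    """An n-ary association: a trigger concept plus role-labelled members."""

    local_id: str
    annotator: str
    doc_id: str
    type_tag: str
    trigger_ref: str
    args: list[tuple[str, str]]  # (role label, member local_id)


@dataclass(frozen=True)
class AgreementRecord:
    """A concept attribution and the annotators that assert it.

    One record per distinct (document, span, topic identifier) triple seen
    during a merge; ``supporting_annotators`` holds every tool asserting
    that attribution. Two or more supporters mean independent annotators
    agree on the same semantic identifier at the same span, which raises
    confidence that the concept was correctly identified.
    """

    doc_id: str
    offset: int
    length: int
    topic_id: str
    supporting_annotators: frozenset[str]

    @property
    def span(self) -> tuple[int, int]:
        return self.offset, self.length


@dataclass
class Violation:
    """One invariant violation found by :func:`validate_set`."""

    kind: str
    doc_id: str
    local_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.kind}] {self.doc_id}/{self.local_id}: {self.message}"


class AnnotationSet:
    """One annotator's output: documents plus keyed annotation collections.

    Concepts, relations and events are keyed by ``(doc_id, local_id)``.
    """

    def __init__(self, annotator: str):
        self.annotator = annotator
        self.documents: dict[str, Document] = {}
        self.concepts: dict[tuple[str, str], ConceptAnnotation] = {}
        self.relations: dict[tuple[str, str], RelationAnnotation] = {}
        self.events: dict[tuple[str, str], EventAnnotation] = {}

    def add_document(self, doc: Document) -> Document:
        if doc.doc_id in self.documents:
            existing = self.documents[doc.doc_id]
            if existing.text != doc.text:
                raise DocumentConflictError(
                    f"document {doc.doc_id!r} already present with different text"
                )
            return existing
        self.documents[doc.doc_id] = doc
        return doc

    def add_concept(self, ann: ConceptAnnotation) -> None:
        self.concepts[(ann.doc_id, ann.local_id)] = ann

    def add_relation(self, rel: RelationAnnotation) -> None:
        self.relations[(rel.doc_id, rel.local_id)] = rel

    def add_event(self, ev: EventAnnotation) -> None:
        self.events[(ev.doc_id, ev.local_id)] = ev

    def concept(self, doc_id: str, local_id: str) -> ConceptAnnotation:
        try:
            return self.concepts[(doc_id, local_id)]
        except KeyError:
            raise DanglingReferenceError(
                f"no concept {local_id!r} in document {doc_id!r} "
                f"(annotator {self.annotator!r})"
            ) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.annotator == other.annotator
            and self.documents == other.documents
            and self.concepts == other.concepts
            and self.relations == other.relations
            and self.events == other.events
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AnnotationSet({self.annotator!r}, docs={len(self.documents)}, "
            f"concepts={len(self.concepts)}, relations={len(self.relations)}, "
            f"events={len(self.events)})"
        )


def concat_sets(sets: Iterable[AnnotationSet]) -> AnnotationSet:
    """Combine several sets from the *same* annotator into one.

    Useful with readers that yield one set per document (BioC). Documents
    appearing in several inputs must carry identical text.
    """
    sets = list(sets)
    if not sets:
        raise AnnotationError("concat_sets requires at least one set")
    annotators = {s.annotator for s in sets}
    if len(annotators) != 1:
        raise AnnotationError(f"cannot concat sets from annotators {sorted(annotators)}")
    out = AnnotationSet(sets[0].annotator)
    for s in sets:
        for doc in s.documents.values():
            out.add_document(doc)
        out.concepts.update(s.concepts)
        out.relations.update(s.relations)
        out.events.update(s.events)
    return out


def validate_set(aset: AnnotationSet, strict: bool = False) -> list[Violation]:
    """Report every invariant violation in ``aset``.

    Checks: fragments in bounds, sorted and non-overlapping; single-fragment
    ``exact`` strings matching the document substring character for
    character; duplicate topic identifiers; dangling relation/event member
    references; references to unknown documents. Returns an empty list iff
    the set is consistent. In strict mode the first violation is raised as
    :class:`ValidationError`.
    """
    violations: list[Violation] = []

    def report(kind: str, doc_id: str, local_id: str, message: str) -> None:
        v = Violation(kind, doc_id, local_id, message)
        if strict:
            raise ValidationError(str(v))
        violations.append(v)

    for (doc_id, local_id), ann in aset.concepts.items():
        doc = aset.documents.get(doc_id)
        if doc is None:
            report("unknown-document", doc_id, local_id, "document not in set")
            continue
        if not ann.fragments:
            report("no-fragments", doc_id, local_id, "concept has no fragments")
            continue
        prev_end = -1
        in_bounds = True
        for frag in ann.fragments:
            if frag.offset < 0 or frag.length < 1 or frag.end > len(doc.text):
                report(
                    "span-out-of-bounds", doc_id, local_id,
                    f"fragment ({frag.offset},{frag.length}) outside document "
                    f"of length {len(doc.text)}",
                )
                in_bounds = False
            if frag.offset < prev_end:
                report(
                    "fragments-unordered", doc_id, local_id,
                    "fragments overlap or are not sorted by offset",
                )
            prev_end = frag.end
        if in_bounds:
            covered = " ".join(
                doc.text[f.offset : f.end] for f in ann.fragments
            )
            if covered != ann.exact:
                report(
                    "span-mismatch", doc_id, local_id,
                    f"exact {ann.exact!r} != document text {covered!r}",
                )
        if len(set(ann.topic_ids)) != len(ann.topic_ids):
            report("duplicate-topics", doc_id, local_id,
                   f"duplicate topic ids in {ann.topic_ids}")

    for (doc_id, local_id), rel in aset.relations.items():
        if doc_id not in aset.documents:
            report("unknown-document", doc_id, local_id, "document not in set")
        if rel.arg1_ref == rel.arg2_ref:
            report("self-relation", doc_id, local_id,
                   f"arg1 and arg2 both reference {rel.arg1_ref!r}")
        for ref in (rel.arg1_ref, rel.arg2_ref):
            if (doc_id, ref) not in aset.concepts:
                report("dangling-reference", doc_id, local_id,
                       f"relation member {ref!r} not found")

    for (doc_id, local_id), ev in aset.events.items():
        if doc_id not in aset.documents:
            report("unknown-document", doc_id, local_id, "document not in set")
        if not ev.args:
            report("empty-event", doc_id, local_id, "event has no arguments")
        refs = [ev.trigger_ref] + [r for _, r in ev.args]
        for ref in refs:
            if (doc_id, ref) not in aset.concepts:
                report("dangling-reference", doc_id, local_id,
                       f"event member {ref!r} not found")
        for role, _ in ev.args:
            if not role:
                report("empty-role", doc_id, local_id, "event argument with empty role")

    return violations


def resolve_members(
    aset: AnnotationSet,
    rel_or_event: Union[RelationAnnotation, EventAnnotation],
) -> list[ConceptAnnotation]:
    """Return the member concepts of a relation or event, in argument order.

    For relations: ``[arg1, arg2]``. For events: the trigger concept first,
    then the arguments in their declared order. Raises
    :class:`DanglingReferenceError` naming any missing local_id.
    """
    doc_id = rel_or_event.doc_id
    if isinstance(rel_or_event, RelationAnnotation):
        refs = [rel_or_event.arg1_ref, rel_or_event.arg2_ref]
    else:
        refs = [rel_or_event.trigger_ref] + [r for _, r in rel_or_event.args]
    return [aset.concept(doc_id, ref) for ref in refs]


@dataclass
class MergedCorpus:
    """Union of several annotators' output with provenance retained.

    Annotation lists are deterministically ordered by
    (doc_id, annotator, local_id).
    """

    documents: dict[str, Document]
    concepts: list[ConceptAnnotation]
    relations: list[RelationAnnotation]
    events: list[EventAnnotation]


def merge_sets(
    sets: Sequence[AnnotationSet],
) -> tuple[MergedCorpus, list[AgreementRecord]]:
    """Merge multi-annotator output into one corpus and count agreement.

    Every annotation is retained with its annotator provenance — merging
    never drops or fabricates annotations. Agreement is counted per
    distinct (doc_id, span, topic_id) attribution: one
    :class:`AgreementRecord` per triple observed, whose supporters are the
    annotators asserting it. The span of a concept is its fragment
    envelope. Concepts carrying no topic identifier contribute no record.

    Output ordering is deterministic and independent of the input list
    order. Raises :class:`DocumentConflictError` when two sets disagree on
    the text of a shared document.
    """
    if not sets:
        raise AnnotationError("merge_sets requires at least one AnnotationSet")

    documents: dict[str, Document] = {}
    for s in sorted(sets, key=lambda s: s.annotator):
        for doc in s.documents.values():
            if doc.doc_id in documents:
                if documents[doc.doc_id].text != doc.text:
                    raise DocumentConflictError(
                        f"conflicting text for document {doc.doc_id!r}"
                    )
            else:
                documents[doc.doc_id] = doc

    def sort_key(ann):
        return (ann.doc_id, ann.annotator, ann.local_id)

    concepts = sorted((c for s in sets for c in s.concepts.values()), key=sort_key)
    relations = sorted((r for s in sets for r in s.relations.values()), key=sort_key)
    events = sorted((e for s in sets for e in s.events.values()), key=sort_key)

    supporters: dict[tuple[str, int, int, str], set[str]] = {}
    for c in concepts:
        offset, length = c.envelope()
        for topic in c.topic_ids:
            supporters.setdefault(
                (c.doc_id, offset, length, topic), set()
            ).add(c.annotator)

    records = [
        AgreementRecord(doc_id, offset, length, topic, frozenset(names))
        for (doc_id, offset, length, topic), names in sorted(supporters.items())
    ]
    return MergedCorpus(documents, concepts, relations, events), records


def copy_set(aset: AnnotationSet, annotator: str | None = None) -> AnnotationSet:
    """Deep copy a set, optionally renaming the annotator throughout."""
    new = copy.deepcopy(aset)
    if annotator is not None:
        new.annotator = annotator
        for ann in (
            list(new.concepts.values())
            + list(new.relations.values())
            + list(new.events.values())
        ):
            ann.annotator = annotator
    return new
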