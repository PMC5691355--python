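"""Seeded synthetic corpora with gold-standard annotations.

Real evaluation corpora require running external concept-recognition
services; these fixtures instead emulate the *shape* of that setting so
every stage of the pipeline is testable offline: two simulated
annotators with partially overlapping concept attributions, one
exporting BioC XML and the other BioNLP standoff (mirroring the common
split between literature NER frameworks and clinical NLP systems).

Documents are deterministic filler sentences with known biomedical
surface strings planted at recorded positions, so gold offsets are exact
by construction and never collide with the filler text. The generator's
own bookkeeping of which annotator asserted which (document, span,
topic) attribution is the oracle against which merge-time agreement is
checked.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .mapping import MOCK_SERVICE, MappingConfig
from .model import (
    AgreementRecord,
    AnnotationSet,
    ConceptAnnotation,
    Document,
    EventAnnotation,
    Fragment,
    RelationAnnotation,
)

#: relation types the standoff-side annotator emits
RELATION_TYPES = ("degree_of", "location_of")
#: event type used for the simple one-argument events
EVENT_TYPE = "Gene_expression"

_FILLER = (
    "the patients presented with progressive findings and were",
    "clinical observation of the cohort revealed marked",
    "follow up examination confirmed persistent",
    "molecular analysis of the samples indicated",
    "reported literature describes frequent",
    "longitudinal assessment documented gradual",
)

_TAIL = (
    "in the majority of cases.",
    "across all examined subjects.",
    "during the observation period.",
    "with variable severity.",
    "confirmed by independent review.",
)


def default_vocab() -> list[tuple[str, str, str]]:
    """(surface string, category tag, topic id) vocabulary entries.

    Includes the canonical worked-example identifiers: the OMIM entry
    for Alzheimer disease, the UMLS concept for skeletal muscle atrophy,
    and the UMLS muscular-dystrophy concept.
    """
    return [
        ("Alzheimer Disease", "Disease", "OMIM:104300"),
        ("Skeletal muscle atrophy", "Finding", "umls:C0234958"),
        ("Muscular dystrophy", "Disease", "umls:C0027061"),
        ("Duchenne muscular dystrophy", "Disease", "OMIM:310200"),
        ("dystrophin", "Gene", "umls:C0057958"),
        ("chronic pain", "Symptom", "umls:C0150055"),
    ]


def default_config() -> MappingConfig:
    """Mapping configuration matching the fixture vocabulary.

    Maps the event type to its Gene Regulation Ontology class, gives the
    two relation types stable property URIs, and declares the offline
    mock normalization service.
    """
    return MappingConfig(
        tag_map={
            "Gene_expression": "http://purl.bioontology.org/ontology/GRO#GeneExpression",
        },
        property_map={
            "degree_of": "https://w3id.org/annokb/vocab/degreeOf",
            "location_of": "https://w3id.org/annokb/vocab/locationOf",
        },
        services=[MOCK_SERVICE],
    )


@dataclass
class FixtureSpec:
    """Parameters of one synthetic corpus; the seed fixes all randomness."""

    n_docs: int = 20
    vocab: list[tuple[str, str, str]] = field(default_factory=default_vocab)
    mentions_per_doc: int = 4
    relations_per_doc: int = 1
    events_per_doc: int = 1
    overlap_fraction: float = 0.5
    seed: int = 42
    annotator_a: str = "toolA"  # exports BioC
    annotator_b: str = "toolB"  # exports standoff

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.n_docs < 0:
            raise ValueError("n_docs must be >= 0")
        if self.n_docs > 0 and not self.vocab:
            raise ValueError("vocab must be non-empty when n_docs > 0")
        surfaces = [s for s, _, _ in self.vocab]
        if len(set(surfaces)) != len(surfaces):
            raise ValueError("vocabulary surface strings must be unique")


@dataclass
class FixtureCorpus:
    """Generator output: documents, both annotator sets, gold agreement."""

    documents: dict[str, Document]
    set_a: AnnotationSet
    set_b: AnnotationSet
    gold: list[AgreementRecord]


def generate(spec: FixtureSpec) -> FixtureCorpus:
    """Generate a corpus with two partially agreeing annotators.

    Per document, ``mentions_per_doc`` vocabulary entries are planted in
    filler sentences. ``round(overlap_fraction * mentions)`` of them are
    attributed by both annotators at identical (span, topic); the rest
    are randomly assigned to exactly one annotator. Annotator B
    additionally asserts typed relations and simple one-argument events
    over its own concepts. Everything is deterministic in the seed.
    """
    rng = random.Random(spec.seed)
    documents: dict[str, Document] = {}
    set_a = AnnotationSet(spec.annotator_a)
    set_b = AnnotationSet(spec.annotator_b)
    supporters: dict[tuple[str, int, int, str], set[str]] = {}

    for i in range(spec.n_docs):
        doc_id = str(25766617 + i)
        mentions = [rng.choice(spec.vocab) for _ in range(spec.mentions_per_doc)]

        parts: list[str] = []
        spans: list[tuple[int, int]] = []
        pos = 0
        for surface, _category, _topic in mentions:
            lead = rng.choice(_FILLER) + " "
            tail = " " + rng.choice(_TAIL) + " "
            parts.append(lead)
            pos += len(lead)
            spans.append((pos, len(surface)))
            parts.append(surface)
            pos += len(surface)
            parts.append(tail)
            pos += len(tail)
        text = "".join(parts).rstrip()
        doc = Document(doc_id, text)
        documents[doc_id] = doc
        set_a.add_document(doc)
        set_b.add_document(doc)

        n = len(mentions)
        n_shared = round(spec.overlap_fraction * n)
        shared = set(rng.sample(range(n), n_shared))
        to_a, to_b = [], []
        for idx in range(n):
            if idx in shared:
                to_a.append(idx)
                to_b.append(idx)
            elif rng.random() < 0.5:
                to_a.append(idx)
            else:
                to_b.append(idx)

        def add_concepts(aset: AnnotationSet, indices: list[int]) -> list[str]:
            ids = []
            for k, idx in enumerate(indices, start=1):
                surface, category, topic = mentions[idx]
                offset, length = spans[idx]
                local_id = f"T{k}"
                aset.add_concept(
                    ConceptAnnotation(
                        local_id=local_id,
                        annotator=aset.annotator,
                        doc_id=doc_id,
                        fragments=(Fragment(offset, length),),
                        exact=surface,
                        category_tag=category,
                        topic_ids=[topic],
                    )
                )
                supporters.setdefault(
                    (doc_id, offset, length, topic), set()
                ).add(aset.annotator)
                ids.append(local_id)
            return ids

        add_concepts(set_a, to_a)
        b_ids = add_concepts(set_b, to_b)

        for k in range(1, spec.relations_per_doc + 1):
            if len(b_ids) < 2:
                break
            arg1, arg2 = rng.sample(b_ids, 2)
            set_b.add_relation(
                RelationAnnotation(
                    f"R{k}", spec.annotator_b, doc_id,
                    rng.choice(RELATION_TYPES), arg1, arg2,
                )
            )
        for k in range(1, spec.events_per_doc + 1):
            if len(b_ids) < 2:
                break
            trigger, theme = rng.sample(b_ids, 2)
            set_b.add_event(
                EventAnnotation(
                    f"E{k}", spec.annotator_b, doc_id,
                    EVENT_TYPE, trigger, [("Theme", theme)],
                )
            )

    gold = [
        AgreementRecord(doc_id, offset, length, topic, frozenset(names))
        for (doc_id, offset, length, topic), names in sorted(supporters.items())
    ]
    return FixtureCorpus(documents, set_a, set_b, gold)


def write_fixture_tree(corpus: FixtureCorpus, outdir: str | Path) -> None:
    """Write the corpus to disk: standoff .txt/.ann pairs for annotator
    B, one BioC collection for annotator A, and gold.json."""
    from .bioc import write_bioc
    from .standoff import write_standoff

    outdir = Path(outdir)
    standoff_dir = outdir / "standoff"
    standoff_dir.mkdir(parents=True, exist_ok=True)
    for doc_id, (text, ann) in write_standoff(corpus.set_b).items():
        (standoff_dir / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        (standoff_dir / f"{doc_id}.ann").write_text(ann, encoding="utf-8")
    (outdir / "bioc.xml").write_text(write_bioc([corpus.set_a]), encoding="utf-8")
    gold = [
        {
            "doc_id": r.doc_id,
            "offset": r.offset,
            "length": r.length,
            "topic_id": r.topic_id,
            "supporting_annotators": sorted(r.supporting_annotators),
        }
        for r in corpus.gold
    ]
    (outdir / "gold.json").write_text(
        json.dumps(gold, indent=1), encoding="utf-8"
    )
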