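"""BioC XML reader and writer.

BioC is the community XML interchange format for text-mining results:
``collection > document > passage > annotation/relation``. Annotations
carry ``infon`` key/value metadata, one or more ``location`` elements with
document-level character offsets, and the covered ``text``. Relations hold
``node`` elements referencing annotation ids with role labels.

Reader conventions:

* the ``type`` infon becomes the concept's category tag;
* any other infon whose value names a semantic identifier populates
  ``topic_ids`` — an ``identifier``/``identifiers`` infon is split on
  ``|`` and each token kept verbatim when already namespaced
  (``OMIM:104300``), while a bare token under a resource-named infon key
  (``<infon key="OMIM">104300</infon>``) is namespaced by that key;
* offsets are taken as document-level (the BioC convention); if an
  annotation's text only matches after adding the enclosing passage
  offset, the passage-relative offset is corrected with a warning;
* a relation with a ``trigger``-role node (or more than two nodes) is an
  event; otherwise a two-node relation is a binary relation.
"""

from __future__ import annotations

import logging

from lxml import etree

from .model import (
    AnnotationSet,
    ConceptAnnotation,
    Document,
    EventAnnotation,
    Fragment,
    RelationAnnotation,
    validate_set,
)

log = logging.getLogger(__name__)

#: infon keys that never contribute topic identifiers
_NON_TOPIC_INFONS = {"type", "annotator", "note", "kind", "file", "date", "key"}


class BiocParseError(Exception):
    """Malformed or structurally invalid BioC content."""


def _infons(element) -> list[tuple[str, str]]:
    return [
        (inf.get("key", ""), inf.text or "")
        for inf in element.findall("infon")
    ]


def _topics_from_infons(infons: list[tuple[str, str]]) -> list[str]:
    topics: list[str] = []
    for key, value in infons:
        if key in _NON_TOPIC_INFONS or not value.strip():
            continue
        for token in value.replace(";", "|").split("|"):
            token = token.strip()
            if not token:
                continue
            topic = token if ":" in token else f"{key}:{token}"
            if topic not in topics:
                topics.append(topic)
    return topics


def read_bioc(xml: str | bytes, annotator: str) -> list[AnnotationSet]:
    """Parse a BioC collection into one AnnotationSet per document."""
    if isinstance(xml, str):
        xml = xml.encode("utf-8")
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise BiocParseError(f"malformed XML: {exc}") from exc
    if root.tag != "collection":
        raise BiocParseError(f"expected <collection> root, found <{root.tag}>")

    sets: list[AnnotationSet] = []
    for doc_el in root.findall("document"):
        doc_id = (doc_el.findtext("id") or "").strip()
        if not doc_id:
            raise BiocParseError("document without <id>")

        # Reconstruct the document text from passage offsets and texts.
        passages = doc_el.findall("passage")
        pieces: list[tuple[int, str]] = []
        for p in passages:
            offset = int(p.findtext("offset") or 0)
            pieces.append((offset, p.findtext("text") or ""))
        length = max((off + len(txt) for off, txt in pieces), default=0)
        buf = [" "] * length
        for off, txt in pieces:
            buf[off : off + len(txt)] = txt
        text = "".join(buf)

        infon_map = dict(_infons(doc_el))
        source_uri = infon_map.get("sourcedoc", "")

        aset = AnnotationSet(annotator)
        aset.add_document(Document(doc_id, text, source_uri))

        # All annotations first: relations may reference across passages.
        for p in passages:
            p_offset = int(p.findtext("offset") or 0)
            for ann_el in p.findall("annotation"):
                _read_annotation(ann_el, aset, doc_id, annotator, text, p_offset)
        for rel_el in doc_el.iterfind(".//relation"):
            _read_relation(rel_el, aset, doc_id, annotator)

        sets.append(aset)
    return sets


def _read_annotation(ann_el, aset, doc_id, annotator, text, passage_offset) -> None:
    local_id = ann_el.get("id") or ""
    if not local_id:
        raise BiocParseError(f"annotation without id in document {doc_id!r}")
    locations = ann_el.findall("location")
    if not locations:
        raise BiocParseError(
            f"annotation {local_id!r} in document {doc_id!r} has no location"
        )
    fragments = []
    for loc in locations:
        offset = int(loc.get("offset", "0"))
        length = int(loc.get("length", "0"))
        fragments.append(Fragment(offset, length))
    fragments.sort(key=lambda f: f.offset)

    covered = ann_el.findtext("text") or ""
    actual = " ".join(text[f.offset : f.end] for f in fragments)
    if covered and actual != covered:
        shifted = [Fragment(f.offset + passage_offset, f.length) for f in fragments]
        shifted_actual = " ".join(text[f.offset : f.end] for f in shifted)
        if shifted_actual == covered:
            log.warning(
                "BioC %s/%s: passage-relative offsets detected; "
                "corrected by adding passage offset %d",
                doc_id, local_id, passage_offset,
            )
            fragments = shifted
            actual = shifted_actual
        else:
            raise BiocParseError(
                f"annotation {local_id!r} in document {doc_id!r}: text "
                f"{covered!r} does not match document at its location(s) "
                f"({actual!r})"
            )

    infons = _infons(ann_el)
    category = dict(infons).get("type", "")
    aset.add_concept(
        ConceptAnnotation(
            local_id=local_id,
            annotator=annotator,
            doc_id=doc_id,
            fragments=tuple(fragments),
            exact=covered or actual,
            category_tag=category,
            topic_ids=_topics_from_infons(infons),
        )
    )


def _read_relation(rel_el, aset, doc_id, annotator) -> None:
    local_id = rel_el.get("id") or ""
    infon_map = dict(_infons(rel_el))
    type_tag = infon_map.get("type", "")
    nodes = [
        (n.get("role", ""), n.get("refid", "")) for n in rel_el.findall("node")
    ]
    for _, refid in nodes:
        if (doc_id, refid) not in aset.concepts:
            raise BiocParseError(
                f"relation {local_id!r} in document {doc_id!r} references "
                f"absent annotation {refid!r}"
            )
    roles = [role for role, _ in nodes]
    is_event = "trigger" in roles or len(nodes) > 2
    if is_event:
        if "trigger" in roles:
            trigger = nodes[roles.index("trigger")][1]
            args = [(role, ref) for role, ref in nodes if role != "trigger"]
        else:
            trigger = nodes[0][1]
            args = nodes[1:]
        aset.add_event(
            EventAnnotation(local_id, annotator, doc_id, type_tag, trigger, list(args))
        )
    elif len(nodes) == 2:
        if set(roles) == {"arg1", "arg2"}:
            nodes = sorted(nodes, key=lambda n: n[0])
        aset.add_relation(
            RelationAnnotation(
                local_id, annotator, doc_id, type_tag, nodes[0][1], nodes[1][1]
            )
        )
    else:
        raise BiocParseError(
            f"relation {local_id!r} in document {doc_id!r} has {len(nodes)} node(s); "
            "expected 2 (relation) or a trigger-bearing event"
        )


def write_bioc(sets: list[AnnotationSet], source: str = "annokb") -> str:
    """Render annotation sets as one BioC collection (UTF-8 XML text).

    Each set contributes its documents; local ids are preserved, so a
    read/write round trip reproduces the sets. Events are written as
    relations with a ``trigger``-role node.
    """
    for aset in sets:
        if validate_set(aset):
            raise ValueError("write_bioc requires sets that pass validate_set")

    root = etree.Element("collection")
    etree.SubElement(root, "source").text = source
    etree.SubElement(root, "date").text = ""
    etree.SubElement(root, "key").text = ""

    for aset in sets:
        for doc_id, doc in sorted(aset.documents.items()):
            doc_el = etree.SubElement(root, "document")
            etree.SubElement(doc_el, "id").text = doc_id
            inf = etree.SubElement(doc_el, "infon", key="sourcedoc")
            inf.text = doc.source_uri
            p_el = etree.SubElement(doc_el, "passage")
            etree.SubElement(p_el, "offset").text = "0"
            etree.SubElement(p_el, "text").text = doc.text

            concepts = sorted(
                (c for (d, _), c in aset.concepts.items() if d == doc_id),
                key=lambda c: c.local_id,
            )
            for c in concepts:
                ann_el = etree.SubElement(p_el, "annotation", id=c.local_id)
                t = etree.SubElement(ann_el, "infon", key="type")
                t.text = c.category_tag
                for topic in c.topic_ids:
                    ident = etree.SubElement(ann_el, "infon", key="identifier")
                    ident.text = topic
                for f in c.fragments:
                    etree.SubElement(
                        ann_el, "location",
                        offset=str(f.offset), length=str(f.length),
                    )
                etree.SubElement(ann_el, "text").text = c.exact

            for r in sorted(
                (r for (d, _), r in aset.relations.items() if d == doc_id),
                key=lambda r: r.local_id,
            ):
                rel_el = etree.SubElement(p_el, "relation", id=r.local_id)
                t = etree.SubElement(rel_el, "infon", key="type")
                t.text = r.type_tag
                etree.SubElement(rel_el, "node", refid=r.arg1_ref, role="arg1")
                etree.SubElement(rel_el, "node", refid=r.arg2_ref, role="arg2")

            for e in sorted(
                (e for (d, _), e in aset.events.items() if d == doc_id),
                key=lambda e: e.local_id,
            ):
                rel_el = etree.SubElement(p_el, "relation", id=e.local_id)
                t = etree.SubElement(rel_el, "infon", key="type")
                t.text = e.type_tag
                etree.SubElement(rel_el, "node", refid=e.trigger_ref, role="trigger")
                for role, ref in e.args:
                    etree.SubElement(rel_el, "node", refid=ref, role=role)

    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")
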