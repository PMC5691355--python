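"""BioNLP shared-task standoff format reader and writer.

Standoff files store annotations separately from the annotated text as
tab-separated lines: ``T`` lines are text-bound concept mentions, ``R``
lines binary relations, ``E`` lines events (trigger plus role-labelled
arguments), ``N`` lines normalizations attaching an external identifier to
a mention. Both the single ``.ann`` file convention and the ``.a1``/``.a2``
split are supported: callers concatenate all annotation streams for a
document before parsing. Attribute (``A``/``M``) and equivalence (``*``)
lines are skipped with a warning.
"""

from __future__ import annotations

import logging
from typing import Iterable

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


class StandoffParseError(Exception):
    """A malformed standoff line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _parse_spans(span_field: str, lineno: int) -> list[Fragment]:
    fragments = []
    for pair in span_field.split(";"):
        parts = pair.split()
        if len(parts) != 2:
            raise StandoffParseError(lineno, f"unparsable span {pair!r}")
        try:
            start, end = int(parts[0]), int(parts[1])
        except ValueError:
            raise StandoffParseError(lineno, f"non-integer span {pair!r}") from None
        if end <= start:
            raise StandoffParseError(lineno, f"empty or inverted span {pair!r}")
        fragments.append(Fragment(start, end - start))
    return fragments


def read_standoff(
    text: str,
    ann_lines: str | Iterable[str],
    annotator: str,
    doc_id: str,
    source_uri: str = "",
) -> AnnotationSet:
    """Parse standoff annotation content against its source document.

    ``ann_lines`` may be the whole file content or an iterable of lines
    (e.g. the concatenation of a ``.a1`` and a ``.a2`` stream). The covered
    text on every ``T`` line is checked against the document substring at
    its span; a disagreement is a parse error, because it means offsets and
    text are out of sync.
    """
    aset = AnnotationSet(annotator)
    doc = aset.add_document(Document(doc_id, text, source_uri))

    if isinstance(ann_lines, str):
        lines = ann_lines.splitlines()
    else:
        lines = [l.rstrip("\n") for l in ann_lines]

    normalizations: list[tuple[int, str, str]] = []  # (lineno, target, topic)

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        local_id = fields[0]
        kind = local_id[:1]

        if kind == "T":
            if len(fields) < 3:
                raise StandoffParseError(
                    lineno, f"T line needs 3 tab-separated fields, got {len(fields)}"
                )
            header = fields[1]
            covered = fields[2]
            try:
                category, span_field = header.split(" ", 1)
            except ValueError:
                raise StandoffParseError(lineno, f"malformed T header {header!r}") from None
            fragments = _parse_spans(span_field, lineno)
            actual = " ".join(doc.text[f.offset : f.end] for f in fragments)
            if actual != covered:
                raise StandoffParseError(
                    lineno,
                    f"span text mismatch: file says {covered!r}, "
                    f"document reads {actual!r}",
                )
            aset.add_concept(
                ConceptAnnotation(
                    local_id=local_id,
                    annotator=annotator,
                    doc_id=doc_id,
                    fragments=tuple(fragments),
                    exact=covered,
                    category_tag=category,
                )
            )
        elif kind == "R":
            if len(fields) < 2:
                raise StandoffParseError(lineno, "R line needs a payload field")
            parts = fields[1].split()
            if len(parts) != 3:
                raise StandoffParseError(
                    lineno, f"R line needs 'Type Arg1:ID Arg2:ID', got {fields[1]!r}"
                )
            type_tag = parts[0]
            try:
                args = dict(p.split(":", 1) for p in parts[1:])
                arg1, arg2 = args["Arg1"], args["Arg2"]
            except (ValueError, KeyError):
                raise StandoffParseError(
                    lineno, f"malformed relation arguments {parts[1:]!r}"
                ) from None
            aset.add_relation(
                RelationAnnotation(local_id, annotator, doc_id, type_tag, arg1, arg2)
            )
        elif kind == "E":
            if len(fields) < 2:
                raise StandoffParseError(lineno, "E line needs a payload field")
            parts = fields[1].split()
            try:
                type_tag, trigger = parts[0].split(":", 1)
            except ValueError:
                raise StandoffParseError(
                    lineno, f"E line must start with Type:Trigger, got {parts[0]!r}"
                ) from None
            args = []
            for p in parts[1:]:
                try:
                    role, ref = p.split(":", 1)
                except ValueError:
                    raise StandoffParseError(
                        lineno, f"malformed event argument {p!r}"
                    ) from None
                args.append((role, ref))
            aset.add_event(
                EventAnnotation(local_id, annotator, doc_id, type_tag, trigger, args)
            )
        elif kind == "N":
            if len(fields) < 2:
                raise StandoffParseError(lineno, "N line needs a payload field")
            parts = fields[1].split()
            if len(parts) != 3:
                raise StandoffParseError(
                    lineno,
                    f"N line needs 'Reference Target Resource:ID', got {fields[1]!r}",
                )
            _, target, topic = parts
            if ":" not in topic:
                raise StandoffParseError(
                    lineno, f"normalization identifier {topic!r} lacks a Resource: prefix"
                )
            normalizations.append((lineno, target, topic))
        elif kind in ("A", "M", "*", "#"):
            log.warning(
                "standoff %s: skipping unsupported %s line %d", doc_id, kind, lineno
            )
        else:
            log.warning(
                "standoff %s: skipping unknown line kind %r at line %d",
                doc_id, kind, lineno,
            )

    # N lines may precede their targets; apply after all T lines are read.
    for lineno, target, topic in normalizations:
        concept = aset.concepts.get((doc_id, target))
        if concept is None:
            raise StandoffParseError(
                lineno, f"normalization targets unknown annotation {target!r}"
            )
        if topic not in concept.topic_ids:
            concept.topic_ids.append(topic)

    return aset


def write_standoff(aset: AnnotationSet) -> dict[str, tuple[str, str]]:
    """Render a set as standoff: ``{doc_id: (text content, ann content)}``.

    Local ids are preserved; ``N`` lines are emitted for every topic
    identifier. Output is deterministic (sorted by id kind and number) so
    two invocations on equal sets are byte-identical.
    """
    if validate_set(aset):
        raise ValueError("write_standoff requires a set that passes validate_set")

    out: dict[str, tuple[str, str]] = {}
    for doc_id, doc in sorted(aset.documents.items()):
        lines: list[str] = []
        n_counter = 1
        concepts = sorted(
            (c for (d, _), c in aset.concepts.items() if d == doc_id),
            key=lambda c: _id_sort_key(c.local_id),
        )
        for c in concepts:
            span = ";".join(f"{f.offset} {f.end}" for f in c.fragments)
            lines.append(f"{c.local_id}\t{c.category_tag} {span}\t{c.exact}")
        for c in concepts:
            for topic in c.topic_ids:
                lines.append(f"N{n_counter}\tReference {c.local_id} {topic}\t{c.exact}")
                n_counter += 1
        for r in sorted(
            (r for (d, _), r in aset.relations.items() if d == doc_id),
            key=lambda r: _id_sort_key(r.local_id),
        ):
            lines.append(
                f"{r.local_id}\t{r.type_tag} Arg1:{r.arg1_ref} Arg2:{r.arg2_ref}"
            )
        for e in sorted(
            (e for (d, _), e in aset.events.items() if d == doc_id),
            key=lambda e: _id_sort_key(e.local_id),
        ):
            arg_str = " ".join(f"{role}:{ref}" for role, ref in e.args)
            lines.append(f"{e.local_id}\t{e.type_tag}:{e.trigger_ref} {arg_str}")
        ann = "\n".join(lines) + ("\n" if lines else "")
        out[doc_id] = (doc.text, ann)
    return out


def _id_sort_key(local_id: str) -> tuple[str, int, str]:
    """Sort T2 before T10: split the id into prefix and numeric suffix."""
    i = 0
    while i < len(local_id) and not local_id[i].isdigit():
        i += 1
    prefix, suffix = local_id[:i], local_id[i:]
    return (prefix, int(suffix) if suffix.isdigit() else 0, suffix)
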