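"""Ontology mapping configuration and concept normalization.

A JSON configuration file drives the semantic enrichment of parsed
annotations:

* ``tag_map`` maps raw category tags (e.g. ``Gene_expression``) to
  ontology term URIs (e.g. the Gene Regulation Ontology class);
* ``property_map`` maps raw relation/event types (e.g. ``relatedWith``)
  to ontology properties (e.g. Dublin Core ``dc:relation``);
* ``services`` declares normalization services — HTTP POST endpoints
  accepting ``text/plain`` — each paired with a selector expression that
  extracts semantic identifiers from the service response;
* ``prefixes`` optionally extends the topic-identifier prefix table used
  when identifiers are expanded to URIs.

Selector expressions come in two kinds. ``path`` selectors are a minimal
JSONPath-like dialect over the parsed JSON response supporting the array
wildcard ``[*]``, the object wildcard ``*``, dotted descent, and literal
keys (including ``@``-prefixed ones such as ``@id``) — enough for
real-world annotator APIs, e.g. ``[*].annotatedClass.@id`` (BioPortal
Annotator) or ``*.*.refs`` (BeCAS). ``regex`` selectors collect every
capture-group (or whole-match) occurrence in the raw response text.
"""

from __future__ import annotations

import json
import logging
import re
import urllib.request
from dataclasses import dataclass, field
from typing import Any, Protocol

from .model import AnnotationSet

log = logging.getLogger(__name__)

DEFAULT_NAMESPACE = "https://w3id.org/annokb/tag/"
#: generic fallback property for relation types with no configured mapping
RELATED_TO = "https://w3id.org/annokb/vocab/relatedTo"

_URI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://\S+$|^urn:\S+$")


class ConfigError(Exception):
    """Invalid mapping configuration; message carries the JSON path."""


@dataclass(frozen=True)
class NormalizationService:
    """One external normalization endpoint plus its response selector."""

    endpoint: str
    selector: str
    selector_kind: str = "path"  # "path" | "regex"


@dataclass
class MappingConfig:
    """Validated mapping configuration (all sections optional)."""

    tag_map: dict[str, str] = field(default_factory=dict)
    property_map: dict[str, str] = field(default_factory=dict)
    services: list[NormalizationService] = field(default_factory=list)
    default_namespace: str = DEFAULT_NAMESPACE
    prefixes: dict[str, str] = field(default_factory=dict)


def load_config(json_content: str) -> MappingConfig:
    """Parse and validate a JSON mapping configuration.

    Missing sections default to empty — mapping is entirely optional.
    Schema violations are reported with the offending JSON path.
    """
    try:
        raw = json.loads(json_content)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a JSON object")

    def uri_map(section: str) -> dict[str, str]:
        value = raw.get(section, {})
        if not isinstance(value, dict):
            raise ConfigError(f"{section}: expected an object")
        out = {}
        for key, uri in value.items():
            if not isinstance(uri, str) or not _URI_RE.match(uri):
                raise ConfigError(f"{section}.{key}: {uri!r} is not an absolute URI")
            out[key] = uri
        return out

    tag_map = uri_map("tag_map")
    property_map = uri_map("property_map")

    services = []
    raw_services = raw.get("services", [])
    if not isinstance(raw_services, list):
        raise ConfigError("services: expected an array")
    for i, svc in enumerate(raw_services):
        if not isinstance(svc, dict):
            raise ConfigError(f"services[{i}]: expected an object")
        endpoint = svc.get("service", "")
        if not isinstance(endpoint, str) or not endpoint:
            raise ConfigError(f"services[{i}].service: missing or empty")
        selector = svc.get("query", "")
        if not isinstance(selector, str) or not selector:
            raise ConfigError(f"services[{i}].query: missing or empty")
        kind = svc.get("kind", "path")
        if kind not in ("path", "regex"):
            raise ConfigError(
                f"services[{i}].kind: {kind!r} is not one of 'path', 'regex'"
            )
        if kind == "regex":
            try:
                re.compile(selector)
            except re.error as exc:
                raise ConfigError(
                    f"services[{i}].query: invalid regular expression: {exc}"
                ) from exc
        else:
            _compile_path(selector, f"services[{i}].query")
        services.append(NormalizationService(endpoint, selector, kind))

    default_namespace = raw.get("default_namespace", DEFAULT_NAMESPACE)
    if not isinstance(default_namespace, str) or not _URI_RE.match(default_namespace):
        raise ConfigError(
            f"default_namespace: {default_namespace!r} is not an absolute URI"
        )

    prefixes = raw.get("prefixes", {})
    if not isinstance(prefixes, dict):
        raise ConfigError("prefixes: expected an object")
    for pfx, uri in prefixes.items():
        if not isinstance(uri, str) or not _URI_RE.match(uri):
            raise ConfigError(f"prefixes.{pfx}: {uri!r} is not an absolute URI")

    return MappingConfig(tag_map, property_map, services, default_namespace, dict(prefixes))


_SANITIZE_RE = re.compile(r"[^A-Za-z0-9_.~-]+")


def _sanitize(tag: str) -> str:
    return _SANITIZE_RE.sub("_", tag.strip()).strip("_") or "term"


def map_category(cfg: MappingConfig, tag: str) -> str:
    """Map a raw category tag to its ontology term URI.

    Unmapped tags are minted under the configured default namespace, so
    the mapping is total: every category yields a term.
    """
    if not tag:
        raise ValueError("category tag must be non-empty")
    return cfg.tag_map.get(tag) or cfg.default_namespace + _sanitize(tag)


def map_relation_type(cfg: MappingConfig, type_tag: str) -> str:
    """Map a raw relation/event type to an ontology property URI.

    Types without a configured mapping fall back to the generic
    related-to property rather than minting ad-hoc predicates.
    """
    if not type_tag:
        return RELATED_TO
    return cfg.property_map.get(type_tag, RELATED_TO)


# --- path-selector dialect ---------------------------------------------

_ARRAY_WILDCARD = object()
_OBJECT_WILDCARD = object()


def _compile_path(selector: str, where: str = "selector") -> list[Any]:
    steps: list[Any] = []
    for token in selector.split("."):
        token = token.strip()
        if token == "[*]":
            steps.append(_ARRAY_WILDCARD)
        elif token == "*":
            steps.append(_OBJECT_WILDCARD)
        elif token == "$" and not steps:
            continue  # tolerate an explicit root marker
        elif token:
            steps.append(token)
        else:
            raise ConfigError(f"{where}: empty path step in {selector!r}")
    if not steps:
        raise ConfigError(f"{where}: empty path expression")
    return steps


def _walk(node: Any, steps: list[Any]) -> list[Any]:
    if not steps:
        return [node]
    head, rest = steps[0], steps[1:]
    results: list[Any] = []
    if head is _ARRAY_WILDCARD:
        if isinstance(node, list):
            for item in node:
                results.extend(_walk(item, rest))
    elif head is _OBJECT_WILDCARD:
        if isinstance(node, dict):
            for value in node.values():
                results.extend(_walk(value, rest))
        elif isinstance(node, list):
            for item in node:
                results.extend(_walk(item, rest))
    else:
        if isinstance(node, dict) and head in node:
            results.extend(_walk(node[head], rest))
    return results


def select_identifiers(service: NormalizationService, response_content: str) -> list[str]:
    """Extract identifier strings from a raw service response.

    Path selectors evaluate over the parsed JSON; leaf values that are
    lists are flattened one level (a ``refs`` leaf is a list of ids).
    Regex selectors collect capture group 1 (or the whole match when the
    pattern has no groups). Duplicates are removed preserving first-seen
    order.
    """
    values: list[Any] = []
    if service.selector_kind == "path":
        try:
            data = json.loads(response_content)
        except json.JSONDecodeError as exc:
            raise ValueError(f"service response is not valid JSON: {exc}") from exc
        steps = _compile_path(service.selector)
        for leaf in _walk(data, steps):
            if isinstance(leaf, list):
                values.extend(leaf)
            else:
                values.append(leaf)
    elif service.selector_kind == "regex":
        pattern = re.compile(service.selector)
        for m in pattern.finditer(response_content):
            values.append(m.group(1) if pattern.groups else m.group(0))
    else:  # pragma: no cover - blocked by load_config
        raise ConfigError(f"unknown selector kind {service.selector_kind!r}")

    out: list[str] = []
    for v in values:
        s = str(v)
        if s and s not in out:
            out.append(s)
    return out


# --- normalization clients ---------------------------------------------


class NormalizationClient(Protocol):
    """Contract for invoking a normalization service."""

    def send(self, endpoint: str, text: str) -> str:
        """POST ``text`` as text/plain to ``endpoint``; return the body."""
        ...


class MockNormalizationClient:
    """Offline normalization backed by an exact-string lookup table.

    Responses are shaped like a BioPortal-Annotator reply so the printed
    path selector ``[*].annotatedClass.@id`` extracts the identifiers;
    the whole pipeline therefore runs with no network access. Unknown
    strings yield an empty annotation list.
    """

    def __init__(self, lookup: dict[str, list[str]] | None = None):
        if lookup is None:
            from .fixtures import default_vocab

            lookup = {}
            for surface, _category, topic in default_vocab():
                lookup.setdefault(surface, []).append(topic)
        self.lookup = lookup
        self.calls = 0

    def send(self, endpoint: str, text: str) -> str:
        self.calls += 1
        ids = self.lookup.get(text, [])
        return json.dumps([{"annotatedClass": {"@id": i}} for i in ids])


class HttpNormalizationClient:
    """Live client: HTTP POST with ``text/plain`` content type."""

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def send(self, endpoint: str, text: str) -> str:
        req = urllib.request.Request(
            endpoint,
            data=text.encode("utf-8"),
            headers={"Content-Type": "text/plain"},
            method="POST",
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            return resp.read().decode("utf-8")


#: the mock service declaration matching MockNormalizationClient responses
MOCK_SERVICE = NormalizationService(
    endpoint="mock://annotator",
    selector="[*].annotatedClass.@id",
    selector_kind="path",
)


def normalize_set(
    aset: AnnotationSet,
    cfg: MappingConfig,
    client: NormalizationClient,
) -> AnnotationSet:
    """Attach semantic identifiers to concepts that lack them.

    Every concept with empty ``topic_ids`` is posted (its exact covered
    string) to each configured service; identifiers extracted by the
    service selector are appended. Concepts already carrying identifiers
    are left untouched — their identifiers came with the annotation data
    and take precedence. A failure on one concept is logged and does not
    abort the batch. With no services configured this is a no-op.

    The set is modified in place and returned.
    """
    if not cfg.services:
        return aset
    for concept in aset.concepts.values():
        if concept.topic_ids:
            continue
        for service in cfg.services:
            try:
                response = client.send(service.endpoint, concept.exact)
                for ident in select_identifiers(service, response):
                    if ident not in concept.topic_ids:
                        concept.topic_ids.append(ident)
            except Exception:
                log.warning(
                    "normalization of %s/%s via %s failed",
                    concept.doc_id, concept.local_id, service.endpoint,
                    exc_info=True,
                )
    return aset
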