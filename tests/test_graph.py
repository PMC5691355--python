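"""RDF emission: URI minting, triple-count closed forms, reification."""

import itertools
import random

import pytest
from rdflib import RDF, Graph, Literal, URIRef

from annokb.graph import (
    ANNOTATED_BY,
    DEFAULT_VOCAB,
    AOVocabulary,
    build_graph,
    emit_concept,
    emit_event,
    emit_relation,
    expand_topic,
    mint_uri,
    serialize,
)
from annokb.mapping import MappingConfig
from annokb.model import (
    ConceptAnnotation,
    Document,
    EventAnnotation,
    Fragment,
    RelationAnnotation,
    merge_sets,
)

NS = "https://w3id.org/annokb/annotation/"


class TestMintUri:
    def test_deterministic(self):
        assert mint_uri(NS, "25766617", "toolA", "T1") == mint_uri(
            NS, "25766617", "toolA", "T1"
        )

    def test_injective_by_brute_force(self):
        """Distinct id triples, including separator-abusing ones, collide never."""
        parts = ["T1", "T10", "a/b", "a%2Fb", "a b", "x:y", "ann/1"]
        uris = {}
        for doc, annotator, local in itertools.product(parts, parts, parts):
            uri = mint_uri(NS, doc, annotator, local)
            assert uris.setdefault(uri, (doc, annotator, local)) == (
                doc, annotator, local
            ), f"collision at {uri}"

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            mint_uri(NS, "", "toolA", "T1")


class TestExpandTopic:
    def test_known_prefixes_expand_to_resource_stems(self):
        assert "OMIM/104300" in str(expand_topic("OMIM:104300"))
        assert "umls/id/C0027061" in str(expand_topic("umls:C0027061"))

    def test_absolute_uri_passes_through(self):
        uri = "http://purl.obolibrary.org/obo/DOID_10652"
        assert str(expand_topic(uri)) == uri

    def test_unknown_prefix_goes_under_artifact_namespace(self):
        assert str(expand_topic("mystery:42")).startswith("https://w3id.org/annokb/")

    def test_config_can_extend_prefix_table(self):
        cfg = MappingConfig(prefixes={"doid": "http://purl.obolibrary.org/obo/DOID_"})
        assert str(expand_topic("doid:10652", cfg)) == (
            "http://purl.obolibrary.org/obo/DOID_10652"
        )


def make_concept(n_topics=1, local_id="T1"):
    return ConceptAnnotation(
        local_id, "toolA", "25766617", (Fragment(0, 17),),
        "Alzheimer Disease", "Disease",
        topic_ids=[f"OMIM:{104300 + i}" for i in range(n_topics)],
    )


@pytest.fixture
def doc():
    return Document("25766617", "Alzheimer Disease " + "x" * 80)


class TestEmitConcept:
    def test_worked_example_emits_eight_triples(self, doc):
        triples = emit_concept(make_concept(), doc)
        assert len(triples) == 8
        node = mint_uri(NS, "25766617", "toolA", "T1")
        v = DEFAULT_VOCAB
        assert (node, v.exact_prop, Literal("Alzheimer Disease")) in triples
        topic_objects = [o for s, p, o in triples if p == v.topic_prop]
        assert topic_objects == [expand_topic("OMIM:104300")]
        source_objects = [o for s, p, o in triples if p == v.source_doc_prop]
        assert source_objects == [URIRef("https://pubmed.ncbi.nlm.nih.gov/25766617")]

    @pytest.mark.parametrize("k", [0, 1, 3])
    def test_closed_form_seven_plus_k(self, doc, k):
        assert len(emit_concept(make_concept(n_topics=k), doc)) == 7 + k

    def test_offset_and_range_are_integer_literals(self, doc):
        v = DEFAULT_VOCAB
        triples = emit_concept(make_concept(), doc)
        offsets = [o for s, p, o in triples if p == v.offset_prop]
        ranges = [o for s, p, o in triples if p == v.range_prop]
        assert offsets[0].toPython() == 0 and ranges[0].toPython() == 17

    def test_multi_fragment_concept_publishes_envelope(self, doc):
        ann = ConceptAnnotation(
            "T1", "toolA", "25766617",
            (Fragment(0, 9), Fragment(30, 7)), "Alzheimer Disease", "Disease",
        )
        v = DEFAULT_VOCAB
        triples = emit_concept(ann, doc)
        offsets = [o for s, p, o in triples if p == v.offset_prop]
        ranges = [o for s, p, o in triples if p == v.range_prop]
        assert (offsets[0].toPython(), ranges[0].toPython()) == (0, 37)


class TestEmitRelation:
    def test_reified_relation_is_five_triples_without_direct_edge(self):
        rel = RelationAnnotation("R1", "toolA", "d1", "location_of", "T1", "T2")
        triples = emit_relation(rel)
        assert len(triples) == 5
        t1 = mint_uri(NS, "d1", "toolA", "T1")
        t2 = mint_uri(NS, "d1", "toolA", "T2")
        assert not any(s == t1 and o == t2 for s, p, o in triples)
        assert not any(s == t2 and o == t1 for s, p, o in triples)

    def test_two_relations_same_members_get_distinct_nodes(self):
        r1 = RelationAnnotation("R1", "toolA", "d1", "location_of", "T1", "T2")
        r2 = RelationAnnotation("R2", "toolA", "d1", "degree_of", "T1", "T2")
        subj = lambda ts: {s for s, p, o in ts if p == RDF.type}
        assert subj(emit_relation(r1)) != subj(emit_relation(r2))

    def test_unmapped_type_falls_back_to_generic_related_to(self):
        from annokb.mapping import RELATED_TO

        rel = RelationAnnotation("R1", "toolA", "d1", "relatedWith", "T1", "T2")
        triples = emit_relation(rel, cfg=MappingConfig())
        bodies = [o for s, p, o in triples if p == DEFAULT_VOCAB.body_prop]
        assert bodies == [URIRef(RELATED_TO)]


class TestEmitEvent:
    @pytest.mark.parametrize("roles", [["Theme"], ["Theme", "Cause"]])
    def test_closed_form_four_plus_args(self, roles):
        ev = EventAnnotation(
            "E1", "toolA", "d1", "Gene_expression", "T2",
            [(r, f"T{i+3}") for i, r in enumerate(roles)],
        )
        triples = emit_event(ev)
        assert len(triples) == 4 + len(roles)
        role_props = {str(p) for s, p, o in triples if "/role/" in str(p)}
        assert len(role_props) == len(roles)

    def test_randomized_annotations_match_independent_enumeration(self):
        """Counts hold over randomized shapes vs. a from-scratch enumeration."""
        rng = random.Random(7)
        for _ in range(50):
            k = rng.randint(0, 4)
            concept = make_concept(n_topics=k)
            doc = Document("25766617", "Alzheimer Disease" + " f" * 50)
            got = emit_concept(concept, doc)
            # oracle: one triple per model edge, enumerated independently
            expected = 1 + 1 + 1 + 1 + 1 + 1 + 1 + len(set(concept.topic_ids))
            assert len(got) == expected
            n_args = rng.randint(1, 3)
            ev = EventAnnotation(
                "E1", "toolA", "d1", "Reg", "T0",
                [(f"Role{i}", f"T{i+1}") for i in range(n_args)],
            )
            assert len(emit_event(ev)) == 3 + 1 + n_args


class TestBuildGraph:
    def test_single_concept_graph_is_nine_triples(self, alzheimer_set):
        merged, _ = merge_sets([alzheimer_set])
        g = build_graph(merged)
        assert len(g) == 9

    def test_empty_input_gives_empty_graph(self):
        from annokb.model import AnnotationSet

        merged, _ = merge_sets([AnnotationSet("toolA")])
        assert len(build_graph(merged)) == 0

    def test_additivity_against_brute_force_sum(self, corpus, mapping_config):
        merged, _ = merge_sets([corpus.set_a, corpus.set_b])
        g = build_graph(merged, cfg=mapping_config)
        expected = len(merged.documents)
        for c in merged.concepts:
            expected += 7 + len(c.topic_ids)
        expected += 5 * len(merged.relations)
        for e in merged.events:
            expected += 4 + len(e.args)
        assert len(g) == expected  # fixture corpora are duplicate-free

    def test_every_concept_node_is_structurally_complete(self, corpus, mapping_config):
        """Exactly one exact/offset/range/body/source triple per concept node."""
        merged, _ = merge_sets([corpus.set_a, corpus.set_b])
        g = build_graph(merged, cfg=mapping_config)
        v = DEFAULT_VOCAB
        concept_nodes = [
            s for s in g.subjects(RDF.type, v.annotation_class)
            if (s, v.exact_prop, None) in g
        ]
        assert len(concept_nodes) == len(merged.concepts)
        for node in concept_nodes:
            for prop in (v.exact_prop, v.offset_prop, v.range_prop,
                         v.body_prop, v.source_doc_prop):
                assert len(list(g.objects(node, prop))) == 1

    def test_reification_soundness_by_graph_scan(self, corpus, mapping_config):
        """No triple ever links two concept-annotation URIs directly."""
        merged, _ = merge_sets([corpus.set_a, corpus.set_b])
        g = build_graph(merged, cfg=mapping_config)
        v = DEFAULT_VOCAB
        concept_nodes = {
            s for s in g.subjects(RDF.type, v.annotation_class)
            if (s, v.exact_prop, None) in g
        }
        for s, p, o in g:
            assert not (s in concept_nodes and o in concept_nodes), (s, p, o)

    def test_cross_format_graphs_are_isomorphic(self, corpus, mapping_config):
        from rdflib.compare import isomorphic

        from annokb.bioc import read_bioc, write_bioc
        from annokb.model import concat_sets
        from annokb.standoff import read_standoff, write_standoff

        via_bioc = concat_sets(
            read_bioc(write_bioc([corpus.set_b]), corpus.set_b.annotator)
        )
        via_standoff = concat_sets([
            read_standoff(text, ann, corpus.set_b.annotator, doc_id)
            for doc_id, (text, ann) in write_standoff(corpus.set_b).items()
        ])
        g1 = build_graph(merge_sets([via_bioc])[0], cfg=mapping_config)
        g2 = build_graph(merge_sets([via_standoff])[0], cfg=mapping_config)
        assert isomorphic(g1, g2)


class TestSerialize:
    def test_ntriples_line_count_equals_triple_count(self, alzheimer_set):
        merged, _ = merge_sets([alzheimer_set])
        g = build_graph(merged)
        nt = serialize(g, "ntriples")
        assert len(nt.strip().splitlines()) == 9

    def test_empty_graph_serializes_to_empty_document(self):
        assert serialize(Graph(), "ntriples") == ""

    def test_serialization_is_deterministic_and_sorted(self, corpus, mapping_config):
        merged, _ = merge_sets([corpus.set_a, corpus.set_b])
        g = build_graph(merged, cfg=mapping_config)
        nt1 = serialize(g, "ntriples")
        nt2 = serialize(build_graph(merged, cfg=mapping_config), "ntriples")
        assert nt1 == nt2
        lines = nt1.strip().splitlines()
        assert lines == sorted(lines)

    @pytest.mark.parametrize("fmt", ["turtle", "ntriples"])
    def test_round_trip_preserves_graph(self, alzheimer_set, fmt):
        from rdflib.compare import isomorphic

        merged, _ = merge_sets([alzheimer_set])
        g = build_graph(merged)
        parsed = Graph()
        parsed.parse(data=serialize(g, fmt),
                     format="nt" if fmt == "ntriples" else "turtle")
        assert isomorphic(g, parsed)

    def test_unknown_format_is_an_error(self):
        with pytest.raises(ValueError, match="unknown serialization"):
            serialize(Graph(), "rdfxml")


def test_vocabulary_uris_must_be_distinct():
    with pytest.raises(ValueError):
        AOVocabulary(exact_prop=DEFAULT_VOCAB.offset_prop)
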