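import pytest

from annokb.fixtures import FixtureSpec, default_config, generate
from annokb.model import (
    AnnotationSet,
    ConceptAnnotation,
    Document,
    Fragment,
)

ALZHEIMER_TEXT = (
    "Alzheimer Disease is a progressive neurodegenerative disorder and "
    "the most common cause of dementia."
)


@pytest.fixture
def alzheimer_doc():
    return Document("25766617", ALZHEIMER_TEXT)


@pytest.fixture
def alzheimer_set(alzheimer_doc):
    """One annotator, one concept: the canonical worked example."""
    aset = AnnotationSet("toolA")
    aset.add_document(alzheimer_doc)
    aset.add_concept(
        ConceptAnnotation(
            local_id="T1",
            annotator="toolA",
            doc_id="25766617",
            fragments=(Fragment(0, 17),),
            exact="Alzheimer Disease",
            category_tag="Disease",
            topic_ids=["OMIM:104300"],
        )
    )
    return aset


@pytest.fixture(scope="session")
def corpus():
    """Default two-annotator fixture corpus (20 docs, seed 42)."""
    return generate(FixtureSpec())


@pytest.fixture(scope="session")
def mapping_config():
    return default_config()
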