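import numpy as np
import pytest

from littriage import (
    Corpus,
    Document,
    GeneratorSpec,
    PreprocessConfig,
    generate,
)


@pytest.fixture(scope="session")
def plain_cfg():
    """Pipeline config with no stopwords/synonyms/stemming: tokens pass through."""
    return PreprocessConfig(
        stopword_list=frozenset(), synonym_map={}, stemmer="none"
    )


@pytest.fixture(scope="session")
def default_cfg():
    return PreprocessConfig()


@pytest.fixture
def tiny_labeled_corpus():
    """Six hand-written documents, three per class, with an obvious signal."""
    docs = [
        Document("r1", "Epitope mapping", "CTL epitope from tumor antigen", ("Neoplasms",), "relevant"),
        Document("r2", "Immunotherapy trial", "HLA-A*0201 restricted CTL epitope immunotherapy", (), "relevant"),
        Document("r3", "T cell responses", "tumor antigen specific T cell epitope", (), "relevant"),
        Document("i1", "Surgical outcomes", "resection margins and survival", ("Surgery",), "irrelevant"),
        Document("i2", "Imaging study", "contrast enhanced imaging of lesions", (), "irrelevant"),
        Document("i3", "Chemotherapy dosing", "dose escalation pharmacokinetics", (), "irrelevant"),
    ]
    return Corpus(docs, provenance="hand-built fixture")


@pytest.fixture(scope="session")
def separable_spec():
    """Disjoint class vocabularies: zero shared terms, perfect separability."""
    return GeneratorSpec(
        n_relevant=30,
        n_irrelevant=30,
        shared_vocab_size=1,
        class_vocab_size=40,
        class_term_rate=2.0,
        discriminative_terms=(),
        doc_length_mean=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def separable_corpus(separable_spec):
    return generate(separable_spec)


@pytest.fixture(scope="session")
def benchmark_spec():
    """Moderate-overlap corpus: planted terms at rate 3.0 vs 0.3 over a
    2,000-term shared background, 155 documents per class."""
    return GeneratorSpec(seed=11)


def pubmed_xml(articles):
    """Render a minimal PubmedArticleSet document from (pmid, title,
    abstract_or_None, mesh_list) tuples."""
    parts = ["<?xml version=\"1.0\"?>\n<PubmedArticleSet>"]
    for pmid, title, abstract, mesh in articles:
        parts.append("<PubmedArticle><MedlineCitation>")
        if pmid is not None:
            parts.append(f"<PMID>{pmid}</PMID>")
        parts.append(f"<Article><ArticleTitle>{title}</ArticleTitle>")
        if abstract is not None:
            parts.append(f"<Abstract><AbstractText>{abstract}</AbstractText></Abstract>")
        parts.append("</Article>")
        if mesh:
            parts.append("<MeshHeadingList>")
            for m in mesh:
                parts.append(
                    f"<MeshHeading><DescriptorName>{m}</DescriptorName></MeshHeading>"
                )
            parts.append("</MeshHeadingList>")
        parts.append("</MedlineCitation></PubmedArticle>")
    parts.append("</PubmedArticleSet>")
    return "".join(parts)
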