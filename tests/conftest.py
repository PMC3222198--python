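import numpy as np
import pytest
from hypothesis import settings

from hedgekit.corpus import Document, LabeledCorpus, MeshHeading

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_doc(doc_id, title="", abstract="", mesh=(), pts=(), year=None, journal=None):
    """mesh entries: name, (name, subs), or (name, subs, major)."""
    headings = []
    for m in mesh:
        if isinstance(m, str):
            headings.append(MeshHeading(name=m))
        else:
            name, subs, *rest = m
            headings.append(
                MeshHeading(name=name, subheadings=tuple(subs), major=bool(rest and rest[0]))
            )
    return Document(
        doc_id=doc_id,
        title=title,
        abstract=abstract,
        mesh_headings=tuple(headings),
        publication_types=tuple(pts),
        year=year,
        journal=journal,
    )


def make_corpus(docs, relevant):
    return LabeledCorpus(documents=tuple(docs), relevant_ids=frozenset(relevant))


def random_corpus(rng: np.random.Generator, n_docs: int, tokens, p_occurrence=0.3, prevalence=0.3):
    """Small random corpus: each token occurs independently in each title."""
    docs = []
    for i in range(n_docs):
        words = [t for t in tokens if rng.random() < p_occurrence]
        docs.append(make_doc(f"r{i}", title="base " + " ".join(words)))
    labels = {d.doc_id for d in docs if rng.random() < prevalence}
    if not labels:
        labels = {docs[0].doc_id}
    if len(labels) == len(docs):
        labels.discard(docs[-1].doc_id)
    return make_corpus(docs, labels)


@pytest.fixture
def medline_text():
    return (
        "PMID- 11111\n"
        "TI  - Accuracy of the clinical examination for ascites\n"
        "AB  - We assessed sensitivity and specificity of shifting dullness in a\n"
        "      prospective cohort of adults.\n"
        "MH  - Physical Examination\n"
        "MH  - *Heart Failure/diagnosis\n"
        "MH  - Ascites/*diagnosis/etiology\n"
        "PT  - Journal Article\n"
        "PT  - Comparative Study\n"
        "DP  - 2000 Mar\n"
        "JT  - Test Journal of Medicine\n"
        "\n"
        "PMID- 22222\n"
        "TI  - A study without abstract\n"
        "MH  - Sensitivity and Specificity\n"
        "PT  - Review\n"
        "DP  - 1998\n"
        "\n"
    )
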