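"""Recall gained by checking reference lists of retrieved relevant articles.

Systematic reviewers commonly snowball: the bibliographies of the articles a
search did find are screened for relevant articles the search missed.  Given
a citation graph (citing document → referenced documents), the augmentation
adds every relevant document referenced by a retrieved relevant document and
reports recall before and after.  References pointing outside the corpus are
ignored; by default only one round is applied and only references of
retrieved *relevant* documents are followed, mirroring the manual check.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

from .corpus import LabeledCorpus, UnknownIdError
from .metrics import build_contingency, compute_metrics

__all__ = [
    "CitationGraph",
    "AugmentationResult",
    "read_citation_graph",
    "augment_with_references",
]


@dataclass(frozen=True)
class CitationGraph:
    """citing doc_id → set of referenced doc_ids (endpoints may be off-corpus)."""

    edges: Mapping[str, frozenset[str]]

    def references(self, doc_id: str) -> frozenset[str]:
        return self.edges.get(doc_id, frozenset())


def read_citation_graph(stream: IO[str] | Iterable[str]) -> CitationGraph:
    """Two-column edge list (citing_id, cited_id), tab- or comma-separated."""
    edges: dict[str, set[str]] = {}
    for line_no, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in re.split(r"\t|,", line) if p.strip()]
        if len(parts) != 2:
            raise ValueError(f"line {line_no}: expected two columns, got {line!r}")
        edges.setdefault(parts[0], set()).add(parts[1])
    return CitationGraph(edges={k: frozenset(v) for k, v in edges.items()})


@dataclass(frozen=True)
class AugmentationResult:
    augmented: frozenset[str]
    recall_before: float  # percent, unrounded
    recall_after: float  # percent, unrounded
    recovered: frozenset[str]  # relevant documents added by the augmentation


def augment_with_references(
    corpus: LabeledCorpus,
    retrieved: frozenset[str] | set[str],
    graph: CitationGraph,
    follow_all_retrieved: bool = False,
    transitive: bool = False,
) -> AugmentationResult:
    """Augment a retrieval set with relevant documents found in reference lists.

    One round adds the relevant corpus documents referenced by any retrieved
    relevant document (``follow_all_retrieved=True`` follows references of
    every retrieved document instead).  ``transitive=True`` iterates to a
    fixpoint.  Recall never decreases, and precision cannot decrease because
    only relevant documents are added.
    """
    retrieved = frozenset(retrieved)
    unknown = retrieved - corpus.ids
    if unknown:
        raise UnknownIdError(sorted(unknown))
    relevant = corpus.relevant_ids
    recall_before = compute_metrics(build_contingency(corpus, retrieved)).recall

    current = set(retrieved)
    while True:
        sources = current if follow_all_retrieved else current & relevant
        found = set()
        for doc_id in sources:
            found |= graph.references(doc_id) & relevant
        new = found - current
        current |= new
        if not new or not transitive:
            break

    augmented = frozenset(current)
    recall_after = compute_metrics(build_contingency(corpus, augmented)).recall
    return AugmentationResult(
        augmented=augmented,
        recall_before=recall_before,
        recall_after=recall_after,
        recovered=augmented - retrieved,
    )
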