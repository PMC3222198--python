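"""Labeled bibliographic corpora: data model, MEDLINE flat-file I/O, synthetic generation.

A corpus is a collection of :class:`Document` records (title, abstract, MeSH
headings with subheadings, publication types) together with a gold-standard set
of relevant document IDs.  Real corpora are read from MEDLINE flat files or a
line-delimited JSON format; synthetic corpora emulating a very-low-prevalence
labeled database (tens of relevant records among tens of thousands) are
generated by :func:`generate_synthetic_corpus`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "MeshHeading",
    "Document",
    "LabeledCorpus",
    "TermSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "CorpusError",
    "MedlineParseError",
    "DuplicateIdError",
    "UnknownIdError",
    "DegenerateCorpusError",
    "read_medline",
    "write_medline",
    "read_jsonl",
    "write_jsonl",
    "load_labels",
    "screen_gold_standard",
    "generate_synthetic_corpus",
    "planted_rule_config",
]


class CorpusError(ValueError):
    """Base class for corpus-level errors."""


class MedlineParseError(CorpusError):
    """A malformed line in a MEDLINE flat file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class DuplicateIdError(CorpusError):
    pass


class UnknownIdError(CorpusError):
    def __init__(self, unknown: Sequence[str]):
        self.unknown = tuple(unknown)
        super().__init__(
            f"{len(self.unknown)} labeled ID(s) absent from corpus: "
            + ", ".join(self.unknown[:10])
            + ("..." if len(self.unknown) > 10 else "")
        )


class DegenerateCorpusError(CorpusError):
    pass


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH indexing entry: heading name, attached subheadings, major-topic flag."""

    name: str
    subheadings: tuple[str, ...] = ()
    major: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("MeSH heading name must be non-empty")
        if any(not s for s in self.subheadings):
            raise ValueError("MeSH subheading names must be non-empty")


@dataclass(eq=False)
class Document:
    """One bibliographic record.

    ``abstract`` may be empty (older records often lack one); such documents
    remain searchable — excluding them is a caller-side filtering step.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    mesh_headings: tuple[MeshHeading, ...] = ()
    publication_types: tuple[str, ...] = ()
    year: Optional[int] = None
    journal: Optional[str] = None

    # lazily built token caches used by the query engine
    _token_cache: dict = field(default_factory=dict, repr=False, compare=False)


@dataclass(frozen=True)
class LabeledCorpus:
    """Documents plus the gold-standard set of relevant IDs."""

    documents: tuple[Document, ...]
    relevant_ids: frozenset[str]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        id_set = set(ids)
        if len(id_set) != len(ids):
            raise DuplicateIdError("duplicate doc_id in corpus")
        missing = self.relevant_ids - id_set
        if missing:
            raise UnknownIdError(sorted(missing))
        n_rel = len(self.relevant_ids)
        if n_rel == 0 or n_rel == len(ids):
            raise DegenerateCorpusError(
                f"gold standard of {n_rel} relevant among {len(ids)} documents "
                "leaves recall or fallout undefined"
            )

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(d.doc_id for d in self.documents)

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def prevalence(self) -> float:
        return len(self.relevant_ids) / len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def by_id(self, doc_id: str) -> Document:
        return self._index()[doc_id]

    def _index(self) -> Mapping[str, Document]:
        # cached on first use; frozen dataclass, so stash via object.__setattr__
        idx = self.__dict__.get("_idx")
        if idx is None:
            idx = {d.doc_id: d for d in self.documents}
            object.__setattr__(self, "_idx", idx)
        return idx


# ---------------------------------------------------------------------------
# MEDLINE flat-file I/O
# ---------------------------------------------------------------------------

_TAG_DASH = re.compile(r"^([A-Z][A-Z0-9]{0,3})\s*- (.*)$")
_TAG_TAB = re.compile(r"^([A-Z][A-Z0-9]{0,3})\t(.*)$")
_YEAR = re.compile(r"\b(\d{4})\b")


def _parse_mesh_line(raw: str) -> MeshHeading:
    """Decompose an MH value like ``*Heart Failure/diagnosis/*therapy``.

    An asterisk anywhere (on the heading or a subheading) marks the entry as a
    major topic; asterisks are stripped from the stored names.
    """
    major = "*" in raw
    parts = [p.strip().lstrip("*").strip() for p in raw.split("/")]
    parts = [p for p in parts if p]
    if not parts:
        raise ValueError(f"empty MH entry: {raw!r}")
    return MeshHeading(name=parts[0], subheadings=tuple(parts[1:]), major=major)


def read_medline(stream: IO[str] | Iterable[str]) -> list[Document]:
    """Parse a MEDLINE flat file into documents.

    Accepts the standard ``TAG - value`` layout (tag padded to four columns)
    and a tab-separated ``TAG<TAB>value`` variant; continuation lines are
    indented; a blank line separates records.

    Raises :class:`MedlineParseError` (with the line number) on a malformed
    tag line and :class:`DuplicateIdError` on a repeated PMID.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    fields: list[tuple[str, str]] = []

    def flush(line_no: int) -> None:
        if not fields:
            return
        data: dict[str, list[str]] = {}
        for tag, value in fields:
            data.setdefault(tag, []).append(value)
        pmids = data.get("PMID", [])
        if not pmids:
            raise MedlineParseError("record without PMID", line_no)
        doc_id = pmids[0].strip()
        if doc_id in seen:
            raise DuplicateIdError(f"duplicate PMID {doc_id}")
        seen.add(doc_id)
        year: Optional[int] = None
        if "DP" in data:
            m = _YEAR.search(data["DP"][0])
            if m:
                year = int(m.group(1))
        docs.append(
            Document(
                doc_id=doc_id,
                title=" ".join(data.get("TI", [])).strip(),
                abstract=" ".join(data.get("AB", [])).strip(),
                mesh_headings=tuple(_parse_mesh_line(v) for v in data.get("MH", [])),
                publication_types=tuple(v.strip() for v in data.get("PT", [])),
                year=year,
                journal=data.get("JT", [None])[0],
            )
        )
        fields.clear()

    line_no = 0
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush(line_no)
            continue
        if line[0] in " \t" and fields:
            tag, prev = fields[-1]
            fields[-1] = (tag, prev + " " + line.strip())
            continue
        m = _TAG_DASH.match(line) or _TAG_TAB.match(line)
        if m is None:
            raise MedlineParseError(f"malformed tag line: {line!r}", line_no)
        fields.append((m.group(1), m.group(2)))
    flush(line_no + 1)
    return docs


def write_medline(documents: Iterable[Document], stream: IO[str]) -> None:
    """Write documents in MEDLINE flat-file layout (round-trips with read_medline)."""
    for doc in documents:
        stream.write(f"PMID- {doc.doc_id}\n")
        if doc.title:
            stream.write(f"TI  - {doc.title}\n")
        if doc.abstract:
            stream.write(f"AB  - {doc.abstract}\n")
        for mh in doc.mesh_headings:
            star = "*" if mh.major else ""
            stream.write(f"MH  - {star}{'/'.join((mh.name,) + mh.subheadings)}\n")
        for pt in doc.publication_types:
            stream.write(f"PT  - {pt}\n")
        if doc.year is not None:
            stream.write(f"DP  - {doc.year}\n")
        if doc.journal:
            stream.write(f"JT  - {doc.journal}\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Line-delimited structured records (native fixture format)
# ---------------------------------------------------------------------------


def read_jsonl(stream: IO[str] | Iterable[str]) -> list[Document]:
    """Read one JSON document per line (the diff-friendly native format)."""
    docs: list[Document] = []
    seen: set[str] = set()
    for line_no, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise MedlineParseError(f"invalid JSON record: {exc}", line_no) from exc
        doc_id = str(obj["doc_id"])
        if doc_id in seen:
            raise DuplicateIdError(f"duplicate doc_id {doc_id}")
        seen.add(doc_id)
        docs.append(
            Document(
                doc_id=doc_id,
                title=obj.get("title", ""),
                abstract=obj.get("abstract", ""),
                mesh_headings=tuple(
                    MeshHeading(name=m[0], subheadings=tuple(m[1]), major=bool(m[2]))
                    for m in obj.get("mesh", [])
                ),
                publication_types=tuple(obj.get("pub_types", [])),
                year=obj.get("year"),
                journal=obj.get("journal"),
            )
        )
    return docs


def write_jsonl(documents: Iterable[Document], stream: IO[str]) -> None:
    for doc in documents:
        obj = {
            "doc_id": doc.doc_id,
            "title": doc.title,
            "abstract": doc.abstract,
            "mesh": [[m.name, list(m.subheadings), m.major] for m in doc.mesh_headings],
            "pub_types": list(doc.publication_types),
            "year": doc.year,
            "journal": doc.journal,
        }
        stream.write(json.dumps(obj, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Labels and gold-standard bookkeeping
# ---------------------------------------------------------------------------


def load_labels(stream: IO[str] | Iterable[str], documents: Sequence[Document]) -> LabeledCorpus:
    """Attach a gold standard (one doc_id per line) to a document collection.

    Raises :class:`UnknownIdError` if a listed ID is absent from the corpus and
    :class:`DegenerateCorpusError` for an empty label list (recall would be
    undefined).
    """
    ids = {d.doc_id for d in documents}
    labels: list[str] = []
    for line in stream:
        line = line.strip()
        if line and not line.startswith("#"):
            labels.append(line)
    if not labels:
        raise DegenerateCorpusError("empty label list: recall undefined")
    unknown = sorted(set(labels) - ids)
    if unknown:
        raise UnknownIdError(unknown)
    return LabeledCorpus(documents=tuple(documents), relevant_ids=frozenset(labels))


def screen_gold_standard(
    documents: Sequence[Document],
    *,
    medline_ids: Optional[set[str]] = None,
    search_found_ids: Optional[set[str]] = None,
    require_abstract: bool = True,
) -> tuple[list[Document], dict[str, int]]:
    """Apply the standard eligibility exclusions to a candidate gold standard.

    Sequentially excludes documents (a) not indexed in MEDLINE, (b) not found
    by the subject-specific search, and (c) lacking an abstract.  Returns the
    retained documents and a count of exclusions per reason.
    """
    counts = {"not_in_medline": 0, "not_found_by_search": 0, "no_abstract": 0}
    kept: list[Document] = []
    for doc in documents:
        if medline_ids is not None and doc.doc_id not in medline_ids:
            counts["not_in_medline"] += 1
            continue
        if search_found_ids is not None and doc.doc_id not in search_found_ids:
            counts["not_found_by_search"] += 1
            continue
        if require_abstract and not doc.abstract:
            counts["no_abstract"] += 1
            continue
        kept.append(doc)
    return kept, counts


# ---------------------------------------------------------------------------
# Synthetic corpora
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermSpec:
    """A vocabulary token with class-conditional occurrence probabilities.

    ``field`` places the token in the title, the abstract, or as a MeSH
    heading, so field-qualified query matching is exercised.  In planted-rule
    mode labels derive from term occurrences, so a single marginal occurrence
    probability applies: ``p_relevant`` is used and ``p_nonrelevant`` ignored.
    """

    token: str
    p_relevant: float
    p_nonrelevant: float
    field: str = "title"

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Za-z][A-Za-z0-9]*", self.token):
            raise ValueError(f"vocabulary token must be a single word: {self.token!r}")
        for p in (self.p_relevant, self.p_nonrelevant):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.field not in ("title", "abstract", "mesh"):
            raise ValueError(f"unknown field {self.field!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_docs: int
    prevalence: float
    vocabulary: tuple[TermSpec, ...]
    planted_rule: Optional[str] = None
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise DegenerateCorpusError(
                f"prevalence {self.prevalence} is degenerate (must be in (0, 1))"
            )
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated corpus."""

    planted_rule: Optional[str]
    relevant_ids: frozenset[str]


def generate_synthetic_corpus(config: SyntheticConfig) -> tuple[LabeledCorpus, SyntheticTruth]:
    """Generate a labeled corpus from class-conditional term probabilities.

    Without a planted rule, labels are independent Bernoulli(prevalence) draws
    and each vocabulary term occurs with its class-conditional probability.
    With a planted rule (a Boolean query over vocabulary tokens), occurrences
    are drawn first and the label is the rule's value XOR a Bernoulli
    label-noise flip.  Identical config (including seed) gives a byte-identical
    corpus.
    """
    from . import query  # deferred: query imports Document from this module

    rule_node = None
    if config.planted_rule is not None:
        rule_node = query.parse_query(config.planted_rule)
        rule_terms = {leaf.term.lower() for leaf in query.iter_leaves(rule_node)}
        vocab_tokens = {t.token.lower() for t in config.vocabulary}
        stray = rule_terms - vocab_tokens
        if stray:
            raise ValueError(f"planted rule references non-vocabulary terms: {sorted(stray)}")

    rng = np.random.default_rng(config.seed)
    n = config.n_docs
    if rule_node is None:
        labels = rng.random(n) < config.prevalence
    else:
        labels = np.zeros(n, dtype=bool)  # assigned after occurrences

    occurrences = np.zeros((len(config.vocabulary), n), dtype=bool)
    for j, spec in enumerate(config.vocabulary):
        if rule_node is None:
            p = np.where(labels, spec.p_relevant, spec.p_nonrelevant)
        else:
            p = spec.p_relevant
        occurrences[j] = rng.random(n) < p

    docs: list[Document] = []
    for i in range(n):
        title_words = [f"record{i:07d}"]
        abstract_words = ["background", "methods"]
        mesh: list[MeshHeading] = []
        for j, spec in enumerate(config.vocabulary):
            if not occurrences[j, i]:
                continue
            if spec.field == "title":
                title_words.append(spec.token)
            elif spec.field == "abstract":
                abstract_words.append(spec.token)
            else:
                mesh.append(MeshHeading(name=spec.token))
        docs.append(
            Document(
                doc_id=f"SYN{i:07d}",
                title=" ".join(title_words),
                abstract=" ".join(abstract_words),
                mesh_headings=tuple(mesh),
            )
        )

    if rule_node is not None:
        flips = rng.random(n) < config.label_noise
        for i, doc in enumerate(docs):
            labels[i] = query.evaluate_query(doc, rule_node) != flips[i]

    relevant = frozenset(doc.doc_id for doc, lab in zip(docs, labels) if lab)
    if not relevant or len(relevant) == len(docs):
        raise DegenerateCorpusError(
            f"generated corpus has {len(relevant)} relevant of {len(docs)} documents"
        )
    corpus = LabeledCorpus(documents=tuple(docs), relevant_ids=relevant)
    return corpus, SyntheticTruth(planted_rule=config.planted_rule, relevant_ids=relevant)


def planted_rule_config(
    seed: int,
    n_docs: int = 5000,
    label_noise: float = 0.0,
) -> SyntheticConfig:
    """A standard planted-rule study condition.

    A noiseless three-term rule ``(palpation AND auscultation) OR bruit`` with
    occurrence probabilities chosen so the rule holds for about 2% of
    documents, plus ten label-independent distractor terms spread across
    title, abstract and MeSH fields.
    """
    signal = (
        TermSpec("palpation", 0.10, 0.10, "title"),
        TermSpec("auscultation", 0.10, 0.10, "abstract"),
        TermSpec("bruit", 0.0105, 0.0105, "title"),
    )
    distractors = tuple(
        TermSpec(tok, p, p, fld)
        for tok, p, fld in [
            ("cohort", 0.30, "title"),
            ("assay", 0.15, "abstract"),
            ("imaging", 0.12, "title"),
            ("serum", 0.20, "abstract"),
            ("biopsy", 0.08, "title"),
            ("neonatal", 0.05, "abstract"),
            ("murine", 0.10, "title"),
            ("protein", 0.25, "abstract"),
            ("sequence", 0.18, "title"),
            ("registry", 0.07, "mesh"),
        ]
    )
    return SyntheticConfig(
        n_docs=n_docs,
        prevalence=0.02,
        vocabulary=signal + distractors,
        planted_rule="(palpation[tw] AND auscultation[tw]) OR bruit[tw]",
        label_noise=label_noise,
        seed=seed,
    )
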