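"""Named search-filter definitions: the built-in filters and user filter files.

Filters are named "FirstAuthor-Year[-Variant]" or by their descriptive
training name.  The built-ins are the published clinical-examination filters:
the best single-term filters, the best OR-combinations over diagnosis-only
and clinical-examination-only term slates, and the multi-term filter induced
by recursive partitioning.  Previously published diagnosis filters are not
shipped (their strings are not reproduced here); load them from a definition
file with :func:`load_filters`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable

from .query import QueryNode, parse_query

__all__ = [
    "FilterDefinition",
    "builtin_filters",
    "get_filter",
    "load_filters",
    "write_filters",
    "user_filter_template",
]


@dataclass(frozen=True)
class FilterDefinition:
    name: str
    query_text: str
    provenance: str = ""

    @property
    def node(self) -> QueryNode:
        return parse_query(self.query_text)


_BUILTINS = (
    FilterDefinition(
        "Diagnosis-subheading",
        "Diagnosis[subheading]",
        "best-recall single-term filter (training)",
    ),
    FilterDefinition(
        "MedicalHistoryTaking-MeSH",
        "Medical history taking[MeSH]",
        "best-precision/F single-term filter (training)",
    ),
    FilterDefinition(
        "Dx-high-recall",
        'Diagnosis[tw] OR "sensitivity and specificity"[MeSH]',
        "best-recall combination of diagnosis terms (training)",
    ),
    FilterDefinition(
        "Dx-precise",
        "Predictive value of tests[mesh] OR specificity[TIAB]",
        "best-precision/F combination of diagnosis terms (training)",
    ),
    FilterDefinition(
        "CE-high-recall",
        "Clinical*[tw] OR symptom*[tw] OR exam*[tw] OR criteria[tw] OR tests[tw] OR test[tw]",
        "best-recall combination of clinical-examination terms (training)",
    ),
    FilterDefinition(
        "CE-precise",
        "Tests[tw] OR physical[tw]",
        "best-precision/F combination of clinical-examination terms (training)",
    ),
    FilterDefinition(
        "RP-filter",
        '(Diagnosis[tw] AND (specific*[tw] OR clinical*[tw] OR exam*[tw])) '
        'OR "sensitivity and specificity"[MeSH]',
        "multi-term filter induced by recursive partitioning",
    ),
)


def builtin_filters() -> list[FilterDefinition]:
    """The shipped filter definitions; every one parses under the dialect."""
    return list(_BUILTINS)


def get_filter(name: str) -> FilterDefinition:
    for f in _BUILTINS:
        if f.name == name:
            return f
    raise KeyError(f"no builtin filter named {name!r}")


def load_filters(stream: IO[str] | Iterable[str]) -> list[FilterDefinition]:
    """Load tab-separated definitions: name, query string, optional provenance.

    Blank lines and ``#`` comments are skipped.  Duplicate names and
    unparseable queries are rejected, naming the offending filter.
    """
    defs: list[FilterDefinition] = []
    seen: set[str] = set()
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(
                f"line {line_no}: expected name<TAB>query[<TAB>provenance], got {line!r}"
            )
        name, query_text = parts[0].strip(), parts[1].strip()
        provenance = parts[2].strip() if len(parts) > 2 else ""
        if name in seen:
            raise ValueError(f"duplicate filter name {name!r} (line {line_no})")
        seen.add(name)
        try:
            parse_query(query_text)
        except ValueError as exc:
            raise ValueError(f"filter {name!r} does not parse: {exc}") from exc
        defs.append(FilterDefinition(name=name, query_text=query_text, provenance=provenance))
    return defs


def write_filters(definitions: Iterable[FilterDefinition], stream: IO[str]) -> None:
    for d in definitions:
        stream.write(f"{d.name}\t{d.query_text}\t{d.provenance}\n")


def user_filter_template() -> str:
    """The shipped empty definition file for previously published filters."""
    return (
        resources.files("hedgekit")
        .joinpath("data/previously_published_filters.tsv")
        .read_text()
    )
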