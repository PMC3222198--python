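"""PubMed-style Boolean query dialect: parsing, serialization, evaluation.

The dialect covers the constructs used in published search filters for
bibliographic databases: field-tagged terms (``diagnosis[sh]``,
``"sensitivity and specificity"[MeSH]``), trailing-``*`` truncation
(``specific*[tw]``), and the Boolean operators AND, OR and NOT with
precedence NOT > AND > OR.  NOT is binary set-difference, as in PubMed;
a query may not begin with NOT.

Field-tag semantics:

========== ==============================================================
``[ti]``    token or phrase match in the title
``[TIAB]``  title or abstract
``[tw]``    title, abstract, MeSH heading names, or subheading names
``[MeSH]``  exact heading-name match, plus descendants when a hierarchy
            is supplied (``[MeSH:noexp]`` suppresses the explosion)
``[sh]``    match among attached subheading names
``[pt]``    match among publication types
========== ==============================================================

Matching is case-insensitive; tokenization splits on any non-alphanumeric
character; there is no stemming beyond explicit ``*`` truncation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping, Optional, Union

from .corpus import Document, LabeledCorpus

__all__ = [
    "TermLeaf",
    "BoolNode",
    "QueryNode",
    "QueryParseError",
    "parse_query",
    "to_query_string",
    "evaluate_query",
    "retrieve",
    "iter_leaves",
    "load_mesh_hierarchy",
]

# canonical field tags; keys are the lower-cased spellings accepted on input
_FIELD_ALIASES = {
    "tw": "tw",
    "tiab": "TIAB",
    "ti": "ti",
    "mesh": "MeSH",
    "mesh:noexp": "MeSH:noexp",
    "mh": "MeSH",
    "sh": "sh",
    "subheading": "sh",
    "pt": "pt",
}

_FIELDS = frozenset(_FIELD_ALIASES.values())


class QueryParseError(ValueError):
    """Malformed query string; carries the 0-based character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class TermLeaf:
    """A single search term: raw text, truncation flag, and field tag."""

    term: str
    field: str = "tw"
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("term text must be non-empty")
        if self.field not in _FIELDS:
            raise ValueError(f"unknown field tag {self.field!r}")


@dataclass(frozen=True)
class BoolNode:
    op: str  # "AND" | "OR" | "NOT"
    left: "QueryNode"
    right: "QueryNode"

    def __post_init__(self) -> None:
        if self.op not in ("AND", "OR", "NOT"):
            raise ValueError(f"unknown operator {self.op!r}")


QueryNode = Union[TermLeaf, BoolNode]


# ---------------------------------------------------------------------------
# Lexing and parsing
# ---------------------------------------------------------------------------

_WORD = re.compile(r"[^\s()\[\]\"]+")


def _lex(text: str) -> list[tuple[str, str, int]]:
    """Tokens: (kind, value, position) with kinds LP RP WORD QUOTED TAG OP."""
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "(":
            tokens.append(("LP", "(", i))
            i += 1
        elif ch == ")":
            tokens.append(("RP", ")", i))
            i += 1
        elif ch == '"':
            j = text.find('"', i + 1)
            if j < 0:
                raise QueryParseError("unbalanced quote", i)
            tokens.append(("QUOTED", text[i + 1 : j], i))
            i = j + 1
        elif ch == "[":
            j = text.find("]", i + 1)
            if j < 0:
                raise QueryParseError("unbalanced field-tag bracket", i)
            tokens.append(("TAG", text[i + 1 : j], i))
            i = j + 1
        else:
            m = _WORD.match(text, i)
            assert m is not None
            word = m.group(0)
            if word.upper() in ("AND", "OR", "NOT"):
                tokens.append(("OP", word.upper(), i))
            else:
                tokens.append(("WORD", word, i))
            i = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _lex(text)
        self.pos = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def error(self, message: str) -> QueryParseError:
        pos = self.tokens[self.pos][2] if self.pos < len(self.tokens) else len(self.text)
        return QueryParseError(message, pos)

    # precedence climbing: OR < AND < NOT, all left-associative
    def parse(self) -> QueryNode:
        node = self.parse_or()
        if self.peek() is not None:
            raise self.error(f"unexpected token {self.peek()[1]!r}")
        return node

    def parse_or(self) -> QueryNode:
        node = self.parse_and()
        while (tok := self.peek()) and tok[0] == "OP" and tok[1] == "OR":
            self.advance()
            node = BoolNode("OR", node, self.parse_and())
        return node

    def parse_and(self) -> QueryNode:
        node = self.parse_not()
        while (tok := self.peek()) and tok[0] == "OP" and tok[1] == "AND":
            self.advance()
            node = BoolNode("AND", node, self.parse_not())
        return node

    def parse_not(self) -> QueryNode:
        node = self.parse_atom()
        while (tok := self.peek()) and tok[0] == "OP" and tok[1] == "NOT":
            self.advance()
            node = BoolNode("NOT", node, self.parse_atom())
        return node

    def parse_atom(self) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise self.error("empty operand")
        kind, value, pos = tok
        if kind == "LP":
            self.advance()
            node = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != "RP":
                raise QueryParseError("unbalanced parenthesis", pos)
            self.advance()
            return node
        if kind == "QUOTED":
            self.advance()
            return self._leaf(value, pos)
        if kind == "WORD":
            # consecutive bare words before a tag bind as one phrase
            # (e.g. "Medical history taking[MeSH]")
            words = [self.advance()[1]]
            while (nxt := self.peek()) and nxt[0] == "WORD":
                words.append(self.advance()[1])
            return self._leaf(" ".join(words), pos)
        if kind == "OP" and value == "NOT":
            raise QueryParseError("NOT is binary: a query may not begin with NOT", pos)
        raise self.error(f"unexpected token {value!r}")

    def _leaf(self, term: str, pos: int) -> TermLeaf:
        field = "tw"
        tok = self.peek()
        if tok is not None and tok[0] == "TAG":
            self.advance()
            raw = tok[1].strip().lower()
            if raw not in _FIELD_ALIASES:
                raise QueryParseError(f"unknown field tag [{tok[1]}]", tok[2])
            field = _FIELD_ALIASES[raw]
        truncated = term.endswith("*")
        term = term.rstrip("*").strip()
        if not term:
            raise QueryParseError("empty term", pos)
        return TermLeaf(term=term, field=field, truncated=truncated)


def parse_query(text: str) -> QueryNode:
    """Parse a query string; raises :class:`QueryParseError` with position."""
    if not text or not text.strip():
        raise QueryParseError("empty query", 0)
    return _Parser(text).parse()


def to_query_string(node: QueryNode) -> str:
    """Serialize a query tree back to the dialect (parses to an equal tree)."""
    return _serialize(node, 0)


_PREC = {"OR": 1, "AND": 2, "NOT": 3}


def _serialize(node: QueryNode, parent_prec: int) -> str:
    if isinstance(node, TermLeaf):
        term = node.term + ("*" if node.truncated else "")
        if " " in term:
            term = f'"{term}"'
        return f"{term}[{node.field}]"
    prec = _PREC[node.op]
    left = _serialize(node.left, prec)
    right = _serialize(node.right, prec + 1)  # left-associative
    s = f"{left} {node.op} {right}"
    return f"({s})" if prec < parent_prec else s


def iter_leaves(node: QueryNode) -> Iterator[TermLeaf]:
    if isinstance(node, TermLeaf):
        yield node
    else:
        yield from iter_leaves(node.left)
        yield from iter_leaves(node.right)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")


def _tokenize(text: str) -> tuple[str, ...]:
    return tuple(t for t in _TOKEN_SPLIT.split(text.lower()) if t)


def _doc_sequences(doc: Document, scope: str) -> list[tuple[str, ...]]:
    """Token sequences searched by a given textual scope, cached per document."""
    cache = doc._token_cache
    seqs = cache.get(scope)
    if seqs is None:
        if scope == "ti":
            seqs = [_tokenize(doc.title)]
        elif scope == "tiab":
            seqs = [_tokenize(doc.title), _tokenize(doc.abstract)]
        else:  # tw: title, abstract, heading names, subheading names
            seqs = [_tokenize(doc.title), _tokenize(doc.abstract)]
            for mh in doc.mesh_headings:
                seqs.append(_tokenize(mh.name))
                for sub in mh.subheadings:
                    seqs.append(_tokenize(sub))
        seqs = [s for s in seqs if s]
        cache[scope] = seqs
    return seqs


def _phrase_in(seq: tuple[str, ...], phrase: tuple[str, ...], truncated: bool) -> bool:
    k = len(phrase)
    if k == 0 or k > len(seq):
        return False
    head, last = phrase[:-1], phrase[-1]
    for start in range(len(seq) - k + 1):
        if seq[start : start + k - 1] == head:
            tail = seq[start + k - 1]
            if tail.startswith(last) if truncated else tail == last:
                return True
    return False


def _name_matches(name: str, term: str, truncated: bool) -> bool:
    a = " ".join(_tokenize(name))
    b = " ".join(_tokenize(term))
    return a.startswith(b) if truncated else a == b


def evaluate_query(
    doc: Document,
    node: QueryNode,
    hierarchy: Optional[Mapping[str, frozenset[str]]] = None,
) -> bool:
    """Decide whether a document matches a parsed query.

    ``hierarchy`` maps a lower-cased MeSH heading name to the set of its
    descendant names; without it, ``[MeSH]`` matches the named heading only
    (no explosion).
    """
    if isinstance(node, BoolNode):
        if node.op == "AND":
            return evaluate_query(doc, node.left, hierarchy) and evaluate_query(
                doc, node.right, hierarchy
            )
        if node.op == "OR":
            return evaluate_query(doc, node.left, hierarchy) or evaluate_query(
                doc, node.right, hierarchy
            )
        return evaluate_query(doc, node.left, hierarchy) and not evaluate_query(
            doc, node.right, hierarchy
        )

    field = node.field
    if field in ("ti", "TIAB", "tw"):
        scope = {"ti": "ti", "TIAB": "tiab", "tw": "tw"}[field]
        phrase = _tokenize(node.term)
        return any(
            _phrase_in(seq, phrase, node.truncated) for seq in _doc_sequences(doc, scope)
        )
    if field in ("MeSH", "MeSH:noexp"):
        names = {node.term.lower()}
        if field == "MeSH" and hierarchy is not None:
            names |= hierarchy.get(" ".join(_tokenize(node.term)), frozenset())
        return any(
            _name_matches(mh.name, name, node.truncated)
            for mh in doc.mesh_headings
            for name in names
        )
    if field == "sh":
        return any(
            _name_matches(sub, node.term, node.truncated)
            for mh in doc.mesh_headings
            for sub in mh.subheadings
        )
    # pt
    return any(
        _name_matches(pt, node.term, node.truncated) for pt in doc.publication_types
    )


def retrieve(
    corpus: LabeledCorpus,
    node: QueryNode,
    hierarchy: Optional[Mapping[str, frozenset[str]]] = None,
) -> frozenset[str]:
    """IDs of exactly the documents matching the query."""
    return frozenset(
        doc.doc_id for doc in corpus.documents if evaluate_query(doc, node, hierarchy)
    )


def load_mesh_hierarchy(stream: IO[str] | Iterable[str]) -> dict[str, frozenset[str]]:
    """Load a two-column child→parent file into a parent→descendants map.

    Names are normalized to lower-cased token strings.  The returned map feeds
    the optional ``hierarchy`` argument of :func:`evaluate_query`.
    """
    parents: dict[str, set[str]] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in re.split(r"\t|,", line) if p.strip()]
        if len(parts) != 2:
            raise ValueError(f"expected two columns (child, parent): {line!r}")
        child = " ".join(_tokenize(parts[0]))
        parent = " ".join(_tokenize(parts[1]))
        parents.setdefault(parent, set()).add(child)

    def descendants(name: str, seen: set[str]) -> set[str]:
        out: set[str] = set()
        for child in parents.get(name, ()):
            if child not in seen:
                seen.add(child)
                out.add(child)
                out |= descendants(child, seen)
        return out

    return {name: frozenset(descendants(name, {name})) for name in parents}
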