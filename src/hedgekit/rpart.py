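"""Multi-term filter induction by recursive partitioning.

A classification tree is grown over Boolean term-filters: at each node the
candidate term with the lowest cost-weighted error rate on the node's
documents becomes the split, the node's documents are partitioned by term
presence, and growth continues on each side with the used term removed from
that path's slate.  A branch stops when the best split's 2×2 association is
no longer significant (P > alpha), when no split strictly reduces the
weighted error, or at the depth bound.  Leaves are then classified
retrieve/discard to minimize cost-weighted error subject to a whole-tree
recall floor (recall-first: ties retrieve), and the tree is converted to a
Boolean filter string — a disjunction over retrieve-paths, factored through
the tree structure, using binary NOT for absent-edges.

Misclassification costs default to prevalence-balanced weights computed from
the full training corpus, so the rare relevant class is not swamped by the
nonrelevant mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterator, Mapping, Optional, Sequence

from .combiner import CandidateTerm
from .corpus import LabeledCorpus
from .metrics import (
    ContingencyTable,
    SplitEvaluation,
    prevalence_balanced_costs,
    split_significance,
    weighted_error_rate,
)
from .query import BoolNode, QueryNode, evaluate_query

__all__ = [
    "RPConfig",
    "RPNode",
    "EmptyFilterError",
    "FilterNotExpressibleError",
    "choose_split",
    "grow_tree",
    "tree_to_boolean",
    "tree_retrieve",
    "tree_to_text",
    "tree_to_json",
    "iter_rp_leaves",
]


class EmptyFilterError(ValueError):
    """The tree retrieves nothing: no Boolean filter can be derived."""


class FilterNotExpressibleError(ValueError):
    """The retrieve region needs a pure complement, which the dialect's
    binary NOT cannot express."""


@dataclass(frozen=True)
class RPConfig:
    """Stopping and cost parameters for tree growth.

    ``alpha``: significance threshold a split's 2×2 association must beat.
    ``recall_floor``: minimum whole-tree recall (percent) the classified tree
    must keep — the overfitting guard applied recall-first.
    ``cost_fn``/``cost_fp``: misclassification costs; ``None`` means
    prevalence-balanced defaults from the training corpus.
    ``max_depth``: safety bound on tree depth.
    """

    alpha: float = 0.05
    recall_floor: float = 99.0
    cost_fn: Optional[float] = None
    cost_fp: Optional[float] = None
    max_depth: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.recall_floor <= 100.0:
            raise ValueError("recall_floor must be in [0, 100]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class RPNode:
    doc_ids: frozenset[str]
    depth: int
    split_term: Optional[CandidateTerm] = None
    present_child: Optional["RPNode"] = None
    absent_child: Optional["RPNode"] = None
    node_table: Optional[ContingencyTable] = None  # split term vs labels here
    p_value: Optional[float] = None
    weighted_error: Optional[float] = None
    leaf_class: Optional[str] = None  # "retrieve" | "discard" on leaves
    n_relevant: int = field(default=0)

    @property
    def is_leaf(self) -> bool:
        return self.split_term is None


def _node_table(node_ids: frozenset[str], retrieved: frozenset[str], relevant: frozenset[str]) -> ContingencyTable:
    present = retrieved & node_ids
    rel = relevant & node_ids
    a = len(present & rel)
    return ContingencyTable(
        a=a, b=len(present) - a, c=len(rel) - a, d=len(node_ids) - len(present) - len(rel) + a
    )


def choose_split(
    node_ids: frozenset[str],
    corpus: LabeledCorpus,
    candidates: Sequence[CandidateTerm],
    config: RPConfig,
    costs: Optional[tuple[float, float]] = None,
) -> Optional[SplitEvaluation]:
    """Best split of a document subset, or None when it fails significance.

    The winner minimizes the weighted error rate of its presence/absence
    partition on the node's documents; ties break toward higher recall, lower
    fallout, then the lexicographically smallest label.  Returns None when the
    best split's association is not significant at ``config.alpha`` or when
    the split would not separate the node.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if not node_ids:
        raise ValueError("empty node")
    cost_fn, cost_fp = costs if costs is not None else _resolve_costs(corpus, config)
    relevant = corpus.relevant_ids

    best: Optional[tuple[tuple, CandidateTerm, ContingencyTable, float]] = None
    for cand in candidates:
        table = _node_table(node_ids, cand.retrieved, relevant)
        wer = weighted_error_rate(table, cost_fn, cost_fp)
        recall = table.a / table.n_relevant if table.n_relevant else 0.0
        fallout = table.b / table.n_nonrelevant if table.n_nonrelevant else 0.0
        key = (wer, -recall, fallout, cand.label)
        if best is None or key < best[0]:
            best = (key, cand, table, wer)
    _, cand, table, wer = best

    if table.a + table.b == 0 or table.c + table.d == 0:
        return None  # does not separate the node
    p = split_significance(table)
    if p > config.alpha:
        return None
    present = ContingencyTable(a=table.a, b=table.b, c=0, d=0)
    absent = ContingencyTable(a=0, b=0, c=table.c, d=table.d)
    return SplitEvaluation(term=cand, weighted_error=wer, p_value=p, child_tables=(present, absent))


def _resolve_costs(corpus: LabeledCorpus, config: RPConfig) -> tuple[float, float]:
    if config.cost_fn is not None and config.cost_fp is not None:
        if config.cost_fn <= 0 or config.cost_fp <= 0:
            raise ValueError("misclassification costs must be positive")
        return config.cost_fn, config.cost_fp
    return prevalence_balanced_costs(corpus.prevalence)


def _leaf_opt_cost(node_ids: frozenset[str], relevant: frozenset[str], cost_fn: float, cost_fp: float) -> float:
    a = len(node_ids & relevant)
    b = len(node_ids) - a
    return min(cost_fn * a, cost_fp * b)  # discard loses a relevant; retrieve admits b


def grow_tree(
    corpus: LabeledCorpus,
    candidates: Sequence[CandidateTerm],
    config: RPConfig = RPConfig(),
) -> RPNode:
    """Grow and classify a recursive-partitioning tree.

    Candidates should be pre-screened (the permissive recall/fallout screen);
    a used term is removed from the slate along its own path but remains
    available in sibling subtrees.  After growth, leaves are classified to
    minimize cost-weighted error subject to the whole-tree recall floor.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    cost_fn, cost_fp = _resolve_costs(corpus, config)
    relevant = corpus.relevant_ids

    def build(node_ids: frozenset[str], slate: tuple[CandidateTerm, ...], depth: int) -> RPNode:
        node = RPNode(doc_ids=node_ids, depth=depth, n_relevant=len(node_ids & relevant))
        if depth >= config.max_depth or not slate:
            return node
        ev = choose_split(node_ids, corpus, slate, config, (cost_fn, cost_fp))
        if ev is None:
            return node
        cand: CandidateTerm = ev.term  # type: ignore[assignment]
        present_ids = frozenset(cand.retrieved & node_ids)
        absent_ids = node_ids - present_ids
        # greedy descent: accept only splits that strictly lower the total
        # weighted error under unconstrained optimal leaf classification
        parent_cost = _leaf_opt_cost(node_ids, relevant, cost_fn, cost_fp)
        child_cost = _leaf_opt_cost(present_ids, relevant, cost_fn, cost_fp) + _leaf_opt_cost(
            absent_ids, relevant, cost_fn, cost_fp
        )
        if child_cost >= parent_cost:
            return node
        node.split_term = cand
        node.node_table = _node_table(node_ids, cand.retrieved, relevant)
        node.p_value = ev.p_value
        node.weighted_error = ev.weighted_error
        child_slate = tuple(t for t in slate if t.label != cand.label)
        node.present_child = build(present_ids, child_slate, depth + 1)
        node.absent_child = build(absent_ids, child_slate, depth + 1)
        return node

    root = build(corpus.ids, tuple(candidates), 0)
    _classify_leaves(root, corpus, cost_fn, cost_fp, config.recall_floor)
    return root


def iter_rp_leaves(tree: RPNode) -> Iterator[RPNode]:
    if tree.is_leaf:
        yield tree
    else:
        yield from iter_rp_leaves(tree.present_child)
        yield from iter_rp_leaves(tree.absent_child)


def _classify_leaves(
    root: RPNode,
    corpus: LabeledCorpus,
    cost_fn: float,
    cost_fp: float,
    recall_floor: float,
) -> None:
    """Retrieve-first classification under the whole-tree recall floor.

    Start from the all-retrieve tree (recall 100) and greedily discard the
    leaves whose discarding most reduces the cost-weighted error, skipping any
    discard that would push whole-tree recall below the floor.  Ties (zero
    reduction) retrieve, favoring recall.
    """
    relevant = corpus.relevant_ids
    n_rel = len(relevant)
    leaves = list(iter_rp_leaves(root))
    for leaf in leaves:
        leaf.leaf_class = "retrieve"
    stats = []
    for idx, leaf in enumerate(leaves):
        a = leaf.n_relevant
        b = len(leaf.doc_ids) - a
        reduction = cost_fp * b - cost_fn * a
        if reduction > 0:
            stats.append((-reduction, idx, leaf, a))
    retrieved_rel = n_rel
    for _, _, leaf, a in sorted(stats, key=lambda s: (s[0], s[1])):
        if 100.0 * (retrieved_rel - a) / n_rel >= recall_floor:
            leaf.leaf_class = "discard"
            retrieved_rel -= a


# ---------------------------------------------------------------------------
# Boolean conversion
# ---------------------------------------------------------------------------

# internal expression algebra with a unary complement, used only during
# conversion; complements must be absorbed into binary NOT before emission
_T, _F = ("T",), ("F",)


def _expr(node: RPNode):
    if node.is_leaf:
        return _T if node.leaf_class == "retrieve" else _F
    t = node.split_term
    p = _expr(node.present_child)
    a = _expr(node.absent_child)
    if p == _T and a == _T:
        return _T
    if p == _F and a == _F:
        return _F
    if p == _T and a == _F:
        return ("leaf", t)
    if p == _F and a == _T:
        return ("neg", t)
    if a == _F:
        return ("and", ("leaf", t), p)
    if p == _F:
        return ("and", ("neg", t), a)
    if p == _T:
        return ("or", ("leaf", t), a)
    if a == _T:
        return ("or", p, ("neg", t))
    return ("or", ("and", ("leaf", t), p), ("and", ("neg", t), a))


def _flatten(expr, op: str):
    if expr[0] == op:
        for sub in expr[1:]:
            yield from _flatten(sub, op)
    else:
        yield expr


def _to_query(expr) -> QueryNode:
    kind = expr[0]
    if kind == "leaf":
        return expr[1].node
    if kind == "neg":
        raise FilterNotExpressibleError(
            "the retrieve region is a pure complement; the dialect's NOT is "
            "binary and cannot express it"
        )
    if kind == "and":
        positives: list[QueryNode] = []
        negatives: list[QueryNode] = []
        for conj in _flatten(expr, "and"):
            if conj[0] == "neg":
                negatives.append(conj[1].node)
            else:
                positives.append(_to_query(conj))
        if not positives:
            raise FilterNotExpressibleError(
                "a conjunction of only complements cannot be expressed with binary NOT"
            )
        node = positives[0]
        for p in positives[1:]:
            node = BoolNode("AND", node, p)
        for n in negatives:
            node = BoolNode("NOT", node, n)
        return node
    if kind == "or":
        node: Optional[QueryNode] = None
        for disj in _flatten(expr, "or"):
            q = _to_query(disj)
            node = q if node is None else BoolNode("OR", node, q)
        return node
    raise AssertionError(f"unexpected expression {expr!r}")


def tree_to_boolean(tree: RPNode) -> QueryNode:
    """Convert a classified tree to an extensionally equivalent Boolean filter.

    The filter is the disjunction over retrieve-leaves of each root-to-leaf
    path's conjunction (term for present-edges, NOT term for absent-edges),
    factored through shared prefixes by the recursive construction.  Raises
    :class:`EmptyFilterError` when no leaf retrieves and
    :class:`FilterNotExpressibleError` when the retrieve region is a pure
    complement (see module notes).
    """
    if any(leaf.leaf_class is None for leaf in iter_rp_leaves(tree)):
        raise ValueError("tree leaves are not classified; grow_tree classifies them")
    expr = _expr(tree)
    if expr == _F:
        raise EmptyFilterError("tree retrieves nothing")
    if expr == _T:
        raise FilterNotExpressibleError("tree retrieves everything; no filter separates")
    return _to_query(expr)


def tree_retrieve(
    tree: RPNode,
    corpus: LabeledCorpus,
    hierarchy: Optional[Mapping[str, frozenset[str]]] = None,
) -> frozenset[str]:
    """IDs of documents reaching retrieve-leaves, by per-document tree walk.

    Works on any corpus (not only the training one): split terms are
    re-evaluated against each document.
    """
    out = set()
    for doc in corpus.documents:
        node = tree
        while not node.is_leaf:
            present = evaluate_query(doc, node.split_term.node, hierarchy)
            node = node.present_child if present else node.absent_child
        if node.leaf_class == "retrieve":
            out.add(doc.doc_id)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def tree_to_text(tree: RPNode, indent: str = "") -> str:
    a = tree.n_relevant
    b = len(tree.doc_ids) - a
    if tree.is_leaf:
        return f"{indent}[{tree.leaf_class}] relevant={a} nonrelevant={b}\n"
    head = (
        f"{indent}split: {tree.split_term.label} "
        f"(weighted_error={tree.weighted_error:.4f}, p={tree.p_value:.3g}, "
        f"relevant={a}, nonrelevant={b})\n"
    )
    return (
        head
        + f"{indent}present:\n"
        + tree_to_text(tree.present_child, indent + "  ")
        + f"{indent}absent:\n"
        + tree_to_text(tree.absent_child, indent + "  ")
    )


def _tree_dict(tree: RPNode) -> dict:
    a = tree.n_relevant
    base = {"depth": tree.depth, "n_docs": len(tree.doc_ids), "n_relevant": a}
    if tree.is_leaf:
        base["leaf_class"] = tree.leaf_class
    else:
        base.update(
            split_term=tree.split_term.label,
            weighted_error=tree.weighted_error,
            p_value=tree.p_value,
            present=_tree_dict(tree.present_child),
            absent=_tree_dict(tree.absent_child),
        )
    return base


def tree_to_json(tree: RPNode, stream: Optional[IO[str]] = None) -> str:
    text = json.dumps(_tree_dict(tree), indent=2)
    if stream is not None:
        stream.write(text + "\n")
    return text
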