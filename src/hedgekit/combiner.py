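"""Screening of single-term filters and exhaustive OR-combination search.

Candidate terms are screened by recall/fallout thresholds (either both must
hold, or either may hold — the looser screen used to feed recursive
partitioning), then every OR-combination of the survivors within a size range
is scored.  Combination retrieval sets are unions of cached per-term retrieval
sets, never query re-evaluation, which makes the exhaustive sweep cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .corpus import LabeledCorpus
from .metrics import MetricsReport, build_contingency, compute_metrics
from .query import QueryNode, parse_query, retrieve

__all__ = [
    "CandidateTerm",
    "BudgetExceededError",
    "EmptyResultError",
    "make_candidates",
    "screen_terms",
    "enumerate_or_combinations",
    "select_best",
]


class BudgetExceededError(RuntimeError):
    pass


class EmptyResultError(LookupError):
    pass


@dataclass(frozen=True)
class CandidateTerm:
    """A candidate filter with its cached retrieval set and training metrics."""

    label: str
    node: QueryNode
    retrieved: frozenset[str]
    metrics: MetricsReport


def make_candidates(
    labels: Iterable[str],
    corpus: LabeledCorpus,
    hierarchy: Optional[Mapping[str, frozenset[str]]] = None,
) -> list[CandidateTerm]:
    """Parse, retrieve and score a slate of candidate query strings."""
    out: list[CandidateTerm] = []
    for label in labels:
        node = parse_query(label)
        hits = retrieve(corpus, node, hierarchy)
        out.append(
            CandidateTerm(
                label=label,
                node=node,
                retrieved=hits,
                metrics=compute_metrics(build_contingency(corpus, hits)),
            )
        )
    return out


def screen_terms(
    candidates: Sequence[CandidateTerm],
    min_recall: float,
    max_fallout: float,
    mode: str = "and",
) -> list[CandidateTerm]:
    """Keep candidates passing the recall/fallout thresholds, order preserved.

    ``mode="and"``: recall > min_recall AND fallout < max_fallout (the strict
    screen); ``mode="or"``: recall > min_recall OR fallout < max_fallout (the
    permissive screen feeding tree induction).  Thresholds are percentages.
    """
    if not 0 <= min_recall <= 100 or not 0 <= max_fallout <= 100:
        raise ValueError("thresholds must be in [0, 100]")
    if mode not in ("and", "or"):
        raise ValueError(f"unknown screen mode {mode!r}")
    out = []
    for cand in candidates:
        hi_recall = cand.metrics.recall > min_recall
        lo_fallout = cand.metrics.fallout < max_fallout
        keep = (hi_recall and lo_fallout) if mode == "and" else (hi_recall or lo_fallout)
        if keep:
            out.append(cand)
    return out


def enumerate_or_combinations(
    terms: Sequence[CandidateTerm],
    k_min: int,
    k_max: int,
    corpus: LabeledCorpus,
    max_subsets: int = 10**6,
) -> list[tuple[tuple[CandidateTerm, ...], MetricsReport]]:
    """Score every size-k OR-combination for k in [k_min, k_max].

    The retrieval set of a combination is the union of its members' cached
    sets.  Raises :class:`BudgetExceededError` if the subset count exceeds
    ``max_subsets`` (exhaustive search over large slates is prohibitive by
    design — that regime belongs to recursive partitioning).
    """
    if not 1 <= k_min <= k_max <= len(terms):
        raise ValueError(f"need 1 <= k_min <= k_max <= {len(terms)}")
    import math

    total = sum(math.comb(len(terms), k) for k in range(k_min, k_max + 1))
    if total > max_subsets:
        raise BudgetExceededError(
            f"{total} subsets exceed the budget of {max_subsets}"
        )
    scored = []
    for k in range(k_min, k_max + 1):
        for subset in itertools.combinations(terms, k):
            union: frozenset[str] = frozenset().union(*(t.retrieved for t in subset))
            report = compute_metrics(build_contingency(corpus, union))
            scored.append((subset, report))
    return scored


_OBJECTIVES = ("recall", "precision", "f")


def select_best(
    scored: Sequence[tuple[tuple[CandidateTerm, ...], MetricsReport]],
    objective: str,
    fallout_cap: float = 50.0,
    recall_floor: float = 50.0,
) -> tuple[tuple[CandidateTerm, ...], MetricsReport]:
    """Pick the best combination under an objective and its constraint.

    ``recall``: highest recall with fallout below ``fallout_cap``;
    ``precision``: highest precision with recall above ``recall_floor``;
    ``f``: highest F-measure (unconstrained).  Ties break toward higher
    recall, then lower fallout, then the lexicographically smallest sorted
    label tuple, so the result is order-independent.
    """
    if objective not in _OBJECTIVES:
        raise ValueError(f"objective must be one of {_OBJECTIVES}")
    if not scored:
        raise EmptyResultError("no scored combinations given")

    def admissible(report: MetricsReport) -> bool:
        if objective == "recall":
            return report.fallout < fallout_cap
        if objective == "precision":
            return report.recall > recall_floor and report.precision is not None
        return report.f_measure is not None

    def score(report: MetricsReport) -> float:
        if objective == "recall":
            return report.recall
        if objective == "precision":
            return report.precision  # type: ignore[return-value]
        return report.f_measure  # type: ignore[return-value]

    def sort_key(item):
        subset, report = item
        return (
            -score(report),
            -report.recall,
            report.fallout,
            tuple(sorted(t.label for t in subset)),
        )

    pool = [item for item in scored if admissible(item[1])]
    if not pool:
        raise EmptyResultError(f"no combination satisfies the {objective} constraint")
    return min(pool, key=sort_key)
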