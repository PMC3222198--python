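"""Retrieval metrics and the statistics used by recursive partitioning.

The 2×2 contingency table cells are named A (relevant retrieved),
B (nonrelevant retrieved), C (relevant missed), D (nonrelevant missed), and
the derived measures are

    recall    = A / (A + C)
    precision = A / (A + B)
    F         = 2·P·R / (P + R)
    NNR       = 1 / precision          (number needed to read)
    fallout   = B / (B + D)

Recall, precision and fallout are reported in percent; F is computed on the
percent scale (as filter-evaluation tables conventionally print it); NNR is
articles per relevant article.  The weighted error rate generalizes the
misclassification rate with class-dependent costs, defaulting to
prevalence-balanced costs so the rare relevant class is not swamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from scipy import stats

from .corpus import LabeledCorpus, UnknownIdError

__all__ = [
    "ContingencyTable",
    "MetricsReport",
    "SplitEvaluation",
    "UndefinedRecallError",
    "build_contingency",
    "compute_metrics",
    "weighted_error_rate",
    "prevalence_balanced_costs",
    "split_significance",
    "round_half_up",
    "f_measure_from_percent",
    "nnr_from_percent",
]


class UndefinedRecallError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # relevant retrieved
    b: int  # nonrelevant retrieved
    c: int  # relevant missed
    d: int  # nonrelevant missed

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_relevant(self) -> int:
        return self.a + self.c

    @property
    def n_nonrelevant(self) -> int:
        return self.b + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class MetricsReport:
    """Raw (unrounded) performance measures; ``rounded()`` mirrors print style.

    ``precision`` and ``f_measure`` are ``None`` when nothing was retrieved
    (precision undefined); ``nnr`` is ``inf`` when no relevant document was
    retrieved.
    """

    recall: float  # percent
    precision: Optional[float]  # percent, None when a + b = 0
    f_measure: Optional[float]  # percent scale
    fallout: float  # percent
    nnr: float  # 1/precision-as-fraction; inf when a = 0

    def rounded(self) -> dict:
        """Print-style rounding: whole-percent recall, 2-decimal precision/F,
        NNR to two significant figures up to 10 and an integer above."""
        out = {
            "recall": int(round_half_up(self.recall, 0)),
            "precision": None
            if self.precision is None
            else float(round_half_up(self.precision, 2)),
            "f_measure": None
            if self.f_measure is None
            else float(round_half_up(self.f_measure, 2)),
            "fallout": float(round_half_up(self.fallout, 2)),
        }
        if math.isinf(self.nnr):
            out["nnr"] = math.inf
        elif self.nnr <= 10:
            out["nnr"] = float(round_half_up(self.nnr, 1))
        else:
            out["nnr"] = int(round_half_up(self.nnr, 0))
        return out


@dataclass(frozen=True)
class SplitEvaluation:
    """One candidate term assessed as a split of a document subset."""

    term: object  # CandidateTerm; typed loosely to avoid a module cycle
    weighted_error: float
    p_value: float
    child_tables: tuple[ContingencyTable, ContingencyTable]  # (present, absent)


def round_half_up(x: float, ndigits: int) -> Decimal:
    """Round half away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)


def build_contingency(corpus: LabeledCorpus, retrieved: frozenset[str] | set[str]) -> ContingencyTable:
    """Cross-tabulate a retrieval set against the corpus gold standard."""
    retrieved = frozenset(retrieved)
    unknown = retrieved - corpus.ids
    if unknown:
        raise UnknownIdError(sorted(unknown))
    rel = corpus.relevant_ids
    a = len(retrieved & rel)
    b = len(retrieved) - a
    c = len(rel) - a
    d = corpus.n_documents - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def compute_metrics(table: ContingencyTable) -> MetricsReport:
    """Apply the standard formulas; raises if no relevant documents exist."""
    if table.n_relevant == 0:
        raise UndefinedRecallError("no relevant documents: recall undefined")
    recall = 100.0 * table.a / table.n_relevant
    retrieved = table.a + table.b
    if retrieved == 0:
        precision: Optional[float] = None
        f: Optional[float] = None
    else:
        precision = 100.0 * table.a / retrieved
        f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    nnr = math.inf if table.a == 0 else retrieved / table.a
    fallout = 0.0 if table.n_nonrelevant == 0 else 100.0 * table.b / table.n_nonrelevant
    return MetricsReport(recall=recall, precision=precision, f_measure=f, fallout=fallout, nnr=nnr)


def f_measure_from_percent(recall: float, precision: float) -> float:
    """F-measure on the percent scale from percent recall and precision.

    Applies F = 2·P·R/(P+R) directly to the percent values, the convention of
    printed filter-evaluation tables.
    """
    if recall < 0 or precision < 0:
        raise ValueError("recall and precision must be non-negative")
    if recall + precision == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def nnr_from_percent(precision: float) -> float:
    """Number needed to read from percent precision: 100/precision."""
    if precision < 0:
        raise ValueError("precision must be non-negative")
    return math.inf if precision == 0 else 100.0 / precision


def prevalence_balanced_costs(prevalence: float) -> tuple[float, float]:
    """Default misclassification costs (cost_fn, cost_fp) = (1/π, 1/(1−π)).

    Under these costs the weighted error rate equals the mean of the miss rate
    and the fallout as fractions, so the rare relevant class carries the same
    total weight as the abundant nonrelevant class.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    return 1.0 / prevalence, 1.0 / (1.0 - prevalence)


def weighted_error_rate(table: ContingencyTable, cost_fn: float, cost_fp: float) -> float:
    """Cost-weighted misclassification rate of a retrieval seen as a classifier:

        (cost_fn·C + cost_fp·B) / (cost_fn·(A+C) + cost_fp·(B+D))

    Zero iff the retrieval classifies perfectly; invariant to joint rescaling
    of both costs.
    """
    if cost_fn <= 0 or cost_fp <= 0:
        raise ValueError("misclassification costs must be positive")
    denom = cost_fn * table.n_relevant + cost_fp * table.n_nonrelevant
    if denom == 0:
        return 0.0
    return (cost_fn * table.c + cost_fp * table.b) / denom


def split_significance(table: ContingencyTable) -> float:
    """P value of the association between retrieval and relevance.

    Pearson chi-square without continuity correction on the 2×2 table; when
    any expected cell is below 5, Fisher's exact test (two-sided) is used
    instead.  A zero margin (no variation on either axis) yields P = 1.
    """
    obs = [[table.a, table.b], [table.c, table.d]]
    row = [table.a + table.b, table.c + table.d]
    col = [table.a + table.c, table.b + table.d]
    n = table.n
    if n == 0 or 0 in row or 0 in col:
        return 1.0
    min_expected = min(r * c / n for r in row for c in col)
    if min_expected < 5:
        return float(stats.fisher_exact(obs).pvalue)
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(p)
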