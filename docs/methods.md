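# Methods

## The problem

A search filter (hedge) is a Boolean query meant to retrieve one class of
studies from a bibliographic database. Filter development needs a labeled
corpus: a set of records with a hand-screened gold standard of relevant
articles. The defining difficulty is extreme class imbalance — relevant
articles are typically well under 1% of the corpus — so every statistic used
during development must be protected against the nonrelevant mass swamping
the relevant class.

hedgekit covers the full development loop: evaluate candidate single terms,
exhaustively combine the survivors with OR, induce a mixed AND/OR filter by
recursive partitioning, validate against a held-out corpus, and quantify the
extra recall available from reference-list checking.

## Retrieval model and metrics

A query is evaluated per document. Text scopes tokenize on any
non-alphanumeric character and case-fold; there is no stemming — truncation
is explicit (`exam*` is a token-prefix match). Quoted and unquoted
multi-word terms match as contiguous token phrases. `[tw]` searches title,
abstract, MeSH heading names and subheading names as separate token
sequences (phrases never match across field boundaries). `[MeSH]` is an
exact heading-name match; explosion to descendant headings happens only when
the caller supplies a hierarchy (child→parent file), because no vocabulary
hierarchy ships with the package — `noexp` then suppresses it. `NOT` is
binary set-difference, mirroring the database dialects these filters target;
a query cannot begin with `NOT`.

Retrieval against a labeled corpus yields the 2×2 table (A relevant
retrieved, B nonrelevant retrieved, C relevant missed, D nonrelevant
missed) and

- recall = A/(A+C), precision = A/(A+B), fallout = B/(B+D), all in percent;
- F = 2PR/(P+R) computed on the percent scale, the convention of printed
  filter-evaluation tables;
- number needed to read NNR = 1/precision (articles read per relevant
  article found).

When nothing is retrieved, precision and F are reported as missing rather
than 0, so empty filters can never win a ranking; NNR is infinite when no
relevant article is retrieved. Rounded report values mirror print style
(whole-percent recall, two-decimal precision/F, NNR to two significant
figures up to 10 and an integer above); the raw values are always retained
alongside, because printed tables rounded from unrounded intermediates are
not generally recomputable from their own rounded columns.

## Weighted error rate and split significance

The tree inducer ranks candidate splits by the cost-weighted
misclassification rate

    WER = (cost_fn·C + cost_fp·B) / (cost_fn·(A+C) + cost_fp·(B+D)).

Default costs are prevalence-balanced: cost_fn = 1/π, cost_fp = 1/(1−π)
with π the relevant prevalence of the *full training corpus* (not the
current node), under which WER is exactly the mean of the miss rate and the
fallout — each class contributes equally regardless of imbalance. Both costs
are configurable; WER is invariant to jointly rescaling them.

Split significance is the Pearson chi-square test of independence on the
2×2 retrieved × relevant table, one degree of freedom, no continuity
correction; when any expected cell is below 5 the two-sided Fisher exact
test is used instead. A zero margin (the split does not vary, or the node is
single-class) yields P = 1, which stops the branch. The test is applied to
the split's own 2×2 association — equivalent to comparing the class
proportions of the two child subsets — which is the reading adopted here of
"the two tables created by the split"; it is a design choice, exposed via
`alpha` (default 0.05).

## Combination search

Single terms are screened by thresholds on recall and fallout, in two modes:
both conditions (the strict screen used before exhaustive combination,
default recall > 25% and fallout < 50%) or either condition (the permissive
screen that feeds tree induction, default recall > 25% or fallout < 75%).
All OR-combinations of the survivors within a size range are scored; each
combination's retrieval set is the union of cached per-term retrieval sets,
which the tests verify is identical to re-evaluating the OR query. A subset
budget (default 10⁶) makes the exponential regime an explicit error rather
than a hang: exhaustive search is for small slates, trees for large ones.
Selection objectives mirror practice: best recall subject to a fallout cap,
best precision subject to a recall floor, best F. Ties break toward higher
recall, then lower fallout, then the lexicographically smallest label tuple,
so results are independent of input order.

## Recursive partitioning

Growth is greedy: at each node the candidate with the lowest WER on the
node's documents becomes the split, provided its association passes the
significance test and the split strictly lowers the total weighted error
under optimal (unconstrained) leaf classification. The used term is removed
from the slate along that path but stays available to siblings. Depth is
bounded (default 10) as an overfitting guard.

Leaves are then classified retrieve/discard. Classification is
recall-first: start from the all-retrieve tree and greedily discard the
leaves whose discarding most reduces cost-weighted error, skipping any
discard that would push *whole-tree* recall below the floor (default 99%).
Ties retrieve. The floor is deliberately enforced on the whole tree rather
than per branch: a per-branch reading would forbid any pure-nonrelevant
leaf from being discarded, and no useful filter could be expressed.

`tree_to_boolean` converts the classified tree to a filter: the disjunction
over retrieve-leaves of each root-to-leaf path conjunction (term on
present-edges, NOT term on absent-edges), factored through shared prefixes
by recursive construction — e.g. a present-side retrieve leaf over subtree
`A` emits `t OR A` rather than `(t) OR (NOT t AND A)`. Extensional
equivalence with the tree is guaranteed and verified by a per-document
tree-walk oracle; syntactic minimality is best-effort. Because the dialect's
NOT is binary, a retrieve region that is a pure complement (no positive
anchor anywhere on the path — e.g. a single split whose absent side
retrieves while the present side discards) cannot be written as a query and
raises `FilterNotExpressibleError`. Trees grown on rare-relevant corpora do
not produce such regions, since the large nonrelevant all-absent leaf is
always discarded.

## Reference-list augmentation

Given a citation graph (citing → referenced IDs; off-corpus references
ignored), one augmentation round adds the relevant documents referenced by
retrieved relevant documents — mirroring how a reviewer checks the
bibliographies of included articles, where relevance is judged on sight, so
only relevant references enter the result. Recall and precision therefore
never decrease. Following references of all retrieved documents, and
iterating to transitive closure, are flag-gated variants; the default is a
single round over relevant retrievals.

## Synthetic corpora

The generator emulates a very-low-prevalence labeled corpus. Each vocabulary
term is a single token placed in the title, abstract, or as a MeSH heading,
with class-conditional occurrence probabilities; labels are independent
Bernoulli draws at the configured prevalence. With a planted Boolean rule,
occurrences are drawn first (each term at its marginal probability — the
class-conditional pair cannot apply when the label derives from the
occurrences) and the label is the rule value XOR an optional noise flip.
Generation is fully determined by the seed.

The standard planted-rule condition used in tests and the acceptance script
is 5,000 documents, a noiseless rule `(palpation AND auscultation) OR bruit`
with occurrence probabilities (0.10, 0.10, 0.0105) giving the rule a ≈2%
hit rate, and ten label-independent distractors at realistic occurrence
rates (0.05–0.30). Sizes were chosen so every relevant subgroup still holds
dozens of documents (significance tests retain power) while the full suite
runs in seconds.

What passing these tests shows — and does not. Synthetic corpora have exact
single-token terms, field-clean placement, conditionally independent
occurrences and (in planted-rule mode) a perfectly realizable target. Real
bibliographic corpora have correlated terms, indexing inconsistency (e.g.
relevant studies only partially tagged with the pertinent MeSH headings),
multi-word and truncated term families, and no guarantee that any Boolean
combination of candidate terms separates the classes. Recovery of a planted
rule therefore validates the machinery (screening, splitting, stopping,
classification, Boolean conversion), not the expected precision of filters
developed on real data, which published evaluations find to be very low
(under 2%) in this domain.

## Numerical and edge-case choices

- Rounding of report values is half-away-from-zero (decimal), matching
  printed tables, never banker's rounding.
- A corpus with zero or all-relevant documents is rejected as degenerate
  (recall or fallout would be undefined), as is an empty label list.
- Duplicate document IDs and labels referencing unknown IDs are hard errors
  naming the offenders; MEDLINE parse errors carry the line number.
- Candidate ties anywhere (split choice, combination selection) break by
  fixed deterministic keys; reruns are byte-identical.
- Costs must be strictly positive; thresholds are validated to [0, 100].

## Known limitations

- `[tw]` approximates text-word scope as title ∪ abstract ∪ heading ∪
  subheading names; databases index further fields (e.g. author keywords)
  that the data model omits.
- No automatic term mapping: untagged terms default to `[tw]` rather than
  being expanded against a vocabulary.
- No date/range tags, `[majr]`, or proximity operators.
- MeSH explosion requires a user-supplied hierarchy; none ships.
- Tree induction offers no cross-validation pruning or surrogate splits;
  predictors are Boolean term-filters only.
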