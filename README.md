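# hedgekit

Tools for developing and validating Boolean literature-search filters
("hedges") against labeled bibliographic corpora.

Search filters are pretested Boolean queries — e.g.
`(Diagnosis[tw] AND (specific*[tw] OR clinical*[tw] OR exam*[tw])) OR
"sensitivity and specificity"[MeSH]` — designed to retrieve a class of
studies (such as clinical-examination studies, which quantify the diagnostic
value of symptoms and signs) from MEDLINE-style databases. Developing a good
filter means evaluating many candidate terms against a hand-labeled corpus in
which relevant articles are extremely rare (on the order of 60 relevant among
50,000+ records) and combining the best terms without overfitting. hedgekit
is aimed at information specialists, systematic reviewers and methodologists
who build or audit such filters.

## What it does

- **Corpus handling** — MEDLINE flat files (`PMID`/`TI`/`AB`/`MH`/`PT` tags)
  and a line-delimited JSON format; gold-standard label lists; a seeded
  synthetic-corpus generator with class-conditional term probabilities and an
  optional planted Boolean rule.
- **Query engine** — the PubMed-style dialect with field tags `[tw]`,
  `[TIAB]`, `[ti]`, `[MeSH]` (optional explosion via a user hierarchy,
  `[MeSH:noexp]`), `[sh]`, `[pt]`, quoted phrases, `*` truncation, and
  `AND`/`OR`/binary `NOT`.
- **Metrics** — the 2×2 contingency table and recall `A/(A+C)`, precision
  `A/(A+B)`, F-measure `2PR/(P+R)` on the percent scale, fallout `B/(B+D)`,
  and number needed to read `1/precision`; plus the cost-weighted error rate
  and the chi-square split-significance test used by tree induction.
- **Combination search** — screen single terms by recall/fallout thresholds,
  exhaustively score every OR-combination of the survivors, and select the
  best under recall-, precision- or F-objectives with constraints.
- **Recursive partitioning** — grow a classification tree over term-filters
  by minimizing the prevalence-weighted error rate, with significance
  stopping (P > .05), a whole-tree recall floor (default 99%), and conversion
  of the tree to a Boolean filter string that mixes AND and OR.
- **Reference-list checking** — quantify the recall gained by following the
  bibliographies of retrieved relevant articles (citation snowballing).
- **Registry** — the published clinical-examination filters as named,
  parseable definitions, plus user filter files.

## Worked example

Induce a multi-term filter on a synthetic corpus whose labels follow a
planted rule `(palpation AND auscultation) OR bruit` at 2% prevalence, with
ten distractor terms:

```python
from hedgekit.corpus import planted_rule_config, generate_synthetic_corpus
from hedgekit.combiner import make_candidates, screen_terms
from hedgekit.rpart import RPConfig, grow_tree, tree_to_boolean
from hedgekit.query import retrieve, to_query_string
from hedgekit.metrics import build_contingency, compute_metrics

cfg = planted_rule_config(seed=7, n_docs=5000)
corpus, truth = generate_synthetic_corpus(cfg)
print("docs", corpus.n_documents, "relevant", len(corpus.relevant_ids))

candidates = make_candidates([f"{t.token}[tw]" for t in cfg.vocabulary], corpus)
slate = screen_terms(candidates, 25, 75, mode="or")   # permissive screen
tree = grow_tree(corpus, slate, RPConfig())           # alpha .05, floor 99%
filt = tree_to_boolean(tree)
print("filter:", to_query_string(filt))
report = compute_metrics(build_contingency(corpus, retrieve(corpus, filt)))
print(report.rounded())
```

Output:

```
docs 5000 relevant 95
filter: auscultation[tw] AND (palpation[tw] OR bruit[tw]) OR bruit[tw] NOT auscultation[tw]
{'recall': 100, 'precision': 100.0, 'f_measure': 100.0, 'fallout': 0.0, 'nnr': 1.0}
```

The induced filter is extensionally identical to the planted rule: recall
100% (every relevant document retrieved), precision 100% (no nonrelevant
document retrieved), so a reader needs to read exactly 1 article per relevant
article found (NNR 1.0).

The same workflow is available from the shell:

```sh
hedgekit simulate --config cfg.json --out-prefix corpus
hedgekit develop  --corpus corpus.jsonl --labels corpus.labels \
                  --terms terms.txt --out-dir run/
hedgekit evaluate --corpus corpus.jsonl --labels corpus.labels \
                  --filter RP-filter --out report.csv
hedgekit augment  --corpus corpus.jsonl --labels corpus.labels \
                  --filter RP-filter --graph refs.tsv --out aug.json
```

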