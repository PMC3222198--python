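import numpy as np
import pytest

from hedgekit.combiner import CandidateTerm, make_candidates, screen_terms
from hedgekit.corpus import generate_synthetic_corpus, planted_rule_config
from hedgekit.metrics import (
    build_contingency,
    compute_metrics,
    prevalence_balanced_costs,
    weighted_error_rate,
)
from hedgekit.query import parse_query, retrieve, to_query_string
from hedgekit.rpart import (
    EmptyFilterError,
    FilterNotExpressibleError,
    RPConfig,
    RPNode,
    choose_split,
    grow_tree,
    iter_rp_leaves,
    tree_retrieve,
    tree_to_boolean,
    tree_to_json,
    tree_to_text,
)

from conftest import make_corpus, make_doc, random_corpus

RP_FILTER = (
    '(Diagnosis[tw] AND (specific*[tw] OR clinical*[tw] OR exam*[tw])) '
    'OR "sensitivity and specificity"[MeSH]'
)


def term(label, corpus=None):
    node = parse_query(label)
    retrieved = retrieve(corpus, node) if corpus is not None else frozenset()
    return CandidateTerm(label=label, node=node, retrieved=retrieved, metrics=None)


def leaf(ids, cls):
    ids = frozenset(ids)
    return RPNode(doc_ids=ids, depth=0, leaf_class=cls)


def split_node(cand, present, absent):
    return RPNode(
        doc_ids=present.doc_ids | absent.doc_ids,
        depth=0,
        split_term=cand,
        present_child=present,
        absent_child=absent,
    )


class TestChooseSplit:
    def test_perfect_separator_wins_with_zero_error(self):
        docs = [make_doc(f"r{i}", title="marker") for i in range(5)] + [
            make_doc(f"n{i}", title="base") for i in range(20)
        ]
        corpus = make_corpus(docs, {f"r{i}" for i in range(5)})
        cands = make_candidates(["marker[tw]", "base[tw]"], corpus)
        ev = choose_split(corpus.ids, corpus, cands, RPConfig())
        assert ev.term.label == "marker[tw]"
        assert ev.weighted_error == 0.0
        assert ev.p_value < 0.05

    def test_uninformative_candidates_yield_none(self):
        # term present in 50% of both classes: no association
        docs = []
        for i in range(40):
            title = "marker" if i % 2 == 0 else "other"
            docs.append(make_doc(f"d{i}", title=title))
        corpus = make_corpus(docs, {f"d{i}" for i in range(0, 40, 4)} | {f"d{i}" for i in range(1, 40, 4)})
        cands = make_candidates(["marker[tw]"], corpus)
        assert choose_split(corpus.ids, corpus, cands, RPConfig()) is None

    def test_matches_exhaustive_per_candidate_scoring(self):
        rng = np.random.default_rng(23)
        corpus = random_corpus(rng, 250, ["alpha", "beta", "gamma", "delta", "epsilon"])
        cands = make_candidates(
            [f"{t}[tw]" for t in ["alpha", "beta", "gamma", "delta", "epsilon"]], corpus
        )
        costs = prevalence_balanced_costs(corpus.prevalence)
        node_ids = frozenset(list(corpus.ids)[:180])
        ev = choose_split(node_ids, corpus, cands, RPConfig(alpha=0.999), costs)
        # brute-force oracle: score every candidate on the node subset
        rel = corpus.relevant_ids & node_ids
        best_err = None
        for cand in cands:
            present = cand.retrieved & node_ids
            a = len(present & rel)
            t = build_contingency  # noqa: F841  (documented alternative path)
            from hedgekit.metrics import ContingencyTable

            table = ContingencyTable(
                a=a,
                b=len(present) - a,
                c=len(rel) - a,
                d=len(node_ids) - len(present) - len(rel) + a,
            )
            err = weighted_error_rate(table, *costs)
            if best_err is None or err < best_err:
                best_err = err
        if ev is not None:
            assert ev.weighted_error == pytest.approx(best_err)

    def test_empty_candidate_list_is_an_error(self):
        corpus = make_corpus([make_doc("a"), make_doc("b")], {"a"})
        with pytest.raises(ValueError):
            choose_split(corpus.ids, corpus, [], RPConfig())


def _grown(seed=31, n_docs=2500):
    cfg = planted_rule_config(seed=seed, n_docs=n_docs)
    corpus, truth = generate_synthetic_corpus(cfg)
    cands = make_candidates([f"{t.token}[tw]" for t in cfg.vocabulary], corpus)
    slate = screen_terms(cands, 25, 75, mode="or")
    return corpus, truth, grow_tree(corpus, slate, RPConfig())


class TestGrowTree:
    def test_single_term_label_gives_depth_one_tree(self):
        docs = [make_doc(f"r{i}", title="marker") for i in range(8)] + [
            make_doc(f"n{i}", title="base") for i in range(40)
        ]
        corpus = make_corpus(docs, {f"r{i}" for i in range(8)})
        cands = make_candidates(["marker[tw]", "base[tw]"], corpus)
        tree = grow_tree(corpus, cands, RPConfig())
        assert tree.split_term.label == "marker[tw]"
        assert tree.present_child.is_leaf and tree.absent_child.is_leaf
        assert tree.present_child.leaf_class == "retrieve"
        assert tree.absent_child.leaf_class == "discard"

    def test_planted_rule_recovered_exactly(self):
        corpus, truth, tree = _grown()
        node = tree_to_boolean(tree)
        hits = retrieve(corpus, node)
        assert hits == truth.relevant_ids

    def test_determinism(self):
        _, _, t1 = _grown(seed=31)
        _, _, t2 = _grown(seed=31)
        assert tree_to_json(t1) == tree_to_json(t2)
        assert to_query_string(tree_to_boolean(t1)) == to_query_string(tree_to_boolean(t2))

    def test_whole_tree_recall_respects_floor(self):
        corpus, _, tree = _grown(seed=77)
        report = compute_metrics(build_contingency(corpus, tree_retrieve(tree, corpus)))
        assert report.recall >= RPConfig().recall_floor

    def test_every_split_strictly_reduces_weighted_error(self):
        corpus, _, tree = _grown(seed=13)
        fn, fp = prevalence_balanced_costs(corpus.prevalence)
        rel = corpus.relevant_ids

        def opt_cost(ids):
            a = len(ids & rel)
            return min(fn * a, fp * (len(ids) - a))

        def check(node):
            if node.is_leaf:
                return
            parent = opt_cost(node.doc_ids)
            children = opt_cost(node.present_child.doc_ids) + opt_cost(node.absent_child.doc_ids)
            assert children < parent
            check(node.present_child)
            check(node.absent_child)

        check(tree)

    def test_used_term_removed_along_path(self):
        corpus, _, tree = _grown(seed=5)

        def check(node, used):
            if node.is_leaf:
                return
            assert node.split_term.label not in used
            check(node.present_child, used | {node.split_term.label})
            check(node.absent_child, used | {node.split_term.label})

        check(tree, set())


class TestTreeToBoolean:
    def test_depth_one_present_retrieve_is_the_bare_term(self):
        t = term("marker[tw]")
        tree = split_node(t, leaf({"a"}, "retrieve"), leaf({"b"}, "discard"))
        assert to_query_string(tree_to_boolean(tree)) == "marker[tw]"

    def test_tree_walk_oracle_equivalence(self):
        corpus, _, tree = _grown(seed=19)
        node = tree_to_boolean(tree)
        walked = tree_retrieve(tree, corpus)
        leaf_union = frozenset().union(
            *(l.doc_ids for l in iter_rp_leaves(tree) if l.leaf_class == "retrieve")
        )
        assert retrieve(corpus, node) == walked == leaf_union

    def test_equivalence_holds_on_fresh_corpora(self):
        fresh = generate_synthetic_corpus(planted_rule_config(seed=101, n_docs=2000))[0]
        _, _, tree = _grown(seed=102, n_docs=2000)
        node = tree_to_boolean(tree)
        assert retrieve(fresh, node) == tree_retrieve(tree, fresh)

    def test_published_chain_structure_yields_published_filter(self):
        """A stick-shaped tree (MeSH split at the root, then diagnosis and the
        three truncated text words) converts to a filter extensionally equal
        to the published multi-term filter."""
        ss = term('"sensitivity and specificity"[MeSH]')
        diag = term("Diagnosis[tw]")
        spec, clin, exam = term("specific*[tw]"), term("clinical*[tw]"), term("exam*[tw]")
        chain = split_node(
            exam, leaf({"p3"}, "retrieve"), leaf({"a3"}, "discard")
        )
        chain = split_node(clin, leaf({"p2"}, "retrieve"), chain)
        chain = split_node(spec, leaf({"p1"}, "retrieve"), chain)
        chain = split_node(diag, chain, leaf({"a0"}, "discard"))
        tree = split_node(ss, leaf({"top"}, "retrieve"), chain)

        converted = tree_to_boolean(tree)
        published = parse_query(RP_FILTER)
        rng = np.random.default_rng(55)
        docs = []
        for i in range(400):
            words = ["filler"]
            for w in ("diagnosis", "specificity", "clinically", "examination"):
                if rng.random() < 0.3:
                    words.append(w)
            mesh = ["Sensitivity and Specificity"] if rng.random() < 0.2 else []
            docs.append(make_doc(f"d{i}", title=" ".join(words), mesh=mesh))
        corpus = make_corpus(docs, {"d0", "d1"})
        assert retrieve(corpus, converted) == retrieve(corpus, published)
        assert retrieve(corpus, converted) == tree_retrieve(tree, corpus)

    def test_no_retrieve_leaf_is_empty_filter_error(self):
        t = term("marker[tw]")
        tree = split_node(t, leaf({"a"}, "discard"), leaf({"b"}, "discard"))
        with pytest.raises(EmptyFilterError):
            tree_to_boolean(tree)

    def test_pure_complement_is_not_expressible(self):
        t = term("marker[tw]")
        tree = split_node(t, leaf({"a"}, "discard"), leaf({"b"}, "retrieve"))
        with pytest.raises(FilterNotExpressibleError):
            tree_to_boolean(tree)

    def test_text_and_json_serializations_cover_the_tree(self):
        corpus, _, tree = _grown(seed=3)
        text = tree_to_text(tree)
        assert "split:" in text and "[retrieve]" in text
        import json

        blob = json.loads(tree_to_json(tree))
        assert blob["n_docs"] == corpus.n_documents
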