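"""Feature spaces: alternate forms, term counting, is-a propagation, tf-idf,
chi-square selection — each against hand traces or brute-force oracles."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer

from autoannot.feature_spaces import (
    FittedVocabulary,
    Ontology,
    OntologyTerm,
    TfidfConfig,
    build_bow_counts,
    build_form_table,
    chi2_select,
    count_ontology_terms,
    fit_tfidf,
    generate_alternate_forms,
    propagate_isa_counts,
    transform_tfidf,
)
from oracles import chi2_scores_oracle, tfidf_oracle


def _ontology(term_names, edges=(), aliases=None):
    terms = {
        tid: OntologyTerm(term_id=tid, name=name,
                          aliases=(aliases or {}).get(tid, []))
        for tid, name in term_names.items()
    }
    return Ontology(terms=terms, isa_edges=list(edges))


class TestAlternateForms:
    def test_hyphen_variants(self):
        forms = generate_alternate_forms("self-control")
        # original hyphenated form, space-split, and joined variants (stemmed)
        assert ("self-control",) in forms
        assert ("self", "control") in forms
        assert ("selfcontrol",) in forms

    def test_parenthetical_fronting(self):
        forms = generate_alternate_forms("memory (working)")
        assert ("work", "memori") in forms

    def test_plain_term(self):
        assert generate_alternate_forms("attention") == {("attent",)}

    def test_slash_split(self):
        forms = generate_alternate_forms("judgment/decision")
        assert ("judgment",) in forms
        assert ("decis",) in forms

    def test_aliases_included(self):
        forms = generate_alternate_forms("executive function",
                                         aliases=["executive control"])
        assert ("execut", "function") in forms
        assert ("execut", "control") in forms


class TestCountOntologyTerms:
    def test_bigram_and_unigram(self):
        onto = _ontology({"t1": "working memory", "t2": "task"})
        counts = count_ontology_terms(["work", "memori", "task"], onto)
        assert counts == {"t1": 1, "t2": 1}

    def test_no_matches(self):
        onto = _ontology({"t1": "working memory"})
        assert count_ontology_terms(["fish", "stick"], onto) == {}

    def test_longest_match_consumes_tokens(self):
        # "working memory" must not also count as the substring term "memory"
        onto = _ontology({"t1": "working memory", "t2": "memory"})
        counts = count_ontology_terms(["work", "memori"], onto)
        assert counts == {"t1": 1}
        counts2 = count_ontology_terms(["memori"], onto)
        assert counts2 == {"t2": 1}


class TestIsaPropagation:
    def test_chain(self):
        onto = _ontology({"A": "a", "B": "b", "C": "c"},
                         edges=[("A", "B"), ("B", "C")])
        out = propagate_isa_counts({"A": 2, "B": 1, "C": 0}, onto)
        assert (out["A"], out["B"], out["C"]) == (2, 3, 3)

    def test_no_edges_identity(self):
        onto = _ontology({"A": "a", "B": "b"})
        out = propagate_isa_counts({"A": 5}, onto)
        assert out["A"] == 5 and out["B"] == 0

    def test_diamond_per_edge_double_counts_apex(self):
        onto = _ontology(
            {"A": "a", "B": "b", "C": "c", "D": "d"},
            edges=[("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")],
        )
        out = propagate_isa_counts({"D": 1}, onto)
        assert (out["D"], out["B"], out["C"], out["A"]) == (1, 1, 1, 2)

    def test_diamond_per_descendant_counts_once(self):
        onto = _ontology(
            {"A": "a", "B": "b", "C": "c", "D": "d"},
            edges=[("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")],
        )
        out = propagate_isa_counts({"D": 1}, onto, mode="per_descendant")
        assert (out["D"], out["B"], out["C"], out["A"]) == (1, 1, 1, 1)

    def test_monotone_vs_raw(self):
        rng = np.random.default_rng(3)
        onto = _ontology(
            {f"T{i}": f"t{i}" for i in range(8)},
            edges=[("T0", "T1"), ("T1", "T2"), ("T3", "T2"), ("T4", "T5")],
        )
        raw = {f"T{i}": int(rng.integers(0, 5)) for i in range(8)}
        out = propagate_isa_counts(raw, onto)
        assert all(out[t] >= raw[t] for t in raw)

    def test_cycle_pruned_with_report(self):
        onto = _ontology({"A": "a", "B": "b"}, edges=[("A", "B"), ("B", "A")])
        assert onto.pruned_edges == [("B", "A")]
        out = propagate_isa_counts({"A": 1}, onto)
        assert out["B"] == 1


class TestTfidf:
    def test_ubiquitous_feature_idf_is_one(self):
        counts = sp.csr_matrix(np.ones((4, 1)))
        vocab = fit_tfidf(counts, ["f"], TfidfConfig(min_feature_instances=0))
        # df = n: idf = ln((1+n)/(1+n)) + 1 = 1
        assert vocab.idf[0] == pytest.approx(1.0)

    def test_threshold_boundary(self):
        counts = sp.csr_matrix(np.array([[1, 1], [1, 0], [1, 0]]))
        vocab = fit_tfidf(counts, ["common", "rare"],
                          TfidfConfig(min_feature_instances=2))
        assert vocab.feature_names == ["common"]

    def test_empty_vocabulary_errors(self):
        counts = sp.csr_matrix(np.array([[1], [0]]))
        with pytest.raises(ValueError, match="threshold"):
            fit_tfidf(counts, ["f"], TfidfConfig(min_feature_instances=5))

    def test_closed_form_weights(self):
        counts = sp.csr_matrix(np.array([[1.0], [3.0], [0.0]]))
        vocab = fit_tfidf(counts, ["f"], TfidfConfig(min_feature_instances=0))
        W = transform_tfidf(counts, vocab, ["f"]).toarray()
        idf = np.log(4 / 3) + 1
        assert W[0, 0] == pytest.approx(idf)          # tf=1 -> idf
        assert W[1, 0] == pytest.approx((1 + np.log(3)) * idf)
        assert W[2, 0] == 0.0                          # tf=0 -> 0

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            counts = rng.poisson(0.8, size=(rng.integers(2, 12), rng.integers(1, 15)))
            if not counts.any():
                continue
            names = [f"f{j}" for j in range(counts.shape[1])]
            vocab = fit_tfidf(sp.csr_matrix(counts.astype(float)), names,
                              TfidfConfig(min_feature_instances=0))
            W = transform_tfidf(sp.csr_matrix(counts.astype(float)), vocab, names)
            np.testing.assert_allclose(W.toarray(), tfidf_oracle(counts), atol=1e-12)

    def test_matches_reference_vectorizer(self):
        """Cross-check against scikit-learn's smoothed sublinear tf-idf."""
        rng = np.random.default_rng(1)
        counts = rng.poisson(1.0, size=(8, 6)).astype(float)
        counts[:, 0] += 1  # ensure no all-zero column
        names = [f"f{j}" for j in range(6)]
        vocab = fit_tfidf(sp.csr_matrix(counts), names,
                          TfidfConfig(min_feature_instances=1))
        W = transform_tfidf(sp.csr_matrix(counts[:, [names.index(f) for f in vocab.feature_names]]),
                            vocab, vocab.feature_names).toarray()
        ref = TfidfTransformer(norm=None, smooth_idf=True, sublinear_tf=True)
        R = ref.fit_transform(sp.csr_matrix(counts[:, [names.index(f) for f in vocab.feature_names]])).toarray()
        np.testing.assert_allclose(W, R, atol=1e-10)

    def test_unseen_test_features_ignored(self):
        vocab = fit_tfidf(sp.csr_matrix(np.ones((2, 1))), ["known"],
                          TfidfConfig(min_feature_instances=0))
        W = transform_tfidf([{"unknown": 5, "known": 1}], vocab)
        assert W.shape == (1, 1)
        assert W[0, 0] == pytest.approx(vocab.idf[0])


class TestChi2Select:
    def test_aligned_feature_ranks_first(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        X = np.column_stack([y.astype(float), np.ones(6)])
        sel = chi2_select(sp.csr_matrix(X), y, ["aligned", "flat"], 1)
        assert sel == [0]

    def test_all_returned_when_few_candidates(self):
        y = np.array([1, 0, 1, 0])
        X = sp.csr_matrix(np.eye(4))
        sel = chi2_select(X, y, list("abcd"), 10)
        assert sorted(sel) == [0, 1, 2, 3]

    def test_constant_zero_feature_ranks_last(self):
        y = np.array([1, 1, 0, 0])
        X = np.column_stack([np.zeros(4), y.astype(float)])
        sel = chi2_select(sp.csr_matrix(X), y, ["zero", "signal"], 2)
        assert sel == [1, 0]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n, p = int(rng.integers(4, 16)), int(rng.integers(2, 10))
            X = rng.poisson(0.7, size=(n, p)).astype(float)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            names = [f"f{j}" for j in range(p)]
            sel = chi2_select(sp.csr_matrix(X), y, names, p)
            scores = chi2_scores_oracle(X, y)
            expected = sorted(range(p), key=lambda j: (-scores[j], names[j]))
            assert sel == expected

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(6)
        X = rng.poisson(1.0, size=(10, 6)).astype(float)
        y = np.array([1, 0] * 5)
        names = [f"f{j}" for j in range(6)]
        sel = chi2_select(sp.csr_matrix(X), y, names, 3)
        perm = rng.permutation(10)
        sel_p = chi2_select(sp.csr_matrix(X[perm]), y[perm], names, 3)
        assert sel == sel_p

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            chi2_select(sp.csr_matrix(np.ones((3, 2))), np.ones(3), ["a", "b"], 1)


def test_build_bow_counts_shared_and_disjoint():
    mats, names = build_bow_counts([{"shared": 2}, {"shared": 1, "own": 3}])
    assert names == ["own", "shared"]
    assert mats.toarray().tolist() == [[0, 2], [3, 1]]
    empty_row, _ = build_bow_counts([{}, {"x": 1}])
    assert empty_row.toarray()[0].sum() == 0


def test_training_only_vocabulary_no_leakage():
    train = [{"train_only": 5}]
    test = [{"test_only": 7, "train_only": 1}]
    counts, names = build_bow_counts(train)
    vocab = fit_tfidf(counts, names, TfidfConfig(min_feature_instances=0))
    assert "test_only" not in vocab.feature_names
    W = transform_tfidf(test, vocab)
    assert W.shape[1] == len(vocab.feature_names)
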