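"""Repeated, stratified five-fold cross-validation over the experiment grid.

One *cell* is a (corpus variant, feature space, classifier family)
combination; the default grid is 2 corpora x 2 spaces x 4 classifiers =
16 cells.  Under the default plan (100 iterations x 5 folds) each label
is fitted and predicted 8,000 times across the grid, yielding 500
performance estimates per label per cell.

Within every (iteration, fold) the vocabulary, idf weights, and
chi-square feature selection are fitted on the training documents only;
folds are shared across cells within an iteration so comparisons are
paired.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, fit as fit_clf, predict as predict_clf, tune
from .corpus_io import Document
from .feature_spaces import (
    Ontology,
    TfidfConfig,
    build_bow_counts,
    build_form_table,
    chi2_select,
    count_ontology_terms,
    fit_tfidf,
    propagate_isa_counts,
    transform_tfidf,
)
from .preprocess import PreprocessConfig, preprocess_text, preprocess_tokens

logger = logging.getLogger(__name__)

__all__ = ["CVPlan", "make_plan", "run_cell", "scheduled_executions",
           "CellResult"]


@dataclass
class CVPlan:
    """Fold assignments for every iteration, reproducible from the seed."""

    n_iterations: int
    n_folds: int
    seed: int
    doc_ids: list[str]
    # folds[iteration][fold] -> array of document row indices
    folds: list[list[np.ndarray]]

    def test_indices(self, iteration: int, fold: int) -> np.ndarray:
        return self.folds[iteration][fold]

    def train_indices(self, iteration: int, fold: int) -> np.ndarray:
        others = [
            self.folds[iteration][f]
            for f in range(self.n_folds)
            if f != fold
        ]
        return np.sort(np.concatenate(others))


def _iterative_stratification(
    Y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Iterative multi-label stratification with hard fold-size caps.

    Labels are processed from rarest to most frequent; each still
    unassigned document carrying the current label goes to the fold
    with the greatest remaining demand for that label, subject to the
    fold not being full.  Group sizes differ by at most one.
    """
    n_docs, n_labels = Y.shape
    base, extra = divmod(n_docs, n_folds)
    capacity = np.array([base + (1 if f < extra else 0) for f in range(n_folds)], float)
    # desired per-fold positives for each label, proportional to capacity
    desired = np.outer(Y.sum(axis=0), capacity / n_docs)  # labels x folds
    assignment = np.full(n_docs, -1, dtype=int)
    remaining = np.ones(n_docs, dtype=bool)

    label_order = np.argsort(Y.sum(axis=0), kind="stable")  # rarest first
    for lab in label_order:
        docs = np.flatnonzero(remaining & (Y[:, lab] > 0))
        docs = docs[rng.permutation(len(docs))]
        for d in docs:
            open_folds = np.flatnonzero(capacity > 0)
            # fold with greatest remaining demand for this label
            demand = desired[lab, open_folds]
            best = demand.max()
            cand = open_folds[demand >= best - 1e-12]
            if len(cand) > 1:
                cap = capacity[cand]
                cand = cand[cap >= cap.max() - 1e-12]
            f = int(cand[rng.integers(len(cand))]) if len(cand) > 1 else int(cand[0])
            assignment[d] = f
            remaining[d] = False
            capacity[f] -= 1
            desired[Y[d] > 0, f] -= 1
    # label-free documents fill remaining capacity
    for d in np.flatnonzero(remaining):
        open_folds = np.flatnonzero(capacity > 0)
        cap = capacity[open_folds]
        cand = open_folds[cap >= cap.max() - 1e-12]
        f = int(cand[rng.integers(len(cand))]) if len(cand) > 1 else int(cand[0])
        assignment[d] = f
        capacity[f] -= 1
    return [np.sort(np.flatnonzero(assignment == f)) for f in range(n_folds)]


def make_plan(
    doc_ids: Sequence[str],
    label_matrix: pd.DataFrame,
    n_iterations: int = 100,
    n_folds: int = 5,
    seed: int = 0,
) -> CVPlan:
    """Stratified repeated k-fold plan over the corpus.

    Stratification is iterative multi-label stratification so every
    label's positive rate per fold approximates its global rate.
    """
    if n_folds > len(doc_ids):
        raise ValueError(f"n_folds={n_folds} exceeds corpus size {len(doc_ids)}")
    if list(label_matrix.index) != list(doc_ids):
        label_matrix = label_matrix.reindex(list(doc_ids))
        if label_matrix.isna().any().any():
            raise ValueError("label matrix rows do not cover the corpus")
    Y = label_matrix.to_numpy()
    ss = np.random.SeedSequence(seed)
    folds = []
    for child in ss.spawn(n_iterations):
        rng = np.random.default_rng(child)
        folds.append(_iterative_stratification(Y, n_folds, rng))
    return CVPlan(
        n_iterations=n_iterations,
        n_folds=n_folds,
        seed=seed,
        doc_ids=list(doc_ids),
        folds=folds,
    )


def scheduled_executions(
    n_iterations: int = 100,
    n_folds: int = 5,
    n_corpora: int = 2,
    n_spaces: int = 2,
    n_classifiers: int = 4,
) -> dict[str, int]:
    """Dry-run enumeration of the experiment grid (no fitting).

    Returns the number of fit/predict executions scheduled per label
    across all cells, and the number of performance estimates per label
    per cell.
    """
    n_cells = n_corpora * n_spaces * n_classifiers
    per_cell = n_iterations * n_folds
    return {
        "n_cells": n_cells,
        "executions_per_label": n_cells * per_cell,
        "estimates_per_label_per_cell": per_cell,
    }


def _derived_seed(master: int, *coords: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=tuple(coords))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CellResult:
    """All predictions and per-run feature selections for one cell."""

    predictions: pd.DataFrame
    # (label, iteration, fold) -> list of selected feature names
    selections: dict[tuple[str, int, int], list[str]] = field(default_factory=dict)
    skipped: list[tuple[str, int, int]] = field(default_factory=list)
    chosen_params: dict[tuple[str, int, int], dict] = field(default_factory=dict)


def featurize_documents(
    documents: Sequence[Document],
    variant: str,
    space: str,
    preprocess_config: PreprocessConfig | None = None,
    ontology: Ontology | None = None,
    isa_mode: str = "per_edge",
) -> list[Counter]:
    """Per-document feature-count maps for one (corpus variant, space)."""
    if preprocess_config is None:
        preprocess_config = PreprocessConfig()
    out: list[Counter] = []
    if space == "bow":
        for doc in documents:
            out.append(preprocess_text(doc.text(variant), preprocess_config))
    elif space == "ontology":
        if ontology is None:
            raise ValueError("ontology space requires an ontology")
        form_table = build_form_table(ontology, preprocess_config)
        for doc in documents:
            tokens = preprocess_tokens(doc.text(variant), preprocess_config)
            raw = count_ontology_terms(tokens, ontology, form_table=form_table)
            out.append(propagate_isa_counts(raw, ontology, mode=isa_mode))
    else:
        raise ValueError(f"unknown feature space {space!r}")
    return out


def run_cell(
    documents: Sequence[Document],
    variant: str,
    space: str,
    classifier: ClassifierSpec,
    plan: CVPlan,
    label_matrix: pd.DataFrame,
    tfidf_config: TfidfConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
    ontology: Ontology | None = None,
    isa_mode: str = "per_edge",
    labels: Sequence[str] | None = None,
    doc_counts: Sequence[Mapping[str, int]] | None = None,
) -> CellResult:
    """Run one (corpus, feature space, classifier) cell over the plan.

    For each (iteration, fold): vocabulary + idf (+ chi-square
    selection, bag-of-words only) are fitted on training documents
    only, then each label is tuned, fitted and predicted on the test
    fold.  Folds whose training side lacks a positive (or negative)
    example for a label are skipped with a logged warning.
    """
    if tfidf_config is None:
        tfidf_config = TfidfConfig()
    if [d.doc_id for d in documents] != plan.doc_ids:
        raise ValueError("documents and plan are not aligned by doc_id")
    label_matrix = label_matrix.reindex(plan.doc_ids)
    if labels is None:
        labels = list(label_matrix.columns)
    Y = label_matrix[list(labels)].to_numpy()

    if doc_counts is None:
        doc_counts = featurize_documents(
            documents, variant, space, preprocess_config, ontology, isa_mode
        )

    rows: list[tuple] = []
    result = CellResult(predictions=pd.DataFrame())
    for it in range(plan.n_iterations):
        for fold in range(plan.n_folds):
            train_idx = plan.train_indices(it, fold)
            test_idx = plan.test_indices(it, fold)
            train_counts = [doc_counts[i] for i in train_idx]
            test_counts = [doc_counts[i] for i in test_idx]
            counts, names = build_bow_counts(train_counts)
            vocab = fit_tfidf(
                counts, names, tfidf_config,
                provenance={"iteration": it, "fold": fold, "variant": variant,
                            "space": space},
            )
            X_train = transform_tfidf(train_counts, vocab)
            X_test = transform_tfidf(test_counts, vocab)
            for li, label in enumerate(labels):
                y_train = Y[train_idx, li]
                y_test = Y[test_idx, li]
                classes = np.unique(y_train)
                if len(classes) < 2:
                    logger.warning(
                        "skipping degenerate fold: label=%s iteration=%d fold=%d",
                        label, it, fold,
                    )
                    result.skipped.append((label, it, fold))
                    continue
                if space == "bow" and X_train.shape[1] > tfidf_config.max_features:
                    sel = chi2_select(
                        X_train, y_train, vocab.feature_names,
                        tfidf_config.max_features,
                    )
                    Xtr, Xte = X_train[:, sel], X_test[:, sel]
                    result.selections[(label, it, fold)] = [
                        vocab.feature_names[j] for j in sel
                    ]
                else:
                    Xtr, Xte = X_train, X_test
                    result.selections[(label, it, fold)] = list(vocab.feature_names)
                seed = _derived_seed(plan.seed, it, fold, li)
                params = tune(classifier, Xtr, y_train, seed=seed)
                model = fit_clf(classifier, params, Xtr, y_train, seed=seed)
                y_pred = predict_clf(model, Xte)
                result.chosen_params[(label, it, fold)] = params
                for pos, doc_i in enumerate(test_idx):
                    rows.append(
                        (label, variant, space, classifier.family, it, fold,
                         plan.doc_ids[doc_i], int(y_test[pos]), int(y_pred[pos]))
                    )
    result.predictions = pd.DataFrame(
        rows,
        columns=["label", "corpus", "feature_space", "classifier",
                 "iteration", "fold", "doc_id", "y_true", "y_pred"],
    )
    return result
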