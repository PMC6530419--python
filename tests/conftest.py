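import numpy as np
import pandas as pd
import pytest

from autoannot.classifiers import ClassifierSpec
from autoannot.cv_engine import featurize_documents, make_plan, run_cell
from autoannot.feature_spaces import TfidfConfig
from autoannot.label_model import LabelSchema, collapse_to_article, filter_labels
from autoannot.preprocess import PreprocessConfig
from autoannot.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def pp_config():
    return PreprocessConfig()


@pytest.fixture(scope="session")
def toy_schema():
    return LabelSchema(
        dimensions=["BehavioralDomain", "ParadigmClass"],
        labels={
            "BehavioralDomain": {
                "Cognition",
                "Cognition.Memory",
                "Cognition.Memory.Working",
                "Emotion",
            },
            "ParadigmClass": {"WordGeneration", "WordGeneration.Covert"},
        },
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Small but non-trivial synthetic corpus shared across tests."""
    return generate(
        GeneratorConfig(n_docs=120, abstract_len=100, fulltext_len=500, seed=7)
    )


@pytest.fixture(scope="session")
def small_label_matrix(small_corpus):
    matrix = collapse_to_article(
        small_corpus.annotations,
        [d.doc_id for d in small_corpus.documents],
        small_corpus.schema,
    )
    filtered, _ = filter_labels(matrix, min_instances=15)
    return filtered


@pytest.fixture(scope="session")
def small_cell(small_corpus, small_label_matrix):
    """One fast logistic-regression cell on the small corpus."""
    docs = small_corpus.documents
    plan = make_plan([d.doc_id for d in docs], small_label_matrix,
                     n_iterations=2, n_folds=5, seed=11)
    counts = featurize_documents(docs, "fulltext", "bow")
    cell = run_cell(
        docs, "fulltext", "bow", ClassifierSpec("logreg"), plan,
        small_label_matrix,
        tfidf_config=TfidfConfig(min_feature_instances=15, max_features=400),
        doc_counts=counts,
    )
    return plan, counts, cell
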