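"""Synthetic labeled corpora with planted term-label associations.

Stands in for a manually annotated article collection: every pipeline
stage (preprocessing, both feature spaces, cross-validation, evaluation,
similarity clustering) can be exercised end to end without any
download.  Each label owns a disjoint pool of invented signal words; a
document's tokens are drawn from its labels' pools with probability
``theta`` (the planted signal strength) and from a Zipf-distributed
background vocabulary otherwise.  Full text is a superset-style
expansion of the abstract: same signal process, more tokens.  A toy
concept ontology mirrors the label hierarchy with is-a edges over the
signal vocabulary, and parenthetical abbreviation definitions plus
British spellings are injected so the normalization steps have work to
do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus_io import AnnotationRecord, Document
from .feature_spaces import Ontology, OntologyTerm
from .label_model import LabelSchema, expand_hierarchy

__all__ = ["GeneratorConfig", "SyntheticCorpus", "generate", "default_schema"]

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"


def default_schema() -> LabelSchema:
    """Two dimensions, seven labels, one three-level chain."""
    return LabelSchema(
        dimensions=["BehavioralDomain", "ParadigmClass"],
        labels={
            "BehavioralDomain": {
                "Cognition",
                "Cognition.Memory",
                "Cognition.Memory.Working",
                "Emotion",
            },
            "ParadigmClass": {
                "WordGeneration",
                "WordGeneration.Covert",
                "PainMonitor",
            },
        },
    )


def _default_prevalence() -> dict[tuple[str, str], float]:
    return {
        ("BehavioralDomain", "Cognition.Memory.Working"): 0.30,
        ("BehavioralDomain", "Cognition.Memory"): 0.15,
        ("BehavioralDomain", "Emotion"): 0.35,
        ("ParadigmClass", "WordGeneration.Covert"): 0.30,
        ("ParadigmClass", "PainMonitor"): 0.35,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    ``theta`` is the probability that a token slot draws from the
    document's label signal pools rather than the background; it
    monotonically controls how recoverable the planted associations
    are.  Default scale (400 documents, 150-token abstracts, 1500-token
    full texts) keeps an end-to-end run on one CPU in minutes.
    """

    n_docs: int = 400
    prevalence: Mapping[tuple[str, str], float] | None = None
    signal_vocab_size: int = 20
    background_vocab_size: int = 2000
    abstract_len: int = 150
    fulltext_len: int = 1500
    theta: float = 0.5
    abbrev_rate: float = 0.1
    british_rate: float = 0.1
    sibling_boost: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.signal_vocab_size < 1 or self.background_vocab_size < 10:
            raise ValueError("vocabulary sizes too small")
        prev = self.prevalence if self.prevalence is not None else _default_prevalence()
        for key, p in prev.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {key} must be in (0, 1)")


@dataclass
class SyntheticCorpus:
    """Generated corpus plus ground truth about the planted structure."""

    documents: list[Document]
    annotations: list[AnnotationRecord]
    schema: LabelSchema
    ontology: Ontology
    signal_pools: dict[tuple[str, str], list[str]]
    label_sets_raw: list[set[tuple[str, str]]]
    label_sets_expanded: list[set[tuple[str, str]]]
    config: GeneratorConfig = field(repr=False, default=None)


def _make_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))]
        + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def _make_vocab(rng: np.random.Generator, n_words: int, taken: set[str]) -> list[str]:
    words: list[str] = []
    attempts = 0
    while len(words) < n_words:
        w = _make_word(rng, int(rng.integers(3, 5)))
        attempts += 1
        if attempts > 100 * n_words + 1000:
            raise ValueError(
                f"cannot generate {n_words} unique words (pool exhausted)"
            )
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


_BRITISH_PAIRS = [
    ("behaviour", "behavior"),
    ("colour", "color"),
    ("analyse", "analyze"),
    ("centre", "center"),
    ("randomised", "randomized"),
]


def _zipf_probs(n: int) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    p = 1.0 / ranks
    return p / p.sum()


def generate(config: GeneratorConfig | None = None) -> SyntheticCorpus:
    """Generate a labeled corpus, its schema, a toy ontology, and truth.

    Label assignments are drawn per configured prevalence (with a
    sibling co-occurrence boost within a dimension, so label
    co-occurrence carries signal for the Dice residualization) and then
    closed under the hierarchy; the emitted annotation records are the
    closed sets, so hierarchical expansion is a no-op on them.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    schema = default_schema()
    prevalence = dict(
        config.prevalence if config.prevalence is not None else _default_prevalence()
    )
    for dim, lab in prevalence:
        if not schema.has(dim, lab):
            raise ValueError(f"prevalence names unknown label {dim}:{lab}")

    all_labels = [
        (dim, lab) for dim in schema.dimensions for lab in sorted(schema.labels[dim])
    ]
    taken: set[str] = set()
    signal_pools = {
        key: _make_vocab(rng, config.signal_vocab_size, taken) for key in all_labels
    }
    background = _make_vocab(rng, config.background_vocab_size, taken)
    bg_probs = _zipf_probs(len(background))

    # label assignment with sibling co-occurrence boost
    assignable = sorted(prevalence)
    raw_sets: list[set[tuple[str, str]]] = []
    for _ in range(config.n_docs):
        chosen: set[tuple[str, str]] = set()
        n_in_dim: dict[str, int] = {}
        for key in assignable:
            dim = key[0]
            p = prevalence[key] * (1.0 + config.sibling_boost * n_in_dim.get(dim, 0))
            if rng.random() < min(p, 0.95):
                chosen.add(key)
                n_in_dim[dim] = n_in_dim.get(dim, 0) + 1
        raw_sets.append(chosen)
    expanded_sets = [expand_hierarchy(s, schema) for s in raw_sets]

    def sample_tokens(n: int, labels: list[tuple[str, str]]) -> list[str]:
        out = []
        for _ in range(n):
            if labels and rng.random() < config.theta:
                pool = signal_pools[labels[rng.integers(len(labels))]]
                out.append(pool[int(rng.integers(len(pool)))])
            else:
                out.append(background[int(rng.choice(len(background), p=bg_probs))])
        return out

    documents: list[Document] = []
    annotations: list[AnnotationRecord] = []
    for i, expanded in enumerate(expanded_sets):
        doc_id = f"doc{i:04d}"
        labels = sorted(expanded)
        n_abs = max(10, int(rng.poisson(config.abstract_len)))
        n_full_extra = max(0, int(rng.poisson(config.fulltext_len)) - n_abs)
        abs_tokens = sample_tokens(n_abs, labels)
        extra_tokens = sample_tokens(n_full_extra, labels)

        # British spellings: some slots use the British variant
        for toks in (abs_tokens, extra_tokens):
            for j in range(len(toks)):
                if rng.random() < config.british_rate / 10:
                    brit, amer = _BRITISH_PAIRS[int(rng.integers(len(_BRITISH_PAIRS)))]
                    toks[j] = brit if rng.random() < 0.5 else amer

        # parenthetical abbreviation definition + later standalone uses
        if rng.random() < config.abbrev_rate and len(abs_tokens) > 10:
            w1 = abs_tokens[0]
            w2 = abs_tokens[1]
            abbrev = (w1[0] + w2[0]).upper()
            defn = f"{w1} {w2} ({abbrev})"
            body = abs_tokens[2:]
            n_uses = int(rng.integers(1, 4))
            for _ in range(n_uses):
                body.insert(int(rng.integers(len(body) + 1)), abbrev)
            abs_tokens = [defn] + body

        abstract = " ".join(abs_tokens) + "."
        fulltext = abstract + " " + " ".join(extra_tokens) + "." if extra_tokens else abstract
        documents.append(
            Document(doc_id=doc_id, abstract_text=abstract, fulltext_text=fulltext)
        )
        for dim, lab in labels:
            annotations.append(AnnotationRecord(doc_id, dim, lab))

    ontology = _toy_ontology(schema, signal_pools)
    return SyntheticCorpus(
        documents=documents,
        annotations=annotations,
        schema=schema,
        ontology=ontology,
        signal_pools=signal_pools,
        label_sets_raw=raw_sets,
        label_sets_expanded=expanded_sets,
        config=config,
    )


def _toy_ontology(
    schema: LabelSchema, signal_pools: dict[tuple[str, str], list[str]]
) -> Ontology:
    """Concept ontology over the signal vocabulary.

    Each label gets a head concept (named by the first word of its
    pool); the remaining pool words are concepts that are "is-a" the
    head, and child-label heads are "is-a" parent-label heads, so
    count propagation mirrors the label hierarchy.
    """
    terms: dict[str, OntologyTerm] = {}
    edges: list[tuple[str, str]] = []

    def head_id(dim: str, lab: str) -> str:
        return f"{dim}:{lab}#head"

    for (dim, lab), pool in sorted(signal_pools.items()):
        hid = head_id(dim, lab)
        terms[hid] = OntologyTerm(term_id=hid, name=pool[0], category="Concept")
        for j, word in enumerate(pool[1:], start=1):
            tid = f"{dim}:{lab}#w{j}"
            terms[tid] = OntologyTerm(term_id=tid, name=word, category="Concept")
            edges.append((tid, hid))
        parent = schema.parent(dim, lab)
        if parent is not None:
            edges.append((hid, head_id(dim, parent)))
    return Ontology(terms=terms, isa_edges=edges)
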