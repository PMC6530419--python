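"""The two feature spaces and the shared tf-idf vectorization.

Bag-of-words: data-driven stemmed 1-3-grams harvested from the training
documents.  Ontology: occurrence counts of controlled-vocabulary terms
(concepts/tasks/disorders with aliases), with each term's count
propagated up the is-a hierarchy before vectorization.

tf-idf uses sublinear term frequency (1 + ln tf) and add-one-smoothed
inverse document frequency, idf(df) = ln((1 + n) / (1 + df)) + 1, both
with natural logarithms and no row normalization.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_selection import chi2 as _sk_chi2

from .preprocess import PreprocessConfig, preprocess_tokens

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "TfidfConfig",
    "FittedVocabulary",
    "build_bow_counts",
    "generate_alternate_forms",
    "count_ontology_terms",
    "propagate_isa_counts",
    "fit_tfidf",
    "transform_tfidf",
    "chi2_select",
]


@dataclass
class OntologyTerm:
    term_id: str
    name: str
    category: str = "Concept"
    aliases: list[str] = field(default_factory=list)


@dataclass
class Ontology:
    """Concept ontology: terms with aliases and a Concept-Concept is-a DAG.

    Only is-a assertions between Concepts carry count propagation; any
    cycles in the input are broken by dropping the edge that closes the
    cycle (deterministic order), with a loud warning.
    """

    terms: dict[str, OntologyTerm]
    isa_edges: list[tuple[str, str]]  # (child, parent)
    pruned_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for child, parent in self.isa_edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"is-a edge endpoint missing: {child} -> {parent}")
        self._prune_cycles()

    def _prune_cycles(self) -> None:
        """Drop edges closing cycles, scanning edges in input order."""
        kept: list[tuple[str, str]] = []
        children: dict[str, list[str]] = {}

        def reaches(src: str, dst: str) -> bool:
            stack, seen = [src], set()
            while stack:
                cur = stack.pop()
                if cur == dst:
                    return True
                if cur in seen:
                    continue
                seen.add(cur)
                stack.extend(children.get(cur, ()))
            return False

        for child, parent in self.isa_edges:
            # edge child->parent closes a cycle iff parent already reaches child
            if reaches(parent, child):
                self.pruned_edges.append((child, parent))
                logger.warning(
                    "ontology: dropping cycle-closing is-a edge %s -> %s",
                    child, parent,
                )
            else:
                kept.append((child, parent))
                children.setdefault(child, []).append(parent)
        self.isa_edges = kept

    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    @classmethod
    def from_json(cls, path: str | Path) -> "Ontology":
        """Load ``[{id, name, category, aliases: [...], isa: [parent ids]}]``."""
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        terms: dict[str, OntologyTerm] = {}
        edges: list[tuple[str, str]] = []
        for entry in raw:
            term = OntologyTerm(
                term_id=entry["id"],
                name=entry["name"],
                category=entry.get("category", "Concept"),
                aliases=list(entry.get("aliases", [])),
            )
            if term.term_id in terms:
                raise ValueError(f"duplicate ontology term id {term.term_id!r}")
            terms[term.term_id] = term
        for entry in raw:
            for parent in entry.get("isa", []):
                edges.append((entry["id"], parent))
        return cls(terms=terms, isa_edges=edges)

    def to_json(self, path: str | Path) -> None:
        parents: dict[str, list[str]] = {}
        for child, parent in self.isa_edges:
            parents.setdefault(child, []).append(parent)
        raw = [
            {
                "id": t.term_id,
                "name": t.name,
                "category": t.category,
                "aliases": t.aliases,
                "isa": parents.get(t.term_id, []),
            }
            for t in (self.terms[k] for k in sorted(self.terms))
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(raw, fh, indent=1, ensure_ascii=False)


@dataclass(frozen=True)
class TfidfConfig:
    """Vectorization settings.

    ``min_feature_instances`` is a document-frequency floor (a feature
    must appear in at least that many training articles), mirroring the
    80-article label floor; set ``count_mode="total"`` to threshold on
    the summed raw count instead.  ``max_features`` caps the
    bag-of-words space via per-label chi-square selection.
    """

    min_feature_instances: int = 80
    max_features: int = 1754
    count_mode: str = "documents"  # or "total"

    def __post_init__(self) -> None:
        if self.min_feature_instances < 0:
            raise ValueError("min_feature_instances must be >= 0")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.count_mode not in ("documents", "total"):
            raise ValueError("count_mode must be 'documents' or 'total'")


@dataclass
class FittedVocabulary:
    """Ordered feature names with idf weights, fitted on training docs only."""

    feature_names: list[str]
    idf: np.ndarray
    document_frequency: np.ndarray
    n_docs: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValueError("feature names must be unique")
        if np.any(self.idf <= 0):
            raise ValueError("idf must be positive")

    @property
    def index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_names)}


def build_bow_counts(
    doc_counts: Sequence[Mapping[str, int]],
    feature_names: Sequence[str] | None = None,
) -> tuple[sp.csr_matrix, list[str]]:
    """Assemble per-document feature-count maps into a docs x features matrix.

    When ``feature_names`` is given (transform path) columns follow it
    and unseen features are ignored; otherwise columns are the sorted
    union of features over the documents.
    """
    if feature_names is None:
        names = sorted(set().union(*[set(c) for c in doc_counts]) if doc_counts else set())
    else:
        names = list(feature_names)
    index = {f: j for j, f in enumerate(names)}
    indptr, indices, data = [0], [], []
    for counts in doc_counts:
        for feat, cnt in counts.items():
            j = index.get(feat)
            if j is not None and cnt:
                indices.append(j)
                data.append(cnt)
        indptr.append(len(indices))
    mat = sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(len(doc_counts), len(names)),
    )
    mat.sum_duplicates()
    return mat, names


def generate_alternate_forms(
    term_name: str,
    aliases: Iterable[str] = (),
    config: PreprocessConfig | None = None,
) -> set[tuple[str, ...]]:
    """All stemmed surface forms of an ontology term.

    Variants: the name and every alias; hyphens removed (joined and
    space-separated); possessive apostrophes stripped; parenthetical
    statements moved to the front; slash-separated alternatives split.
    Each variant runs through the shared normalization pipeline so it
    matches the preprocessed token stream of a document.
    """
    if config is None:
        config = PreprocessConfig()
    surface: set[str] = set()
    queue = [term_name, *aliases]
    while queue:
        s = queue.pop()
        if not s or s in surface:
            continue
        surface.add(s)
        if "/" in s:
            queue.extend(part.strip() for part in s.split("/"))
        if "(" in s and ")" in s:
            inner = s[s.index("(") + 1 : s.index(")")].strip()
            outer = (s[: s.index("(")] + s[s.index(")") + 1 :]).strip()
            if inner and outer:
                queue.append(f"{inner} {outer}")
        if "-" in s:
            queue.append(s.replace("-", " "))
            queue.append(s.replace("-", ""))
        if "'s" in s:
            queue.append(s.replace("'s", ""))
        elif "'" in s:
            queue.append(s.replace("'", ""))
    forms: set[tuple[str, ...]] = set()
    for s in surface:
        stemmed = tuple(preprocess_tokens(s, config))
        if stemmed:
            forms.add(stemmed)
    return forms


def count_ontology_terms(
    tokens: Sequence[str],
    ontology: Ontology,
    config: PreprocessConfig | None = None,
    form_table: Mapping[tuple[str, ...], str] | None = None,
) -> Counter[str]:
    """Count non-overlapping occurrences of ontology terms in a stem stream.

    Greedy longest-match-first: at each position the longest matching
    surface form wins and consumes its tokens, so a multi-word term is
    never additionally counted as its single-word substring.  Ties
    between equally long forms of different terms resolve to the
    lexicographically smaller term id.
    """
    if form_table is None:
        form_table = build_form_table(ontology, config)
    if not form_table:
        return Counter()
    max_len = max(len(f) for f in form_table)
    counts: Counter[str] = Counter()
    i, n = 0, len(tokens)
    while i < n:
        matched = False
        for L in range(min(max_len, n - i), 0, -1):
            window = tuple(tokens[i : i + L])
            term = form_table.get(window)
            if term is not None:
                counts[term] += 1
                i += L
                matched = True
                break
        if not matched:
            i += 1
    return counts


def build_form_table(
    ontology: Ontology, config: PreprocessConfig | None = None
) -> dict[tuple[str, ...], str]:
    """Map every stemmed surface form to its term id (smallest id wins ties)."""
    table: dict[tuple[str, ...], str] = {}
    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        for form in generate_alternate_forms(term.name, term.aliases, config):
            if form not in table:
                table[form] = term_id
    return table


def propagate_isa_counts(
    counts: Mapping[str, int],
    ontology: Ontology,
    mode: str = "per_edge",
) -> Counter[str]:
    """Propagate term counts up the is-a hierarchy.

    ``per_edge`` (default): in reverse topological order, each term's
    final count is its own count plus the final counts of its is-a
    children, added once per edge (a diamond double-counts at the apex).
    ``per_descendant``: each term's *raw* count is added once to every
    ancestor, so shared descendants are not double-counted.
    """
    if mode not in ("per_edge", "per_descendant"):
        raise ValueError("mode must be 'per_edge' or 'per_descendant'")
    parents: dict[str, list[str]] = {}
    indeg: Counter[str] = Counter()
    for child, parent in ontology.isa_edges:
        parents.setdefault(child, []).append(parent)
        indeg[parent] += 1
    # Kahn topological order over the child->parent DAG
    order: list[str] = [t for t in sorted(ontology.terms) if indeg[t] == 0]
    head = 0
    while head < len(order):
        node = order[head]
        head += 1
        for parent in sorted(parents.get(node, ())):
            indeg[parent] -= 1
            if indeg[parent] == 0:
                order.append(parent)
    if len(order) != len(ontology.terms):
        cycle = sorted(set(ontology.terms) - set(order))
        raise ValueError(f"ontology contains a cycle among {cycle}")

    final: Counter[str] = Counter({t: counts.get(t, 0) for t in ontology.terms})
    if mode == "per_edge":
        for node in order:
            for parent in parents.get(node, ()):
                final[parent] += final[node]
    else:
        for node in order:
            raw = counts.get(node, 0)
            if raw == 0:
                continue
            seen: set[str] = set()
            stack = list(parents.get(node, ()))
            while stack:
                anc = stack.pop()
                if anc in seen:
                    continue
                seen.add(anc)
                final[anc] += raw
                stack.extend(parents.get(anc, ()))
    return final


def fit_tfidf(
    counts: sp.spmatrix,
    feature_names: Sequence[str],
    config: TfidfConfig | None = None,
    provenance: dict | None = None,
) -> FittedVocabulary:
    """Fit idf weights on training counts, dropping infrequent features."""
    if config is None:
        config = TfidfConfig()
    counts = sp.csr_matrix(counts)
    n_docs = counts.shape[0]
    df = np.asarray((counts > 0).sum(axis=0)).ravel()
    if config.count_mode == "documents":
        keep = df >= config.min_feature_instances
    else:
        total = np.asarray(counts.sum(axis=0)).ravel()
        keep = total >= config.min_feature_instances
    if not keep.any():
        raise ValueError(
            "no features pass the minimum-instance threshold "
            f"({config.min_feature_instances})"
        )
    kept_idx = np.flatnonzero(keep)
    kept_df = df[kept_idx]
    idf = np.log((1.0 + n_docs) / (1.0 + kept_df)) + 1.0
    return FittedVocabulary(
        feature_names=[feature_names[j] for j in kept_idx],
        idf=idf,
        document_frequency=kept_df.astype(np.int64),
        n_docs=n_docs,
        provenance=provenance or {},
    )


def transform_tfidf(
    doc_counts: Sequence[Mapping[str, int]] | sp.spmatrix,
    vocabulary: FittedVocabulary,
    feature_names: Sequence[str] | None = None,
) -> sp.csr_matrix:
    """Apply sublinear tf-idf under a fitted vocabulary.

    Accepts either per-document count maps or a count matrix with
    ``feature_names`` naming its columns; features outside the fitted
    vocabulary are ignored.  weight = (1 + ln tf) * idf for tf > 0.
    """
    if sp.issparse(doc_counts):
        if feature_names is None:
            raise ValueError("feature_names required with a count matrix")
        counts = sp.csr_matrix(doc_counts, dtype=np.float64)
        vocab_index = vocabulary.index
        cols = [vocab_index.get(f, -1) for f in feature_names]
        keep = [j for j, c in enumerate(cols) if c >= 0]
        sub = counts[:, keep]
        mapped = sp.csr_matrix(
            (sub.data, [cols[keep[j]] for j in sub.indices], sub.indptr),
            shape=(counts.shape[0], len(vocabulary.feature_names)),
        )
    else:
        mapped, _ = build_bow_counts(doc_counts, vocabulary.feature_names)
    mapped = sp.csr_matrix(mapped, dtype=np.float64)
    mapped.eliminate_zeros()
    mapped.data = 1.0 + np.log(mapped.data)
    mapped = mapped @ sp.diags(vocabulary.idf)
    return sp.csr_matrix(mapped)


def chi2_select(
    weights: sp.spmatrix,
    y: np.ndarray,
    feature_names: Sequence[str],
    k: int,
) -> list[int]:
    """Indices of the top-k features by chi-square dependence on ``y``.

    Ranked by descending statistic; ties (including all-zero features,
    whose statistic is 0) break on ascending feature name.  When there
    are at most ``k`` candidates all are returned, still ranked.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("chi2_select needs both classes present in y")
    stats, _ = _sk_chi2(sp.csr_matrix(weights), y)
    stats = np.nan_to_num(stats, nan=0.0)
    order = sorted(range(len(feature_names)), key=lambda j: (-stats[j], feature_names[j]))
    return order[: min(k, len(order))]
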