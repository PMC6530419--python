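"""Dimensioned, partially hierarchical label schema and label matrices.

Labels live in named dimensions (Behavioral Domain, Paradigm Class, ...)
and may be hierarchical, encoded as dot-delimited paths
(``Cognition.Memory.Working``) or via explicit parent edges for
non-path variants.  Internally labels are dimension-qualified
(``BehavioralDomain:Cognition.Memory``) so identical names in different
dimensions cannot collide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus_io import AnnotationRecord

__all__ = [
    "LabelSchema",
    "MultiLabelStats",
    "qualify",
    "collapse_to_article",
    "expand_hierarchy",
    "filter_labels",
    "multilabel_stats",
]

QUALIFIER = ":"


def qualify(dimension: str, label: str) -> str:
    return f"{dimension}{QUALIFIER}{label}"


def split_qualified(qlabel: str) -> tuple[str, str]:
    dimension, _, label = qlabel.partition(QUALIFIER)
    return dimension, label


@dataclass
class LabelSchema:
    """Label vocabulary: ordered dimensions, labels, and parent relation.

    ``explicit_parents`` maps (dimension, label) -> parent label for
    hierarchies that are not encoded in the dot path (e.g. task
    variants like "Covert Word Generation" under "Word Generation").
    """

    dimensions: list[str]
    labels: dict[str, set[str]]
    explicit_parents: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dim in self.dimensions:
            self.labels.setdefault(dim, set())
        for (dim, label), parent in self.explicit_parents.items():
            if dim not in self.labels or label not in self.labels[dim]:
                raise ValueError(f"explicit parent for unknown label {dim}:{label}")
            if parent not in self.labels[dim]:
                raise ValueError(
                    f"parent {parent!r} of {dim}:{label} not in schema"
                )
        # dot-path parents must exist (schema is closed under the hierarchy)
        for dim, labs in self.labels.items():
            for lab in labs:
                parent = self.parent(dim, lab)
                if parent is not None and parent not in labs:
                    raise ValueError(
                        f"label {dim}:{lab} has parent {parent!r} missing from schema"
                    )

    def parent(self, dimension: str, label: str) -> str | None:
        """Parent label within the dimension, or None for roots."""
        if (dimension, label) in self.explicit_parents:
            return self.explicit_parents[(dimension, label)]
        if "." in label:
            return label.rsplit(".", 1)[0]
        return None

    def ancestors(self, dimension: str, label: str) -> list[str]:
        out = []
        cur = self.parent(dimension, label)
        while cur is not None:
            out.append(cur)
            cur = self.parent(dimension, cur)
        return out

    def has(self, dimension: str, label: str) -> bool:
        return dimension in self.labels and label in self.labels[dimension]

    def all_qualified(self) -> list[str]:
        out = []
        for dim in self.dimensions:
            out.extend(qualify(dim, lab) for lab in sorted(self.labels[dim]))
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelSchema":
        """Load ``{dimension: [{"label": ..., "parent": ...?}, ...]}``."""
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        dimensions = list(raw)
        labels: dict[str, set[str]] = {}
        parents: dict[tuple[str, str], str] = {}
        for dim, entries in raw.items():
            labels[dim] = set()
            for entry in entries:
                if isinstance(entry, str):
                    entry = {"label": entry}
                labels[dim].add(entry["label"])
                if entry.get("parent"):
                    parents[(dim, entry["label"])] = entry["parent"]
        return cls(dimensions=dimensions, labels=labels, explicit_parents=parents)

    def to_json(self, path: str | Path) -> None:
        raw = {
            dim: [
                {"label": lab, **(
                    {"parent": self.explicit_parents[(dim, lab)]}
                    if (dim, lab) in self.explicit_parents
                    else {}
                )}
                for lab in sorted(self.labels[dim])
            ]
            for dim in self.dimensions
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(raw, fh, indent=1, ensure_ascii=False)


@dataclass(frozen=True)
class MultiLabelStats:
    """Label-cardinality and label-set-proportion summaries.

    ``lc_avg`` is the mean number of labels per article; ``p_uniq`` the
    proportion of articles with a unique label combination; ``p_min``
    (``p_max``) the proportion of articles carrying exactly the
    minimum (maximum) number of labels.  Proportions are raw fractions
    in [0, 1]; presentation layers may scale to percent.
    """

    lc_avg: float
    lc_min: int
    lc_max: int
    p_uniq: float
    p_min: float
    p_max: float


def expand_hierarchy(
    label_set: Iterable[tuple[str, str]], schema: LabelSchema
) -> set[tuple[str, str]]:
    """Close a set of (dimension, label) pairs under the parent relation.

    Monotone and idempotent; a root label set is a fixed point.
    """
    out: set[tuple[str, str]] = set()
    for dim, lab in label_set:
        out.add((dim, lab))
        for anc in schema.ancestors(dim, lab):
            out.add((dim, anc))
    return out


def collapse_to_article(
    records: Iterable[AnnotationRecord],
    doc_ids: Sequence[str],
    schema: LabelSchema,
    expand: bool = True,
) -> pd.DataFrame:
    """Binary article x label matrix from per-contrast annotation records.

    All records for one article collapse to the union of their labels;
    with ``expand`` (the default) the union is then closed under the
    label hierarchy.  Rows follow ``doc_ids`` (articles without records
    get all-zero rows); columns are dimension-qualified, ordered by
    dimension then name.
    """
    per_doc: dict[str, set[tuple[str, str]]] = {d: set() for d in doc_ids}
    for rec in records:
        if not schema.has(rec.dimension, rec.label):
            raise ValueError(
                f"annotation {rec.doc_id!r} references unknown label "
                f"{rec.dimension}:{rec.label}"
            )
        if rec.doc_id in per_doc:
            per_doc[rec.doc_id].add((rec.dimension, rec.label))
    if expand:
        per_doc = {d: expand_hierarchy(s, schema) for d, s in per_doc.items()}
    columns = schema.all_qualified()
    col_index = {c: j for j, c in enumerate(columns)}
    values = np.zeros((len(doc_ids), len(columns)), dtype=np.int8)
    for i, doc in enumerate(doc_ids):
        for dim, lab in per_doc[doc]:
            values[i, col_index[qualify(dim, lab)]] = 1
    return pd.DataFrame(values, index=list(doc_ids), columns=columns)


def filter_labels(
    matrix: pd.DataFrame, min_instances: int = 80
) -> tuple[pd.DataFrame, list[str]]:
    """Drop label columns appearing in fewer than ``min_instances`` articles.

    Returns the filtered matrix (rows untouched, even if all-zero) and
    the names of the dropped columns.
    """
    sums = matrix.sum(axis=0)
    keep = sums >= min_instances
    dropped = [c for c, k in zip(matrix.columns, keep) if not k]
    return matrix.loc[:, keep], dropped


def multilabel_stats(
    matrix: pd.DataFrame, dimension: str | None = None
) -> MultiLabelStats:
    """Descriptive multi-label statistics over all or one dimension."""
    if matrix.shape[0] == 0:
        raise ValueError("multilabel_stats: empty label matrix")
    if dimension is not None:
        cols = [c for c in matrix.columns if split_qualified(c)[0] == dimension]
        if not cols:
            raise ValueError(f"no labels for dimension {dimension!r}")
        matrix = matrix[cols]
    row_sums = matrix.to_numpy().sum(axis=1)
    n = len(row_sums)
    lc_min = int(row_sums.min())
    lc_max = int(row_sums.max())
    row_sets = {
        tuple(np.flatnonzero(matrix.iloc[i].to_numpy())): 0 for i in range(n)
    }
    for i in range(n):
        row_sets[tuple(np.flatnonzero(matrix.iloc[i].to_numpy()))] += 1
    n_unique_sets = len(row_sets)
    return MultiLabelStats(
        lc_avg=float(row_sums.mean()),
        lc_min=lc_min,
        lc_max=lc_max,
        p_uniq=n_unique_sets / n,
        p_min=float((row_sums == lc_min).mean()),
        p_max=float((row_sums == lc_max).mean()),
    )


def stats_report(matrix: pd.DataFrame, schema: LabelSchema) -> pd.DataFrame:
    """Per-dimension + overall stats table (one column per dimension)."""
    cols: dict[str, MultiLabelStats] = {}
    for dim in schema.dimensions:
        if any(split_qualified(c)[0] == dim for c in matrix.columns):
            cols[dim] = multilabel_stats(matrix, dim)
    cols["Overall"] = multilabel_stats(matrix)
    rows = ["LC_avg", "LC_min", "LC_max", "P_uniq", "P_min", "P_max"]
    data = {
        name: [s.lc_avg, s.lc_min, s.lc_max, s.p_uniq, s.p_min, s.p_max]
        for name, s in cols.items()
    }
    return pd.DataFrame(data, index=rows)
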