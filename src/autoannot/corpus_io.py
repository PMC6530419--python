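"""Readers and writers for corpora, annotations and result artifacts.

All artifacts are plain text: JSON Lines for corpora, CSV for tables and
matrices, Newick + JSON for dendrograms.  Every writer/reader pair
round-trips exactly (floats at repr precision), and readers never drop
records silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "AnnotationRecord",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "read_annotations",
    "write_annotations",
    "write_matrix",
    "read_matrix",
    "write_predictions",
    "read_predictions",
]


class CorpusError(ValueError):
    """Malformed or inconsistent input artifact."""


@dataclass
class Document:
    """One article, with abstract and (optionally) full text."""

    doc_id: str
    abstract_text: str = ""
    fulltext_text: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")
        if not self.abstract_text and not self.fulltext_text:
            raise CorpusError(
                f"document {self.doc_id!r}: abstract and full text both empty"
            )

    def text(self, variant: str) -> str:
        if variant == "abstract":
            return self.abstract_text
        if variant == "fulltext":
            return self.fulltext_text or self.abstract_text
        raise ValueError(f"unknown corpus variant {variant!r}")


@dataclass(frozen=True, order=True)
class AnnotationRecord:
    """One (article, dimension, label) assignment.

    Hierarchical labels use dot-delimited paths, e.g.
    ``Cognition.Memory.Working``.
    """

    doc_id: str
    dimension: str
    label: str


def read_corpus(path: str | Path) -> list[Document]:
    """Read a JSON Lines corpus (one article per line).

    Keys: ``doc_id`` (required), ``abstract``, ``fulltext``, ``metadata``.
    Duplicate ids and malformed lines are hard errors.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            if not isinstance(rec, dict) or "doc_id" not in rec:
                raise CorpusError(f"{path}: line {lineno}: missing 'doc_id'")
            doc_id = str(rec["doc_id"])
            if doc_id in seen:
                raise CorpusError(f"{path}: line {lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(
                Document(
                    doc_id=doc_id,
                    abstract_text=rec.get("abstract", ""),
                    fulltext_text=rec.get("fulltext", ""),
                    metadata=rec.get("metadata", {}),
                )
            )
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "abstract": doc.abstract_text,
                        "fulltext": doc.fulltext_text,
                        "metadata": doc.metadata,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_annotations(
    path: str | Path, known_dimensions: Sequence[str] | None = None
) -> list[AnnotationRecord]:
    """Read a 3-column annotation CSV (doc_id, dimension, label).

    Duplicate rows collapse to one (the number dropped is logged).  Rows
    referencing a dimension outside ``known_dimensions`` (when given)
    are collected and reported in one error.
    """
    records: list[AnnotationRecord] = []
    seen: set[AnnotationRecord] = set()
    bad_rows: list[int] = []
    n_dupes = 0
    import csv as _csv

    with open(path, encoding="utf-8", newline="") as fh:
        reader = _csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return []
        if len(header) != 3:
            raise CorpusError(f"{path}: expected 3-column header, got {len(header)}")
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise CorpusError(
                    f"{path}: row {rowno}: expected 3 columns, got {len(row)}"
                )
            rec = AnnotationRecord(*[c.strip() for c in row])
            if known_dimensions is not None and rec.dimension not in known_dimensions:
                bad_rows.append(rowno)
                continue
            if rec in seen:
                n_dupes += 1
                continue
            seen.add(rec)
            records.append(rec)
    if bad_rows:
        raise CorpusError(
            f"{path}: rows referencing unknown dimensions: {bad_rows}"
        )
    if n_dupes:
        logger.info("read_annotations: dropped %d duplicate rows from %s", n_dupes, path)
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    import csv as _csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["doc_id", "dimension", "label"])
        for rec in records:
            writer.writerow([rec.doc_id, rec.dimension, rec.label])


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a named 2-D table as CSV; round-trips bit-identically.

    Floats serialize at repr precision; NaN round-trips as the literal
    ``NaN`` sentinel.
    """
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise CorpusError("matrix row/column names must be unique")
    matrix.to_csv(path, float_format=None, na_rep="NaN")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, na_values=["NaN"], keep_default_na=False)
    df.index = df.index.astype(str)
    return df


_PRED_COLUMNS = [
    "label",
    "corpus",
    "feature_space",
    "classifier",
    "iteration",
    "fold",
    "doc_id",
    "y_true",
    "y_pred",
]


def write_predictions(frame: pd.DataFrame, path: str | Path) -> None:
    """Write per-(doc,label,cell,iteration,fold) predictions as CSV."""
    missing = [c for c in _PRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CorpusError(f"prediction frame missing columns: {missing}")
    frame.to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _PRED_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusError(f"{path}: prediction file missing columns: {missing}")
    return df
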