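"""Macro/Micro F1, baseline pseudo-prediction, hierarchical precision/recall.

Conventions: F1 = 0 (flagged) whenever precision + recall = 0; macro F1
averages per-label F1 without frequency weighting; micro F1 pools
confusion counts across a dimension's labels first.  The baseline
"classifier" assigns every article the dimension's most frequent
labels, as many as the rounded average label cardinality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .label_model import LabelSchema, split_qualified

__all__ = [
    "ConfusionCounts",
    "HierScore",
    "f1_from_counts",
    "macro_f1",
    "micro_f1",
    "dimension_macro",
    "baseline_f1",
    "hierarchical_pr",
    "hierarchical_pr_from_records",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class HierScore:
    """Hierarchical precision/recall after ancestor augmentation."""

    h_precision: float
    h_recall: float


def f1_from_counts(counts: ConfusionCounts) -> tuple[float, float, float, bool]:
    """(precision, recall, F1, degenerate_flag).

    precision = tp/(tp+fp), recall = tp/(tp+fn),
    F1 = 2*p*r/(p+r); zero denominators yield 0 with the flag set.
    """
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        return precision, recall, 0.0, True
    return precision, recall, 2 * precision * recall / (precision + recall), degenerate


def _confusion(group: pd.DataFrame) -> ConfusionCounts:
    yt = group["y_true"].to_numpy()
    yp = group["y_pred"].to_numpy()
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
    )


def macro_f1(records: pd.DataFrame, per_fold: bool = False) -> pd.DataFrame:
    """Per-label, per-iteration F1 with folds pooled (default).

    With ``per_fold`` the score is computed per (iteration, fold)
    instead of pooling an iteration's folds.  Returns a tidy frame
    with columns label, iteration, (fold,) precision, recall, f1.
    """
    keys = ["label", "iteration"] + (["fold"] if per_fold else [])
    rows = []
    for key, group in records.groupby(keys, sort=True):
        p, r, f1, _ = f1_from_counts(_confusion(group))
        rows.append((*key, p, r, f1))
    return pd.DataFrame(rows, columns=keys + ["precision", "recall", "f1"])


def dimension_macro(per_label: pd.DataFrame, dimension: str | None = None) -> pd.DataFrame:
    """Unweighted mean of per-label F1 within a dimension, per iteration."""
    df = per_label.copy()
    df["dimension"] = [split_qualified(l)[0] for l in df["label"]]
    if dimension is not None:
        df = df[df["dimension"] == dimension]
        if df.empty:
            raise ValueError(f"no records for dimension {dimension!r}")
    return (
        df.groupby(["dimension", "iteration"], sort=True)["f1"]
        .mean()
        .reset_index()
    )


def micro_f1(records: pd.DataFrame, dimension: str | None = None) -> pd.DataFrame:
    """Micro F1 per dimension per iteration: counts pooled over labels."""
    if records.empty:
        raise ValueError("micro_f1: no prediction records")
    df = records.copy()
    df["dimension"] = [split_qualified(l)[0] for l in df["label"]]
    if dimension is not None:
        df = df[df["dimension"] == dimension]
        if df.empty:
            raise ValueError(f"no records for dimension {dimension!r}")
    rows = []
    for (dim, it), group in df.groupby(["dimension", "iteration"], sort=True):
        p, r, f1, _ = f1_from_counts(_confusion(group))
        rows.append((dim, it, p, r, f1))
    return pd.DataFrame(rows, columns=["dimension", "iteration", "precision", "recall", "f1"])


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def baseline_f1(
    label_matrix: pd.DataFrame, dimension: str
) -> tuple[pd.Series, float]:
    """Pseudo-prediction baseline for one dimension.

    Predicts, for every article, the dimension's m most frequent labels
    where m = round(LC_avg) (half away from zero); returns per-label F1
    and their unweighted (macro) mean.
    """
    cols = [c for c in label_matrix.columns if split_qualified(c)[0] == dimension]
    if not cols:
        raise ValueError(f"no labels for dimension {dimension!r}")
    sub = label_matrix[cols]
    lc_avg = float(sub.to_numpy().sum(axis=1).mean())
    m = _round_half_away(lc_avg)
    # most frequent labels; ties break on name for determinism
    freq = sub.sum(axis=0)
    ranked = sorted(cols, key=lambda c: (-freq[c], c))
    predicted = set(ranked[:m])
    n = len(sub)
    scores = {}
    for c in cols:
        pos = int(freq[c])
        if c in predicted:
            counts = ConfusionCounts(tp=pos, fp=n - pos, fn=0, tn=0)
        else:
            counts = ConfusionCounts(tp=0, fp=0, fn=pos, tn=n - pos)
        scores[c] = f1_from_counts(counts)[2]
    per_label = pd.Series(scores)
    return per_label, float(per_label.mean())


def _augment(labels: Iterable[str], schema: LabelSchema, dimension: str) -> frozenset[str]:
    out: set[str] = set()
    for lab in labels:
        out.add(lab)
        out.update(schema.ancestors(dimension, lab))
    return frozenset(out)


def hierarchical_pr(
    predicted_sets: Sequence[Iterable[str]],
    true_sets: Sequence[Iterable[str]],
    schema: LabelSchema,
    dimension: str,
) -> HierScore:
    """Ancestor-augmented set precision/recall, averaged over documents.

    Both the predicted and the true label set of each document are
    closed under the hierarchy before computing
    hP = |aug(pred) & aug(true)| / |aug(pred)| and
    hR = |aug(pred) & aug(true)| / |aug(true)|.  Empty augmented sets
    contribute 0.  For a flat hierarchy this is ordinary set
    precision/recall.
    """
    if len(predicted_sets) != len(true_sets):
        raise ValueError("predicted and true collections differ in length")
    hps, hrs = [], []
    for pred, true in zip(predicted_sets, true_sets):
        ap = _augment(pred, schema, dimension)
        at = _augment(true, schema, dimension)
        inter = len(ap & at)
        hps.append(inter / len(ap) if ap else 0.0)
        hrs.append(inter / len(at) if at else 0.0)
    if not hps:
        return HierScore(0.0, 0.0)
    return HierScore(float(np.mean(hps)), float(np.mean(hrs)))


def hierarchical_pr_from_records(
    records: pd.DataFrame, schema: LabelSchema, dimension: str
) -> HierScore:
    """Per-iteration hierarchical P/R from prediction records, averaged.

    Uses only labels of ``dimension``; per iteration each document's
    predicted and true label sets are assembled from the records, and
    the per-iteration scores are averaged.
    """
    df = records[[split_qualified(l)[0] == dimension for l in records["label"]]].copy()
    if df.empty:
        raise ValueError(f"no records for dimension {dimension!r}")
    df["plain"] = [split_qualified(l)[1] for l in df["label"]]
    per_iter: list[HierScore] = []
    for _, group in df.groupby("iteration", sort=True):
        preds: dict[str, set[str]] = {}
        trues: dict[str, set[str]] = {}
        for doc_id, sub in group.groupby("doc_id", sort=True):
            preds[doc_id] = set(sub.loc[sub["y_pred"] == 1, "plain"])
            trues[doc_id] = set(sub.loc[sub["y_true"] == 1, "plain"])
        docs = sorted(preds)
        per_iter.append(
            hierarchical_pr(
                [preds[d] for d in docs], [trues[d] for d in docs], schema, dimension
            )
        )
    return HierScore(
        float(np.mean([s.h_precision for s in per_iter])),
        float(np.mean([s.h_recall for s in per_iter])),
    )
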