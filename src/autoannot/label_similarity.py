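"""Label-feature-similarity analysis.

How similar is the vocabulary the classifiers lean on for different
labels?  For each label we form its feature selection-frequency
distribution across (iteration, fold) runs, correlate distributions
between labels (Spearman, over the union feature set with 0 for
never-selected features), regress out label co-occurrence (Dice index)
by OLS, and cluster the residual similarity matrix with WPGMA
("weighted") linkage on correlation-style distance 1 - similarity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy import stats
from scipy.stats import spearmanr

__all__ = [
    "selection_frequency",
    "selection_table",
    "spearman_matrix",
    "dice_matrix",
    "residualize",
    "cluster_labels",
    "cut_clusters",
    "to_newick",
    "wordcloud_export",
    "ClusterTree",
]


def selection_frequency(
    selections: Mapping[tuple[str, int, int], Sequence[str]], label: str
) -> pd.Series:
    """Mean selection frequency of each feature over a label's runs.

    A feature selected in every (iteration, fold) run scores 1.0;
    features never selected are simply absent (they enter pairwise
    alignment as 0).
    """
    runs = [feats for (lab, _, _), feats in selections.items() if lab == label]
    if not runs:
        raise ValueError(f"no selection runs for label {label!r}")
    counts: dict[str, int] = {}
    for feats in runs:
        for f in set(feats):
            counts[f] = counts.get(f, 0) + 1
    n = len(runs)
    return pd.Series({f: c / n for f, c in sorted(counts.items())}, dtype=float)


def selection_table(
    selections: Mapping[tuple[str, int, int], Sequence[str]]
) -> pd.DataFrame:
    """Labels x features table of selection frequencies (0 = never selected)."""
    labels = sorted({lab for lab, _, _ in selections})
    series = {lab: selection_frequency(selections, lab) for lab in labels}
    table = pd.DataFrame(series).T.fillna(0.0)
    return table.reindex(sorted(table.columns), axis=1)


def spearman_matrix(distributions: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho between label feature distributions.

    Rows of ``distributions`` are labels over the union feature set
    (absent features = 0); ties get average ranks.
    """
    labels = list(distributions.index)
    k = len(labels)
    rho = np.ones((k, k))
    X = distributions.to_numpy()
    if k > 1:
        import warnings

        with warnings.catch_warnings():
            # constant distributions get rho = 0 by convention
            warnings.simplefilter("ignore", category=stats.ConstantInputWarning)
            res = spearmanr(X.T)
        mat = np.atleast_2d(res.statistic) if k > 2 else np.array(
            [[1.0, float(res.statistic)], [float(res.statistic), 1.0]]
        )
        rho = np.asarray(mat, dtype=float)
        rho = np.nan_to_num(rho, nan=0.0)  # constant distributions
        np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=labels, columns=labels)


def dice_matrix(label_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Dice co-occurrence of labels over documents.

    Dice(X, Y) = 2 |docs(X) & docs(Y)| / (|docs(X)| + |docs(Y)|);
    two empty labels get 0 off-diagonal, 1 on the diagonal.
    """
    Y = label_matrix.to_numpy().astype(float)
    inter = Y.T @ Y
    sizes = Y.sum(axis=0)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        dice = np.where(denom > 0, 2 * inter / denom, 0.0)
    np.fill_diagonal(dice, 1.0)
    return pd.DataFrame(dice, index=label_matrix.columns, columns=label_matrix.columns)


def residualize(rho: pd.DataFrame, dice: pd.DataFrame) -> pd.DataFrame:
    """Regress label co-occurrence out of the correlation structure.

    Off-diagonal (upper triangle) rho values are regressed on the
    corresponding Dice values by OLS with intercept; residuals are
    refilled symmetrically and the diagonal is set to the maximal
    residual similarity.  A zero-variance Dice regressor degenerates to
    centering: slope 0, residuals = rho - mean(rho).
    """
    if list(rho.index) != list(dice.index):
        raise ValueError("rho and dice matrices must share label order")
    k = len(rho)
    iu = np.triu_indices(k, 1)
    r = rho.to_numpy()[iu]
    d = dice.to_numpy()[iu]
    if len(r) == 0:
        out = rho.copy()
        return out
    if np.ptp(d) < 1e-15:
        resid = r - r.mean()
    else:
        A = np.column_stack([np.ones_like(d), d])
        coef, *_ = np.linalg.lstsq(A, r, rcond=None)
        resid = r - A @ coef
    out = np.zeros((k, k))
    out[iu] = resid
    out = out + out.T
    np.fill_diagonal(out, resid.max() if len(resid) else 1.0)
    return pd.DataFrame(out, index=rho.index, columns=rho.columns)


@dataclass
class ClusterTree:
    """WPGMA dendrogram over labels (scipy linkage encoding).

    Weighted linkage can produce inversions (non-monotone merge
    heights); heights are recorded as computed.
    """

    labels: list[str]
    linkage: np.ndarray


def cluster_labels(similarity: pd.DataFrame) -> ClusterTree:
    """WPGMA clustering of labels on distance = 1 - similarity.

    Labels are processed in sorted name order so equal-distance merges
    break ties deterministically by label name.
    """
    labels = sorted(similarity.index)
    sim = similarity.loc[labels, labels].to_numpy().astype(float)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    if len(labels) == 1:
        return ClusterTree(labels=labels, linkage=np.empty((0, 4)))
    Z = sch.linkage(squareform(dist, checks=False), method="weighted")
    return ClusterTree(labels=labels, linkage=Z)


def cut_clusters(tree: ClusterTree, n_clusters: int) -> dict[str, int]:
    """Label -> cluster id (1..n_clusters) at a flat cut of the tree."""
    if len(tree.labels) == 1:
        return {tree.labels[0]: 1}
    assign = sch.fcluster(tree.linkage, t=n_clusters, criterion="maxclust")
    return dict(zip(tree.labels, (int(a) for a in assign)))


def to_newick(tree: ClusterTree) -> str:
    """Dendrogram as a Newick string with branch lengths."""
    n = len(tree.labels)
    if n == 1:
        return f"{tree.labels[0]};"
    heights = {i: 0.0 for i in range(n)}

    def name(i: int) -> str:
        return tree.labels[i].replace(" ", "_").replace(",", "").replace(":", "|")

    subtrees = {i: name(i) for i in range(n)}
    for row_idx, (a, b, h, _) in enumerate(tree.linkage):
        a, b = int(a), int(b)
        node = n + row_idx
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        subtrees[node] = f"({subtrees[a]}:{la:.10g},{subtrees[b]}:{lb:.10g})"
        heights[node] = h
    return subtrees[2 * n - 2] + ";"


def save_tree(tree: ClusterTree, newick_path: str | Path, linkage_path: str | Path) -> None:
    Path(newick_path).write_text(to_newick(tree) + "\n", encoding="utf-8")
    payload = {
        "labels": tree.labels,
        "linkage": [[float(x) for x in row] for row in tree.linkage],
        "method": "weighted",
        "distance": "1 - residual similarity",
    }
    Path(linkage_path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def wordcloud_export(
    cluster_members: Sequence[str],
    selections: Mapping[tuple[str, int, int], Sequence[str]],
    top_fraction: float = 0.1,
) -> pd.Series:
    """Ranked term weights for one cluster's word cloud.

    Weight = mean selection frequency of the feature across the
    cluster's labels; the top ceil(fraction * n_features) terms are
    returned, descending by weight with name tie-break.
    """
    if not cluster_members:
        raise ValueError("cluster has no members")
    table = selection_table(
        {k: v for k, v in selections.items() if k[0] in set(cluster_members)}
    )
    means = table.mean(axis=0)
    n_keep = math.ceil(top_fraction * len(means))
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))[:n_keep]
    return pd.Series(dict(ranked), dtype=float)
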