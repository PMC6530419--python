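"""Independent brute-force oracles (explicit loops, no shared code paths).

Each function recomputes a pipeline quantity from first principles so
the implementation can be checked against it on small random instances.
"""

import math

import numpy as np


def tfidf_oracle(counts: np.ndarray) -> np.ndarray:
    """Sublinear tf-idf with add-one-smoothed idf, cell by cell."""
    n_docs, n_feats = counts.shape
    out = np.zeros_like(counts, dtype=float)
    for j in range(n_feats):
        df = 0
        for i in range(n_docs):
            if counts[i, j] > 0:
                df += 1
        idf = math.log((1 + n_docs) / (1 + df)) + 1.0
        for i in range(n_docs):
            tf = counts[i, j]
            out[i, j] = 0.0 if tf == 0 else (1.0 + math.log(tf)) * idf
    return out


def chi2_scores_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Chi-square dependence of each feature column on a binary label.

    Observed counts are the per-class sums of the feature values;
    expected counts follow the class priors (the classic one-degree
    contingency computation on weighted occurrences).
    """
    n, p = X.shape
    n_pos = int(np.sum(y == 1))
    n_neg = n - n_pos
    scores = np.zeros(p)
    for j in range(p):
        obs_pos = 0.0
        obs_neg = 0.0
        for i in range(n):
            if y[i] == 1:
                obs_pos += X[i, j]
            else:
                obs_neg += X[i, j]
        total = obs_pos + obs_neg
        exp_pos = total * n_pos / n
        exp_neg = total * n_neg / n
        s = 0.0
        for obs, exp in ((obs_pos, exp_pos), (obs_neg, exp_neg)):
            if exp > 0:
                s += (obs - exp) ** 2 / exp
        scores[j] = s
    return scores


def f1_oracle(y_true, y_pred) -> float:
    tp = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 1 and p == 0:
            fn += 1
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def _average_ranks(values) -> list:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = _average_ranks(list(x)), _average_ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    if dx == 0 or dy == 0:
        return 0.0
    return num / (dx * dy)


def dice_oracle(col_x, col_y) -> float:
    inter = sum(1 for a, b in zip(col_x, col_y) if a == 1 and b == 1)
    nx = sum(1 for a in col_x if a == 1)
    ny = sum(1 for b in col_y if b == 1)
    if nx + ny == 0:
        return 0.0
    return 2 * inter / (nx + ny)


def ols_residual_oracle(x, y):
    """Residuals of y ~ 1 + x via the normal equations."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(a * a for a in x)
    sxy = sum(a * b for a, b in zip(x, y))
    det = n * sxx - sx * sx
    if det == 0:
        mean = sy / n
        return [b - mean for b in y]
    slope = (n * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / n
    return [b - (intercept + slope * a) for a, b in zip(x, y)]


def wpgma_oracle(dist: np.ndarray, names: list) -> list:
    """WPGMA agglomeration trace: list of (member_set_a, member_set_b, height).

    At each step merge the pair of clusters at minimal distance (ties:
    lexicographically smallest pair of member-name tuples); the merged
    cluster's distance to any other is the plain mean of the two merged
    clusters' distances.
    """
    clusters = {i: (frozenset([names[i]]),) for i in range(len(names))}
    d = {
        (i, j): float(dist[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    active = set(range(len(names)))
    merges = []
    next_id = len(names)
    members = {i: frozenset([names[i]]) for i in range(len(names))}
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                key = d[(i, j)] if (i, j) in d else d[(j, i)]
                tiebreak = tuple(sorted(members[i] | members[j]))
                if best is None or (key, tiebreak) < (best[0], best[3]):
                    best = (key, i, j, tiebreak)
        h, a, b, _ = best
        merges.append((members[a], members[b], h))
        for k in sorted(active - {a, b}):
            da = d[(min(a, k), max(a, k))]
            db = d[(min(b, k), max(b, k))]
            d[(min(next_id, k), max(next_id, k))] = (da + db) / 2.0
        members[next_id] = members[a] | members[b]
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return merges
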