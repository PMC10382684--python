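"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup |F_x - F_y| over the pooled sample points."""
    pooled = np.sort(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), pooled, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), pooled, side="right") / len(y)
    return float(np.abs(fx - fy).max())


def ks_exact_pvalue_enumeration(x, y) -> float:
    """Exact two-sample KS p-value by enumerating all class-preserving splits.

    P(D >= d_obs) over all C(n1+n2, n1) assignments of the pooled values to
    the first group (the permutation null for continuous data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d_obs = ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))
    hits = total = 0
    for comb in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        d = ks_statistic(pooled[mask], pooled[~mask])
        total += 1
        if d >= d_obs - 1e-12:
            hits += 1
    return hits / total


def bw_ratio_double_loop(values, labels) -> float:
    """Naive indicator-sum transcription of the BW-ratio formula."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    means = {k: values[labels == k].mean() for k in (0, 1)}
    between = 0.0
    within = 0.0
    for i in range(len(values)):
        for k in (0, 1):
            ind = 1.0 if labels[i] == k else 0.0
            between += ind * (means[k] - grand) ** 2
            within += ind * (values[i] - means[k]) ** 2
    if within == 0:
        return 0.0 if between == 0 else float("inf")
    return between / within


def auc_pair_counting(scores, labels) -> float:
    """AUC as explicit positive-negative pair counting with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def knn_neighbor_oracle(X_ref, X_query, k):
    """Brute-force neighbor sets under 1 - Spearman's rho, ties by ref order."""
    from scipy import stats

    out = []
    for q in np.asarray(X_query, float):
        d = np.array(
            [1 - stats.spearmanr(q, r).statistic for r in np.asarray(X_ref, float)]
        )
        order = sorted(range(len(d)), key=lambda i: (d[i], i))
        out.append(order[:k])
    return out
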