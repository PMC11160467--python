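"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives a result from first principles (loops, full sorts,
exhaustive enumeration) without touching the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values via the textbook recipe."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def filter_probes_oracle(detection, fdr=0.05, fraction=0.85) -> list:
    """Loop-over-CpGs enumeration of the detection filter."""
    n_species = detection.shape[0]
    need = math.ceil(fraction * n_species)
    adj_rows = {
        sp: bh_adjust(np.nan_to_num(detection.loc[sp].to_numpy(float), nan=1.0))
        for sp in detection.index
    }
    kept = []
    for j, cpg in enumerate(detection.columns):
        count = sum(1 for sp in detection.index if adj_rows[sp][j] < fdr)
        if count >= need:
            kept.append(cpg)
    return kept


def knn_oracle(distances, y, targets, k) -> dict:
    """Full sort of each target's distance row, lexicographic tie-break."""
    out = {}
    train = list(y.index)
    for t in targets:
        ranked = sorted(
            train, key=lambda s: (float(distances.loc[t, s]), s)
        )
        out[t] = float(np.mean([y.loc[s] for s in ranked[:k]]))
    return out


def wilcoxon_exact_oracle(x, y) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments.

    Enumerates every way of choosing which pooled observations belong to
    the first group, computes the Mann-Whitney U for each, and doubles
    the smaller tail at the observed U. Valid for tie-free samples.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n, m = len(x), len(y)

    def u_stat(first):
        return sum(1 for a in first for b in pooled if b not in first and a > b)

    # observed U for x (count of (x_i, y_j) pairs with x_i > y_j)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    idx = range(n + m)
    for comb in itertools.combinations(idx, n):
        first = [pooled[i] for i in comb]
        rest = [pooled[i] for i in idx if i not in comb]
        us.append(sum(1 for a in first for b in rest if a > b))
    us = np.array(us)
    p_le = float(np.mean(us <= u_obs))
    p_ge = float(np.mean(us >= u_obs))
    return min(1.0, 2 * min(p_le, p_ge))
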