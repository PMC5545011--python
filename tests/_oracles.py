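"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities by the most literal route possible
(explicit loops, direct arithmetic) and stay independent of the package
code paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def sse(values) -> float:
    values = list(values)
    if not values:
        return 0.0
    m = sum(values) / len(values)
    return sum((v - m) ** 2 for v in values)


def brute_candidates(X, y, min_leaf, variables):
    """Every admissible (variable, threshold, reduction) by direct loops."""
    y = list(map(float, y))
    total = sse(y)
    out = []
    for var in variables:
        col = [float(v) for v in X[var]]
        levels = sorted(set(col))
        for lo, hi in zip(levels[:-1], levels[1:]):
            thr = (lo + hi) / 2.0
            left = [yy for c, yy in zip(col, y) if c < thr]
            right = [yy for c, yy in zip(col, y) if c >= thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            out.append((var, thr, total - sse(left) - sse(right),
                        left, right))
    return out


def brute_best_split(X, y, min_leaf, variables):
    """First strict maximiser of the SSE reduction, or None."""
    best = None
    for var, thr, red, _, _ in brute_candidates(X, y, min_leaf, variables):
        if red > 1e-12 and (best is None or red > best[2] + 1e-12):
            best = (var, thr, red)
    return best


def brute_grow(X, y, alpha, min_split, min_leaf, variables):
    """Recursive enumerator mirroring the stopping semantics.

    Returns a list of (preorder_id, variable_or_None, threshold_or_None, n)
    describing the grown tree.
    """
    X = X.reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    out = []
    counter = {"next": 1}

    def welch(a, b):
        a, b = np.asarray(a), np.asarray(b)
        if a.var() == 0 and b.var() == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        return float(p) if np.isfinite(p) else 1.0

    def rec(idx):
        nid = counter["next"]
        counter["next"] += 1
        yy = y[idx]
        if len(yy) >= min_split:
            sub = X.iloc[idx]
            cands = brute_candidates(sub, yy, min_leaf, variables)
            best = None
            for var, thr, red, left, right in cands:
                if red > 1e-12 and (best is None or red > best[2] + 1e-12):
                    best = (var, thr, red, left, right)
            if best is not None:
                var, thr, _, left, right = best
                p_adj = min(1.0, welch(left, right) * max(1, len(cands)))
                if p_adj < alpha:
                    out.append((nid, var, thr, len(yy)))
                    col = sub[var].to_numpy(dtype=float)
                    rec(idx[col < thr])
                    rec(idx[col >= thr])
                    return
        out.append((nid, None, None, len(yy)))

    rec(np.arange(len(y)))
    return sorted(out)


def pairwise_auc(predictor, is_block, block_low=True):
    """AUC as explicit concordance over every (diseased, healthy) pair."""
    s = [-v for v in predictor] if block_low else list(predictor)
    pos = [v for v, b in zip(s, is_block) if b]
    neg = [v for v, b in zip(s, is_block) if not b]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
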