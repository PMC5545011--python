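"""Regression-tree derivation (CART) over ordinal test scores.

The model-building stage of a clinical decision rule: the cohort is split
recursively into binary subgroups over the eight test scores, with the
continuous EMG train-of-four ratio as the dependent variable.  At each node
every (variable, threshold) pair is enumerated exhaustively and the split
with the largest reduction in the sum of squared errors (SSE) wins — the
canonical CART regression criterion.  A node stops splitting when it is too
small or when the winning split's two subgroups do not differ significantly
(Welch t-test, Bonferroni-corrected for the number of candidate splits
examined at that node).  There is no pruning step.

Thresholds follow the "score >= t sends the patient right" convention, with
candidate thresholds at midpoints between adjacent observed score values.
Node ids are assigned in depth-first preorder (root = 1, left subtree before
right), the numbering convention used by the published pathway figure.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TEST_NAMES, TestScores
from .errors import ConfigError, MissingScoreError


@dataclass(frozen=True)
class SplitCandidate:
    """One candidate binary split of a node."""

    variable: str
    threshold: float
    sse_reduction: float
    p_value: float  # raw Welch-t p of the induced two-group difference

    def __post_init__(self) -> None:
        if self.sse_reduction < 0:
            raise ValueError("sse_reduction must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class CartConfig:
    """Stopping and significance parameters of the tree grower."""

    alpha: float = 0.05
    min_split: int = 20
    min_leaf: int = 7
    correction: str = "bonferroni"  # or "none"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.min_leaf < 1:
            raise ConfigError("min_leaf must be >= 1")
        if self.min_split < 2 * self.min_leaf:
            raise ConfigError("min_split must be >= 2 * min_leaf")
        if self.correction not in ("bonferroni", "none"):
            raise ConfigError("correction must be 'bonferroni' or 'none'")


@dataclass
class TreeNode:
    """One node of a grown regression tree."""

    id: int
    n: int
    mean_tofr: float
    sd_tofr: float
    min_tofr: float
    max_tofr: float
    kind: str = "terminal"  # or "internal"
    variable: Optional[str] = None
    threshold: Optional[float] = None
    split: Optional[SplitCandidate] = None
    adjusted_p: Optional[float] = None
    left: Optional[int] = None
    right: Optional[int] = None


@dataclass
class RegressionTree:
    """A grown tree: nodes keyed by preorder id, root id 1."""

    nodes: dict[int, TreeNode]
    config: CartConfig
    variables: list[str]

    @property
    def root(self) -> TreeNode:
        return self.nodes[1]

    def terminal_ids(self) -> list[int]:
        return [i for i, nd in sorted(self.nodes.items())
                if nd.kind == "terminal"]

    def to_spec_dict(self, epsilons: Sequence[float] = (0.7, 0.9)) -> dict:
        """Serialise to the decision-tree JSON dialect.

        Terminal nodes predict residual block at a cut-off when the node's
        mean TOFR lies below it.
        """
        nodes = []
        for i, nd in sorted(self.nodes.items()):
            d: dict = {"id": nd.id, "kind": nd.kind, "n": nd.n,
                       "mean_tofr": nd.mean_tofr}
            if nd.kind == "internal":
                d.update(variable=nd.variable, threshold=nd.threshold,
                         left=nd.left, right=nd.right)
            else:
                d["block_lt_07"] = bool(nd.mean_tofr < 0.7)
                d["block_lt_09"] = bool(nd.mean_tofr < 0.9)
            nodes.append(d)
        return {"name": "cart-grown", "version": "1", "nodes": nodes}

    def save_spec(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_spec_dict(), indent=2, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# Split search


def _sse(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    return float(np.sum((y - y.mean()) ** 2))


def _column(X: pd.DataFrame, name: str) -> np.ndarray:
    col = X[name].to_numpy(dtype=float)
    if np.isnan(col).any():
        raise MissingScoreError(
            f"variable '{name}' has missing scores; exclude those patients first"
        )
    return col


def enumerate_candidates(
    X: pd.DataFrame,
    y: np.ndarray,
    min_leaf: int = 1,
    variables: Optional[Sequence[str]] = None,
) -> list[SplitCandidate]:
    """All admissible (variable, midpoint-threshold) splits of this node.

    Candidates are enumerated in deterministic order: variables in the
    canonical test-battery order, thresholds ascending.  A candidate is
    admissible when both children hold at least ``min_leaf`` patients.
    """
    y = np.asarray(y, dtype=float)
    if variables is None:
        variables = [v for v in TEST_NAMES if v in X.columns]
        variables += [c for c in X.columns if c not in variables]
    out: list[SplitCandidate] = []
    total = _sse(y)
    for name in variables:
        col = _column(X, name)
        values = np.unique(col)
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2.0
            right = col >= thr
            n_r = int(right.sum())
            n_l = len(y) - n_r
            if n_l < min_leaf or n_r < min_leaf:
                continue
            reduction = total - _sse(y[~right]) - _sse(y[right])
            out.append(
                SplitCandidate(
                    variable=name,
                    threshold=float(thr),
                    sse_reduction=max(0.0, float(reduction)),
                    p_value=welch_p(y[~right], y[right]),
                )
            )
    return out


def best_split(
    X: pd.DataFrame,
    y: np.ndarray,
    min_leaf: int = 1,
    variables: Optional[Sequence[str]] = None,
) -> Optional[SplitCandidate]:
    """Exhaustively search all splits; return the SSE-reduction maximiser.

    Ties are broken by earlier variable (test-battery order) and then lower
    threshold — the enumeration order — by keeping the first strict
    maximum.  Returns ``None`` when no admissible candidate reduces the SSE
    (e.g. a constant TOFR vector).
    """
    cands = enumerate_candidates(X, y, min_leaf=min_leaf, variables=variables)
    best: Optional[SplitCandidate] = None
    for c in cands:
        if c.sse_reduction > 1e-12 and (best is None or
                                        c.sse_reduction > best.sse_reduction + 1e-12):
            best = c
    return best


# ---------------------------------------------------------------------------
# Significance stopping rule


def welch_p(left: np.ndarray, right: np.ndarray) -> float:
    """Raw p of the unequal-variance two-sample t-test on TOFR.

    Degenerate groups (zero variance on both sides) give p = 1 when the
    means are equal and p = 0 otherwise.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.var(ddof=0) == 0.0 and right.var(ddof=0) == 0.0:
        return 1.0 if left.mean() == right.mean() else 0.0
    p = stats.ttest_ind(left, right, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def split_significant(
    left: np.ndarray,
    right: np.ndarray,
    config: CartConfig,
    n_candidates: int = 1,
) -> tuple[bool, float]:
    """Decide whether a split's two subgroups differ significantly.

    Returns ``(significant, adjusted_p)``; the adjustment is Bonferroni over
    the number of candidate splits examined at the node (capped at 1), or no
    adjustment when ``config.correction == 'none'``.
    """
    config.validate()
    if len(left) < config.min_leaf or len(right) < config.min_leaf:
        raise ValueError("both groups must hold at least min_leaf patients")
    p = welch_p(left, right)
    if config.correction == "bonferroni":
        p = min(1.0, p * max(1, n_candidates))
    return p < config.alpha, p


# ---------------------------------------------------------------------------
# Recursive growing


def grow(
    X: pd.DataFrame,
    y: np.ndarray,
    config: Optional[CartConfig] = None,
    variables: Optional[Sequence[str]] = None,
) -> RegressionTree:
    """Grow a regression tree by recursive partitioning.

    Deterministic: exhaustive split search with fixed tie-breaking, preorder
    node numbering, and no randomness anywhere.  Invariant to the ordering
    of patient rows.
    """
    config = config or CartConfig()
    config.validate()
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("cohort must be non-empty")
    if len(y) != len(X):
        raise ValueError("scores table and TOFR vector differ in length")
    if variables is None:
        variables = [v for v in TEST_NAMES if v in X.columns]
        variables += [c for c in X.columns if c not in variables]
    nodes: dict[int, TreeNode] = {}
    counter = {"next": 1}

    def build(idx: np.ndarray) -> int:
        nid = counter["next"]
        counter["next"] += 1
        yy = y[idx]
        node = TreeNode(
            id=nid, n=len(yy), mean_tofr=float(yy.mean()),
            sd_tofr=float(yy.std(ddof=1)) if len(yy) > 1 else 0.0,
            min_tofr=float(yy.min()), max_tofr=float(yy.max()),
        )
        nodes[nid] = node
        if len(yy) >= config.min_split:
            sub = X.iloc[idx].reset_index(drop=True)
            cands = enumerate_candidates(sub, yy, min_leaf=config.min_leaf,
                                         variables=variables)
            winner: Optional[SplitCandidate] = None
            for c in cands:
                if c.sse_reduction > 1e-12 and (
                    winner is None or c.sse_reduction > winner.sse_reduction + 1e-12
                ):
                    winner = c
            if winner is not None:
                col = sub[winner.variable].to_numpy(dtype=float)
                right_mask = col >= winner.threshold
                ok, adj_p = split_significant(
                    yy[~right_mask], yy[right_mask], config,
                    n_candidates=len(cands),
                )
                if ok:
                    node.kind = "internal"
                    node.variable = winner.variable
                    node.threshold = winner.threshold
                    node.split = winner
                    node.adjusted_p = adj_p
                    node.left = build(idx[~right_mask])
                    node.right = build(idx[right_mask])
        return nid

    build(np.arange(len(y)))
    return RegressionTree(nodes=nodes, config=config, variables=list(variables))


# ---------------------------------------------------------------------------
# Routing


def predict_node(tree: RegressionTree, scores: TestScores) -> tuple[int, float]:
    """Route one score vector to its terminal node.

    Returns the terminal node id and that node's mean TOFR.  A missing score
    on a variable the tree uses raises :class:`MissingScoreError`.
    """
    node = tree.root
    while node.kind == "internal":
        v = scores.get(node.variable)  # type: ignore[arg-type]
        if v is None:
            raise MissingScoreError(
                f"score '{node.variable}' required by node {node.id} is missing"
            )
        node = tree.nodes[node.right if v >= node.threshold else node.left]
    return node.id, node.mean_tofr


def predict_tofr(tree: RegressionTree, scores: TestScores) -> float:
    """Predicted TOFR: the mean of the terminal node the patient reaches."""
    return predict_node(tree, scores)[1]
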