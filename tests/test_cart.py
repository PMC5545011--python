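"""Regression-tree derivation against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_best_split, brute_grow, sse
from porc.cart import (
    CartConfig,
    best_split,
    enumerate_candidates,
    grow,
    predict_node,
    split_significant,
    welch_p,
)
from porc.cohort import SCORE_RANGES, TestScores
from porc.errors import ConfigError, MissingScoreError
from porc.simulate import step_tree_cohort


def random_table(rng, n=12, n_vars=3):
    names = ["open_eyes", "head_lift", "arm_lift"][:n_vars]
    X = pd.DataFrame({
        name: rng.integers(SCORE_RANGES[name][0], SCORE_RANGES[name][1] + 1,
                           size=n)
        for name in names
    })
    y = rng.normal(0.5, 0.3, size=n).clip(0, 1.2)
    return X, y, names


class TestBestSplit:
    def test_constant_tofr_gives_no_split(self):
        X = pd.DataFrame({"arm_lift": [0, 1, 2, 3, 4, 5]})
        assert best_split(X, np.full(6, 0.5)) is None

    def test_pure_step_splits_between_three_and_four(self):
        # eight patients, one variable; split at 3.5 leaves pure children,
        # so the reduction equals the total SSE of 8 * (0.4)^2 = 1.28
        X = pd.DataFrame({"arm_lift": [0, 1, 2, 3, 4, 5, 5, 5]})
        y = np.array([0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9])
        cand = best_split(X, y)
        assert cand.variable == "arm_lift"
        assert cand.threshold == pytest.approx(3.5)
        assert cand.sse_reduction == pytest.approx(sse(y)) == pytest.approx(1.28)

    def test_matches_brute_force_enumeration_over_seeds(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X, y, names = random_table(rng)
            ours = best_split(X, y, min_leaf=2, variables=names)
            oracle = brute_best_split(X, y, min_leaf=2, variables=names)
            if oracle is None:
                assert ours is None
            else:
                assert (ours.variable, ours.threshold) == oracle[:2]
                assert ours.sse_reduction == pytest.approx(oracle[2])

    def test_tie_breaks_by_variable_order_then_threshold(self):
        # two variables inducing identical partitions: earlier battery
        # position (open_eyes) must win
        X = pd.DataFrame({"open_eyes": [0, 0, 5, 5],
                          "arm_lift": [0, 0, 5, 5]})
        y = np.array([0.1, 0.1, 0.9, 0.9])
        cand = best_split(X, y)
        assert cand.variable == "open_eyes"

    def test_min_leaf_excludes_unbalanced_candidates(self):
        X = pd.DataFrame({"arm_lift": [0, 1, 1, 1, 1, 1]})
        y = np.array([0.0, 0.9, 0.9, 0.9, 0.9, 0.9])
        assert best_split(X, y, min_leaf=2) is None


class TestSplitSignificance:
    def test_identical_groups_not_significant(self):
        cfg = CartConfig(min_leaf=1, min_split=2)
        ok, p = split_significant(np.full(3, 0.5), np.full(3, 0.5), cfg)
        assert not ok and p == 1.0

    def test_extreme_separation_significant(self, rng):
        cfg = CartConfig(min_leaf=1, min_split=2)
        left = 0.1 + rng.normal(0, 1e-3, 10)
        right = 0.9 + rng.normal(0, 1e-3, 10)
        ok, p = split_significant(left, right, cfg)
        assert ok and p < 1e-6

    def test_bonferroni_multiplies_by_candidate_count(self, rng):
        left = rng.normal(0.4, 0.1, 12)
        right = rng.normal(0.5, 0.1, 12)
        raw = welch_p(left, right)
        cfg = CartConfig(min_leaf=1, min_split=2)
        _, adjusted = split_significant(left, right, cfg, n_candidates=2)
        assert adjusted == pytest.approx(min(1.0, raw * 2))

    def test_no_correction_mode_uses_raw_p(self, rng):
        left = rng.normal(0.4, 0.1, 12)
        right = rng.normal(0.5, 0.1, 12)
        cfg = CartConfig(min_leaf=1, min_split=2, correction="none")
        _, p = split_significant(left, right, cfg, n_candidates=50)
        assert p == pytest.approx(welch_p(left, right))


class TestGrow:
    def test_no_significant_split_gives_root_only_tree(self, rng):
        X = pd.DataFrame({"arm_lift": rng.integers(0, 6, 60)})
        y = rng.normal(0.5, 0.2, 60)
        tree = grow(X, y, CartConfig(alpha=1e-9))
        assert list(tree.nodes) == [1]
        assert tree.root.kind == "terminal"

    def test_min_split_stopping_rule(self, rng):
        X, y = step_tree_cohort(165, rng)
        tree = grow(X, y, CartConfig(min_split=400))
        assert list(tree.nodes) == [1]

    def test_recovers_generating_root_split(self):
        X, y = step_tree_cohort(400, np.random.default_rng(5), noise_sd=0.05)
        tree = grow(X, y)
        assert tree.root.variable == "arm_lift"
        assert 4.0 < tree.root.threshold <= 5.0

    def test_row_permutation_never_changes_the_tree(self, rng):
        X, y = step_tree_cohort(120, rng)
        tree_a = grow(X, y)
        perm = rng.permutation(len(y))
        tree_b = grow(X.iloc[perm].reset_index(drop=True), y[perm])
        assert sorted(tree_a.nodes) == sorted(tree_b.nodes)
        for i in tree_a.nodes:
            a, b = tree_a.nodes[i], tree_b.nodes[i]
            assert (a.kind, a.variable, a.threshold, a.n) == \
                (b.kind, b.variable, b.threshold, b.n)

    def test_matches_recursive_brute_enumerator_over_seeds(self):
        cfg = CartConfig(alpha=0.05, min_split=4, min_leaf=2)
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            X, y, names = random_table(rng, n=12)
            tree = grow(X, y, cfg, variables=names)
            ours = sorted(
                (i, nd.variable, nd.threshold, nd.n)
                for i, nd in tree.nodes.items()
            )
            oracle = brute_grow(X, y, cfg.alpha, cfg.min_split, cfg.min_leaf,
                                names)
            assert ours == oracle

    def test_every_accepted_split_strictly_reduces_sse(self):
        X, y = step_tree_cohort(300, np.random.default_rng(8))
        tree = grow(X, y)
        node_sse = {
            i: nd.sd_tofr ** 2 * (nd.n - 1) for i, nd in tree.nodes.items()
        }
        assert any(nd.kind == "internal" for nd in tree.nodes.values())
        for i, nd in tree.nodes.items():
            if nd.kind == "internal":
                assert node_sse[nd.left] + node_sse[nd.right] < node_sse[i]

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            grow(pd.DataFrame({"arm_lift": []}), np.array([]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CartConfig(min_split=5, min_leaf=7).validate()


@pytest.fixture(scope="module")
def small_tree():
    X, y = step_tree_cohort(300, np.random.default_rng(2))
    return grow(X, y)


class TestPredictNode:

    def test_all_max_scores_reach_rightmost_terminal(self, small_tree):
        nid, mean = predict_node(small_tree, TestScores.all_maximum())
        # the right-most terminal has the highest id under preorder numbering
        assert nid == max(small_tree.terminal_ids())
        assert mean == small_tree.nodes[nid].mean_tofr

    def test_boundary_value_goes_right(self):
        X = pd.DataFrame({"arm_lift": [0, 0, 0, 0, 5, 5, 5, 5]})
        y = np.array([0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9])
        tree = grow(X, y, CartConfig(alpha=0.05, min_split=4, min_leaf=2))
        root = tree.root
        assert root.kind == "internal"
        at_threshold = TestScores.all_minimum().as_dict()
        at_threshold["arm_lift"] = int(np.ceil(root.threshold))
        nid, _ = predict_node(tree, TestScores(**at_threshold))
        assert nid in _leaf_ids_under(tree, root.right)

    def test_missing_score_raises(self, small_tree):
        scores = TestScores.all_maximum().as_dict()
        scores[small_tree.root.variable] = None
        with pytest.raises(MissingScoreError):
            predict_node(small_tree, TestScores(**scores))

    def test_routing_total_over_full_score_lattice(self, small_tree):
        # every vector of the full eight-test lattice maps to exactly one leaf
        terminals = set(small_tree.terminal_ids())
        ranges = [range(lo, hi + 1) for lo, hi in SCORE_RANGES.values()]
        names = list(SCORE_RANGES)
        seen = set()
        for combo in itertools.product(*ranges):
            nid, _ = predict_node(small_tree,
                                  TestScores(**dict(zip(names, combo))))
            assert nid in terminals
            seen.add(nid)
        assert seen == terminals


def _leaf_ids_under(tree, node_id):
    nd = tree.nodes[node_id]
    if nd.kind == "terminal":
        return {node_id}
    return _leaf_ids_under(tree, nd.left) | _leaf_ids_under(tree, nd.right)
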