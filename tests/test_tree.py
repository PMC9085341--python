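"""Grouping trees: brute-force oracles, Bonferroni counts, determinism."""

import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drgcost.errors import InputError
from drgcost.tree import (
    CARTRegressor,
    CHAIDRegressor,
    TreeConfig,
    TreeModel,
    bonferroni_multiplier,
    compare_models,
    grow_cart,
    grow_tree,
    merge_categories,
    select_split,
    stirling2,
)


# ---------------------------------------------------------------------------
# independent oracles


def oracle_partitions(items):
    """All set partitions, built by assigning each item a block index."""
    items = list(items)
    n = len(items)
    seen = set()
    for labels in itertools.product(range(n), repeat=n):
        blocks = {}
        for item, lab in zip(items, labels):
            blocks.setdefault(lab, []).append(item)
        key = frozenset(frozenset(b) for b in blocks.values())
        if key not in seen:
            seen.add(key)
            yield list(blocks.values())


def oracle_contiguous(items):
    items = list(items)
    for k in range(1, len(items) + 1):
        for cuts in itertools.combinations(range(1, len(items)), k - 1):
            edges = (0,) + cuts + (len(items),)
            yield [items[edges[i]:edges[i + 1]] for i in range(k)]


def anova_p(groups):
    """Reference one-way ANOVA p via scipy, with the same degenerate rules."""
    if len(groups) < 2:
        return 1.0
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0
    if all(np.ptp(g) == 0 for g in groups):
        return 0.0
    f, p = stats.f_oneway(*groups)
    return float(p)


def best_partition_bruteforce(data, scale):
    gen = oracle_contiguous if scale == "ordinal" else oracle_partitions
    cats = list(data)
    pos = {c: i for i, c in enumerate(cats)}
    best = None
    for part in gen(cats):
        p = anova_p([np.concatenate([data[c] for c in g]) for g in part]) if len(part) > 1 else 1.0
        canon = tuple(sorted(
            (tuple(sorted(g, key=pos.get)) for g in part),
            key=lambda g: pos[g[0]],
        ))
        key = (p, len(part), tuple(pos[g[0]] for g in canon))
        if best is None or key < best[0]:
            best = (key, canon, p)
    return best[1], best[2]


def random_category_data(rng, max_cats=4, max_n=12):
    c = int(rng.integers(2, max_cats + 1))
    sizes = rng.multinomial(max_n - c, np.ones(c) / c) + 1
    shift = rng.normal(scale=rng.choice([0.2, 1.0, 4.0]), size=c)
    return {
        f"c{i}": rng.normal(loc=shift[i], size=sizes[i]) for i in range(c)
    }


# ---------------------------------------------------------------------------
# category merging


class TestMergeCategories:
    def test_identical_categories_collapse_to_one(self):
        res = merge_categories({"a": [1.0, 2.0, 3.0], "b": [3.0, 1.0, 2.0]})
        assert res.k == 1
        assert res.p_value == 1.0

    def test_clear_outlier_category_isolated(self):
        data = {
            "a": [0.0, 0.01, -0.01],
            "b": [0.02, 0.0, -0.02],
            "c": [10.0, 10.01, 9.99],
        }
        res = merge_categories(data, order=["a", "b", "c"])
        assert res.partition == (("a", "b"), ("c",))
        oracle_part, _ = best_partition_bruteforce(
            {k: np.asarray(v) for k, v in data.items()}, "nominal"
        )
        assert res.partition == oracle_part

    @pytest.mark.parametrize("scale", ["nominal", "ordinal"])
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_bruteforce_on_small_inputs(self, scale, seed):
        rng = np.random.default_rng(seed)
        data = random_category_data(rng)
        order = sorted(data)
        res = merge_categories(data, scale=scale, order=order)
        _, oracle_p = best_partition_bruteforce(data, scale)
        assert res.p_value == pytest.approx(oracle_p, abs=1e-12)

    def test_empty_category_rejected(self):
        with pytest.raises(InputError):
            merge_categories({"a": [1.0], "b": []})

    def test_min_size_constrains_partitions(self):
        data = {"a": [0.0] * 10, "b": [10.0] * 2, "c": [10.2] * 10}
        res = merge_categories(data, order=["a", "b", "c"], min_size=5)
        assert all(
            sum(len(data[c]) for c in g) >= 5 for g in res.partition
        )


class TestBonferroni:
    @pytest.mark.parametrize(
        "c,k,expected",
        [(2, 2, 1), (3, 2, 3), (4, 2, 7), (4, 3, 6), (5, 2, 15), (4, 4, 1)],
    )
    def test_stirling_counts(self, c, k, expected):
        assert stirling2(c, k) == expected
        assert bonferroni_multiplier(c, k, "nominal") == expected

    @pytest.mark.parametrize("c,k", [(3, 2), (4, 2), (4, 3), (5, 3)])
    def test_ordinal_counts_are_cutpoint_combinations(self, c, k):
        assert bonferroni_multiplier(c, k, "ordinal") == math.comb(c - 1, k - 1)

    def test_binary_predictor_multiplier_is_one(self):
        assert bonferroni_multiplier(2, 2, "nominal") == 1
        assert bonferroni_multiplier(2, 2, "ordinal") == 1


# ---------------------------------------------------------------------------
# split selection


def node_frame(rng, n=200):
    signal = rng.integers(0, 2, size=n)
    return pd.DataFrame({
        "signal": np.where(signal, "hi", "lo"),
        "noise1": rng.choice(["a", "b", "c"], size=n),
        "noise2": rng.choice(["x", "y"], size=n),
    }), signal * 100.0 + rng.normal(scale=1.0, size=n)


class TestSelectSplit:
    def _config(self, **kw):
        defaults = dict(
            predictors=("signal", "noise1", "noise2"),
            min_parent_n=20, min_child_n=10, scales={},
        )
        defaults.update(kw)
        return TreeConfig(**defaults)

    def test_informative_predictor_chosen(self):
        rng = np.random.default_rng(0)
        X, y = node_frame(rng)
        split = select_split(X, y, self._config())
        assert split.predictor == "signal"
        assert split.p_adjusted <= split.p_raw * 10  # sanity
        assert split.p_adjusted >= split.p_raw or split.p_adjusted == 1.0

    def test_constant_predictors_give_no_split(self):
        X = pd.DataFrame({"signal": ["same"] * 50, "noise1": ["a"] * 50,
                          "noise2": ["x"] * 50})
        y = np.arange(50.0)
        assert select_split(X, y, self._config()) is None

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(3)
        X, y = node_frame(rng)
        split = select_split(X, y, self._config())
        assert split.p_adjusted >= split.p_raw - 1e-15

    def test_pure_noise_usually_not_split(self):
        rng = np.random.default_rng(11)
        X, _ = node_frame(rng)
        y = rng.normal(size=len(X))
        split = select_split(X, y, self._config(alpha_split=0.001))
        assert split is None


# ---------------------------------------------------------------------------
# tree growth


class TestCHAIDTree:
    def test_constant_cost_single_leaf(self, default_cohort):
        frame = default_cohort["frame"].iloc[:500].copy()
        frame["total_cost"] = 42.0
        model = grow_tree(frame)
        assert model.n_leaves == 1

    def test_first_split_is_cc_level(self, default_cohort):
        model = grow_tree(default_cohort["frame"])
        assert model.nodes[model.root_id].split_var == "cc_level"
        assert model.nodes[model.root_id].p_adjusted <= 0.05

    def test_row_permutation_invariance(self, default_cohort):
        frame = default_cohort["frame"].iloc[:2000]
        rng = np.random.default_rng(0)
        shuffled = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
        a = grow_tree(frame)
        b = grow_tree(shuffled)
        assert [a.nodes[i].label for i in a.leaf_ids] == [
            b.nodes[i].label for i in b.leaf_ids
        ]
        assert [a.nodes[i].n for i in a.leaf_ids] == [
            b.nodes[i].n for i in b.leaf_ids
        ]

    def test_leaves_partition_cohort(self, default_cohort):
        frame = default_cohort["frame"]
        model = grow_tree(frame)
        assignment = model.apply(frame)
        assert len(assignment) == len(frame)
        leaf_ns = {nid: model.nodes[nid].n for nid in model.leaf_ids}
        counts = pd.Series(assignment).value_counts().to_dict()
        assert counts == leaf_ns
        assert sum(leaf_ns.values()) == len(frame)

    def test_children_sum_to_parent(self, default_cohort):
        model = grow_tree(default_cohort["frame"])
        for node in model.nodes.values():
            if not node.is_leaf:
                assert sum(model.nodes[c].n for c in node.children) == node.n
                assert node.p_adjusted <= 0.05

    def test_alpha_monotone_in_leaf_count(self, default_cohort):
        frame = default_cohort["frame"]
        leaves = [
            grow_tree(frame, TreeConfig(alpha_split=a)).n_leaves
            for a in (1e-6, 0.05, 0.5)
        ]
        assert leaves[0] <= leaves[1] <= leaves[2]

    def test_json_round_trip(self, tmp_path, default_cohort):
        frame = default_cohort["frame"].iloc[:1500]
        model = grow_tree(frame)
        path = tmp_path / "tree.json"
        model.to_json(path)
        back = TreeModel.from_json(path)
        np.testing.assert_array_equal(model.apply(frame), back.apply(frame))


class TestCART:
    def test_two_category_predictor_single_split(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"g": ["a"] * 30 + ["b"] * 30})
        y = np.r_[rng.normal(0, 1, 30), rng.normal(50, 1, 30)]
        est = CARTRegressor(predictors=("g",), min_parent_n=10, min_child_n=5).fit(X, y)
        assert est.n_leaves_ == 2
        assert est.model_.nodes[0].split_var == "g"

    @pytest.mark.parametrize("seed", range(10))
    def test_root_split_matches_exhaustive_sse_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        X = pd.DataFrame({
            "p1": rng.choice(["a", "b", "c"], size=n),
            "p2": rng.choice(["u", "v"], size=n),
            "p3": rng.choice(["m", "n", "o"], size=n),
        })
        y = rng.normal(size=n) + (X["p1"] == "a") * rng.choice([0.0, 3.0])

        def sse(v):
            return ((v - v.mean()) ** 2).sum() if len(v) else 0.0

        best_gain = -1.0
        for pred in X.columns:
            cats = sorted(X[pred].unique())
            if len(cats) < 2:
                continue
            for r in range(1, len(cats)):
                for left in itertools.combinations(cats, r):
                    mask = X[pred].isin(left).to_numpy()
                    if mask.sum() == 0 or (~mask).sum() == 0:
                        continue
                    gain = sse(y) - sse(y[mask]) - sse(y[~mask])
                    best_gain = max(best_gain, gain)

        est = CARTRegressor(
            predictors=("p1", "p2", "p3"), min_parent_n=2, min_child_n=1,
            max_depth=1, scales={},
        ).fit(X, y)
        root = est.model_.nodes[0]
        if root.is_leaf:
            assert best_gain <= 0
        else:
            assert root.statistic == pytest.approx(best_gain, rel=1e-9)

    def test_training_sse_monotone_in_depth(self, default_cohort):
        frame = default_cohort["frame"].iloc[:2500]
        y = frame["total_cost"].to_numpy()
        sses = []
        for depth in (1, 2, 4):
            est = CARTRegressor(max_depth=depth).fit(frame, y)
            pred = est.predict(frame)
            sses.append(((y - pred) ** 2).sum())
        assert sses[0] >= sses[1] >= sses[2]

    def test_ccp_pruning_reduces_leaves(self, default_cohort):
        frame = default_cohort["frame"].iloc[:2500]
        y = frame["total_cost"].to_numpy()
        full = CARTRegressor().fit(frame, y)
        pruned = CARTRegressor(ccp_alpha=1e12).fit(frame, y)
        assert pruned.n_leaves_ <= full.n_leaves_
        assert pruned.n_leaves_ == 1


class TestCompareModels:
    def test_single_leaf_flagged_degenerate(self, default_cohort):
        frame = default_cohort["frame"].iloc[:500].copy()
        frame["total_cost"] = np.linspace(10, 20, len(frame))
        frame["cc_level"] = "CC"
        frame["sex"] = "male"
        frame["discharge_mode"] = "home"
        frame["age_band"] = ">65"
        frame["admission_route"] = "emergency"
        model = grow_tree(frame)
        (comp,) = compare_models([model], frame)
        assert comp.degenerate and comp.correlation == 0.0
        y = frame["total_cost"]
        assert comp.mae == pytest.approx(np.abs(y - y.mean()).mean())

    def test_pure_leaves_zero_mae(self):
        X = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5 + ["c"] * 5})
        y = np.array([1.0] * 5 + [9.0] * 5 + [30.0] * 5)
        frame = X.assign(total_cost=y)
        est = CHAIDRegressor(
            predictors=("g",), min_parent_n=2, min_child_n=1, scales={},
        ).fit(frame, y)
        (comp,) = compare_models([est.model_], frame)
        assert comp.mae == pytest.approx(0.0)
        assert comp.n_groups == 3

    def test_echaid_beats_depth_limited_cart(self, default_cohort):
        frame = default_cohort["frame"]
        echaid = grow_tree(frame)
        cart1 = grow_cart(frame, TreeConfig(algorithm="cart", max_depth=1))
        comp = {c.model: c for c in compare_models([echaid, cart1], frame)}
        assert comp["e-chaid"].correlation >= comp["cart"].correlation
        assert comp["e-chaid"].n_groups > comp["cart"].n_groups
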