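"""Cost-grouping regression trees over categorical predictors.

Two algorithms share the node/leaf machinery:

* **Exhaustive CHAID** (:class:`CHAIDRegressor`) — for each predictor the
  categories are merged into the partition whose one-way ANOVA p-value
  (continuous target) is smallest; the winning predictor is the one with
  the smallest Bonferroni-adjusted p, and a node splits only if that
  adjusted p clears ``alpha_split``.  The Bonferroni multiplier is the
  number of ways to partition the predictor's c observed categories into
  the k merged groups: a Stirling number of the second kind for nominal
  predictors, C(c-1, k-1) for ordinal ones (only contiguous merges are
  allowed).  For small category counts (<= ``exhaustive_limit``) every
  admissible partition is scored directly; beyond that the classic
  sequential least-significant-pair merge with best-partition memory is
  used.  Splits are multiway.

* **CART** (:class:`CARTRegressor`) — binary splits chosen to maximise the
  reduction in within-node sum of squared errors over all binary category
  partitions (cut points for ordinal predictors), with optional
  cost-complexity (weakest-link) pruning.

Both are deterministic: ties in the split score are broken by the declared
predictor order, and category iteration follows a fixed canonical order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigurationError, InputError

__all__ = [
    "TreeConfig",
    "TreeNode",
    "TreeModel",
    "MergeResult",
    "Split",
    "ModelComparison",
    "CHAIDRegressor",
    "CARTRegressor",
    "merge_categories",
    "select_split",
    "grow_tree",
    "grow_cart",
    "compare_models",
    "stirling2",
    "bonferroni_multiplier",
]

#: Default grouping predictors, in tie-break priority order.
DEFAULT_PREDICTORS = ("cc_level", "discharge_mode", "age_band", "sex", "admission_route")

#: Canonical category orders (used for ordinal adjacency and determinism).
LEVEL_ORDERS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "age_band": ("0-17", "18-65", ">65"),
    "cc_level": ("NonCC", "CC", "MCC"),
    "admission_route": ("outpatient_other", "emergency"),
    "discharge_mode": ("home", "transfer", "death", "other"),
    "social_insurance": ("no", "yes"),
    "long_stay": ("no", "yes"),
}

#: Default measurement scales; cc_level may be toggled to ordinal
#: (severity-ordered Non-CC < CC < MCC) via TreeConfig.scales.
DEFAULT_SCALES: dict[str, str] = {"age_band": "ordinal"}


@dataclass
class TreeConfig:
    """Growth control shared by both algorithms."""

    algorithm: str = "e-chaid"  # "e-chaid" | "cart"
    alpha_split: float = 0.05
    bonferroni: bool = True
    max_depth: int = 5
    min_parent_n: int = 100
    min_child_n: int = 50
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    scales: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SCALES))
    target: str = "total_cost"
    exhaustive_limit: int = 6
    ccp_alpha: float | None = None  # CART cost-complexity pruning strength

    def __post_init__(self):
        if not (0 < self.alpha_split < 1):
            raise ConfigurationError("alpha_split must be in (0, 1)")
        if self.min_child_n < 1:
            raise ConfigurationError("min_child_n must be >= 1")
        if self.min_parent_n < 2 * self.min_child_n:
            raise ConfigurationError("min_parent_n must be >= 2*min_child_n")

    def scale_of(self, predictor: str) -> str:
        return self.scales.get(predictor, "nominal")


# ---------------------------------------------------------------------------
# small numerics


def _anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p across groups of a continuous target.

    Degenerate cases: no between-group variation -> (0, 1); between-group
    variation with zero within-group variance -> (inf, 0).
    """
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k < 2 or n <= k:
        return 0.0, 1.0
    grand = sum(float(g.sum()) for g in groups) / n
    ssb = sum(len(g) * (float(g.mean()) - grand) ** 2 for g in groups)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if ssb <= 0:
        return 0.0, 1.0
    if ssw <= 0:
        return math.inf, 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    from scipy import stats

    return f, float(stats.f.sf(f, k - 1, n - k))


def stirling2(c: int, k: int) -> int:
    """Stirling number of the second kind: partitions of c items into k
    nonempty unlabelled groups."""
    if k < 0 or k > c:
        return 0
    if k == 0:
        return 1 if c == 0 else 0
    return sum(
        (-1) ** i * math.comb(k, i) * (k - i) ** c for i in range(k)
    ) // math.factorial(k)


def bonferroni_multiplier(c: int, k: int, scale: str) -> int:
    """Number of ways c observed categories can be partitioned into k merged
    groups — the CHAID Bonferroni multiplier for the chosen split."""
    if scale == "ordinal":
        return math.comb(c - 1, k - 1)
    return stirling2(c, k)


# ---------------------------------------------------------------------------
# partition enumeration


def _set_partitions(items: Sequence) -> Iterator[list[list]]:
    """All partitions of ``items`` into nonempty groups (Bell(n) of them)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _contiguous_partitions(items: Sequence) -> Iterator[list[list]]:
    """Partitions of an ordered sequence into contiguous blocks (2^(n-1))."""
    items = list(items)
    n = len(items)
    for mask in range(1 << max(n - 1, 0)):
        part, block = [], [items[0]]
        for i in range(1, n):
            if mask >> (i - 1) & 1:
                part.append(block)
                block = [items[i]]
            else:
                block.append(items[i])
        part.append(block)
        yield part


@dataclass(frozen=True)
class MergeResult:
    """Best merged partition of one predictor's categories."""

    partition: tuple[tuple[str, ...], ...]
    statistic: float  # one-way F of the partition (0 for the trivial one)
    p_value: float
    n_categories: int

    @property
    def k(self) -> int:
        return len(self.partition)


def _canon_partition(part: Sequence[Sequence[str]], order: Sequence[str]) -> tuple:
    pos = {c: i for i, c in enumerate(order)}
    groups = [tuple(sorted(g, key=lambda c: pos[c])) for g in part]
    return tuple(sorted(groups, key=lambda g: pos[g[0]]))


def merge_categories(
    groups: Mapping[str, Sequence[float]],
    scale: str = "nominal",
    order: Sequence[str] | None = None,
    min_size: int = 1,
    exhaustive_limit: int = 6,
) -> MergeResult:
    """Merge a predictor's categories into the most significant partition.

    Candidate partitions with >= 2 groups are scored by one-way ANOVA p on
    the target; the single-group partition participates with p = 1, so a
    predictor with no signal collapses entirely.  Partitions whose smallest
    group is below ``min_size`` are inadmissible (the trivial partition is
    always admissible).  Ties in p prefer fewer groups, then canonical
    category order.  For <= ``exhaustive_limit`` categories all partitions
    are enumerated; beyond that, least-significant pairs are merged
    sequentially (adjacent pairs only, if ordinal) and the best partition
    seen along the way is returned.
    """
    cats = list(groups.keys())
    arrays = {c: np.asarray(groups[c], dtype=float) for c in cats}
    if any(a.size == 0 for a in arrays.values()):
        raise InputError("every category must be nonempty")
    if order is None:
        order = sorted(cats, key=str)
    else:
        order = [c for c in order if c in arrays] + [
            c for c in cats if c not in order
        ]
    cats = list(order)
    c = len(cats)
    trivial = MergeResult((tuple(cats),), 0.0, 1.0, c)
    if c == 1:
        return trivial

    def admissible(part) -> bool:
        return all(sum(arrays[cat].size for cat in g) >= min_size for g in part)

    def score(part) -> MergeResult:
        f, p = _anova([np.concatenate([arrays[cat] for cat in g]) for g in part])
        return MergeResult(_canon_partition(part, cats), f, p, c)

    candidates: list[MergeResult] = [trivial]
    if c <= exhaustive_limit:
        gen = _contiguous_partitions(cats) if scale == "ordinal" else _set_partitions(cats)
        for part in gen:
            if len(part) >= 2 and admissible(part):
                candidates.append(score(part))
    else:
        current = [[cat] for cat in cats]
        if admissible(current):
            candidates.append(score(current))
        while len(current) > 2:
            pairs = (
                [(i, i + 1) for i in range(len(current) - 1)]
                if scale == "ordinal"
                else [
                    (i, j)
                    for i in range(len(current))
                    for j in range(i + 1, len(current))
                ]
            )
            best_pair, best_p = None, -1.0
            for i, j in pairs:
                gi = np.concatenate([arrays[cat] for cat in current[i]])
                gj = np.concatenate([arrays[cat] for cat in current[j]])
                _, p = _anova([gi, gj])
                if p > best_p:
                    best_pair, best_p = (i, j), p
            i, j = best_pair
            current[i] = current[i] + current[j]
            del current[j]
            if admissible(current):
                candidates.append(score(current))

    pos = {cat: i for i, cat in enumerate(cats)}
    return min(
        candidates,
        key=lambda r: (r.p_value, r.k, tuple(pos[g[0]] for g in r.partition)),
    )


# ---------------------------------------------------------------------------
# split selection (E-CHAID)


@dataclass(frozen=True)
class Split:
    predictor: str
    partition: tuple[tuple[str, ...], ...]
    p_adjusted: float
    p_raw: float
    statistic: float


def select_split(
    X: pd.DataFrame,
    y: np.ndarray,
    config: TreeConfig,
) -> Split | None:
    """Best admissible E-CHAID split of the node, or None.

    Each predictor's categories are merged (:func:`merge_categories`); its
    best raw p is Bonferroni-adjusted by the number of partitions of its c
    observed categories into the chosen k groups.  The predictor with the
    smallest adjusted p wins (ties: declared predictor order); the split is
    admitted only if adjusted p <= alpha_split, every child has at least
    min_child_n records, and it actually divides the node.
    """
    y = np.asarray(y, dtype=float)
    best: Split | None = None
    for predictor in config.predictors:
        if predictor not in X.columns:
            raise ConfigurationError(f"predictor {predictor!r} not in data")
        col = _as_str(X[predictor])
        observed = [
            lv
            for lv in _observed_order(predictor, col)
            if (col == lv).any()
        ]
        if len(observed) < 2:
            continue
        groups = {lv: y[(col == lv).to_numpy()] for lv in observed}
        res = merge_categories(
            groups,
            scale=config.scale_of(predictor),
            order=observed,
            min_size=config.min_child_n,
            exhaustive_limit=config.exhaustive_limit,
        )
        if res.k < 2:
            continue
        mult = (
            bonferroni_multiplier(len(observed), res.k, config.scale_of(predictor))
            if config.bonferroni
            else 1
        )
        p_adj = min(1.0, res.p_value * mult)
        cand = Split(predictor, res.partition, p_adj, res.p_value, res.statistic)
        if best is None or p_adj < best.p_adjusted:
            best = cand
    if best is None or best.p_adjusted > config.alpha_split:
        return None
    return best


def _as_str(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col.map({False: "no", True: "yes"})
    return col.astype(str)


def _observed_order(predictor: str, col: pd.Series) -> list[str]:
    canonical = LEVEL_ORDERS.get(predictor)
    observed = list(pd.unique(col))
    if canonical:
        return [lv for lv in canonical if lv in observed] + sorted(
            lv for lv in observed if lv not in canonical
        )
    return sorted(observed)


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class TreeNode:
    id: int
    parent: int | None
    depth: int
    n: int
    mean: float
    median: float
    split_var: str | None = None
    p_adjusted: float | None = None
    statistic: float | None = None
    children: list[int] = field(default_factory=list)
    branch_categories: tuple[str, ...] | None = None  # edge from the parent
    label: str = ""

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None


@dataclass
class TreeModel:
    """A fitted grouping tree: nodes, leaves in stable order, and routing."""

    algorithm: str
    target: str
    nodes: dict[int, TreeNode]
    root_id: int = 0

    @property
    def leaf_ids(self) -> list[int]:
        return [nid for nid in sorted(self.nodes) if self.nodes[nid].is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_labels(self) -> dict[int, str]:
        return {nid: self.nodes[nid].label or "all" for nid in self.leaf_ids}

    def route(self, row: Mapping[str, str]) -> int:
        node = self.nodes[self.root_id]
        while not node.is_leaf:
            value = str(row[node.split_var])
            nxt = None
            for cid in node.children:
                child = self.nodes[cid]
                if value in (child.branch_categories or ()):
                    nxt = child
                    break
            if nxt is None:  # unseen category: largest child (by n)
                nxt = max(
                    (self.nodes[cid] for cid in node.children), key=lambda c: c.n
                )
            node = nxt
        return node.id

    def apply(self, X: pd.DataFrame) -> np.ndarray:
        """Leaf id for every record."""
        cols = {c: _as_str(X[c]) for c in X.columns}
        frame = pd.DataFrame(cols)
        return np.array([self.route(row) for row in frame.to_dict("records")])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Leaf mean cost for every record."""
        means = {nid: self.nodes[nid].mean for nid in self.leaf_ids}
        return np.array([means[nid] for nid in self.apply(X)])

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "target": self.target,
            "root_id": self.root_id,
            "nodes": [asdict(n) for n in self.nodes.values()],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "TreeModel":
        nodes = {}
        for nd in payload["nodes"]:
            nd = dict(nd)
            if nd.get("branch_categories") is not None:
                nd["branch_categories"] = tuple(nd["branch_categories"])
            node = TreeNode(**nd)
            nodes[node.id] = node
        return cls(payload["algorithm"], payload["target"], nodes, payload["root_id"])

    @classmethod
    def from_json(cls, path: str | Path) -> "TreeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _condition_label(var: str, cats: Sequence[str]) -> str:
    if len(cats) == 1:
        return f"{var}={cats[0]}"
    return f"{var}∈{{{','.join(cats)}}}"


# ---------------------------------------------------------------------------
# estimators


class _BaseTree(BaseEstimator, RegressorMixin):
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise InputError("tree is not fitted")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict(X)

    def apply(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return self.model_.apply(X)

    @property
    def n_leaves_(self) -> int:
        self._check_fitted()
        return self.model_.n_leaves


class CHAIDRegressor(_BaseTree):
    """Exhaustive-CHAID regression tree for a continuous target over
    categorical predictors; see the module docstring for the algorithm."""

    def __init__(
        self,
        alpha_split: float = 0.05,
        bonferroni: bool = True,
        max_depth: int = 5,
        min_parent_n: int = 100,
        min_child_n: int = 50,
        predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
        scales: Mapping[str, str] | None = None,
        exhaustive_limit: int = 6,
    ):
        self.alpha_split = alpha_split
        self.bonferroni = bonferroni
        self.max_depth = max_depth
        self.min_parent_n = min_parent_n
        self.min_child_n = min_child_n
        self.predictors = predictors
        self.scales = scales
        self.exhaustive_limit = exhaustive_limit

    def _config(self) -> TreeConfig:
        return TreeConfig(
            algorithm="e-chaid",
            alpha_split=self.alpha_split,
            bonferroni=self.bonferroni,
            max_depth=self.max_depth,
            min_parent_n=self.min_parent_n,
            min_child_n=self.min_child_n,
            predictors=tuple(self.predictors),
            scales=dict(self.scales) if self.scales is not None else dict(DEFAULT_SCALES),
            exhaustive_limit=self.exhaustive_limit,
        )

    def fit(self, X: pd.DataFrame, y: Sequence[float]):
        y = np.asarray(y, dtype=float)
        if len(X) == 0:
            raise InputError("empty cohort")
        config = self._config()
        nodes: dict[int, TreeNode] = {}
        counter = [0]

        def new_node(idx: np.ndarray, parent, depth, branch, label) -> TreeNode:
            nid = counter[0]
            counter[0] += 1
            yi = y[idx]
            node = TreeNode(
                id=nid, parent=parent, depth=depth, n=int(idx.sum()),
                mean=float(yi.mean()), median=float(np.median(yi)),
                branch_categories=branch, label=label,
            )
            nodes[nid] = node
            return node

        def grow(node: TreeNode, idx: np.ndarray):
            if node.depth >= config.max_depth or node.n < config.min_parent_n:
                return
            split = select_split(X.loc[idx], y[idx], config)
            if split is None:
                return
            col = _as_str(X[split.predictor])
            node.split_var = split.predictor
            node.p_adjusted = split.p_adjusted
            node.statistic = split.statistic
            for cats in split.partition:
                child_idx = idx & col.isin(cats).to_numpy()
                cond = _condition_label(split.predictor, cats)
                label = f"{node.label} & {cond}" if node.label else cond
                child = new_node(child_idx, node.id, node.depth + 1, tuple(cats), label)
                node.children.append(child.id)
            for cid in list(node.children):
                child = nodes[cid]
                mask = idx & col.isin(child.branch_categories).to_numpy()
                grow(child, mask)

        all_idx = np.ones(len(X), dtype=bool)
        # positional masks require a positional frame
        X = X.reset_index(drop=True)
        root = new_node(all_idx, None, 0, None, "")
        grow(root, all_idx)
        self.model_ = TreeModel("e-chaid", config.target, nodes)
        self.leaf_assignment_ = self.model_.apply(X)
        return self


class CARTRegressor(_BaseTree):
    """Binary regression tree over categorical predictors: each split is the
    (predictor, two-set category partition) that maximally reduces the
    within-node sum of squared errors, with optional weakest-link pruning."""

    def __init__(
        self,
        max_depth: int = 5,
        min_parent_n: int = 100,
        min_child_n: int = 50,
        predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
        scales: Mapping[str, str] | None = None,
        ccp_alpha: float | None = None,
    ):
        self.max_depth = max_depth
        self.min_parent_n = min_parent_n
        self.min_child_n = min_child_n
        self.predictors = predictors
        self.scales = scales
        self.ccp_alpha = ccp_alpha

    def fit(self, X: pd.DataFrame, y: Sequence[float]):
        y = np.asarray(y, dtype=float)
        if len(X) == 0:
            raise InputError("empty cohort")
        X = X.reset_index(drop=True)
        scales = dict(self.scales) if self.scales is not None else dict(DEFAULT_SCALES)
        nodes: dict[int, TreeNode] = {}
        counter = [0]

        def sse(v: np.ndarray) -> float:
            return float(((v - v.mean()) ** 2).sum()) if v.size else 0.0

        def best_split(idx: np.ndarray):
            yi = y[idx]
            parent_sse = sse(yi)
            best = None  # (gain, predictor_order, left_cats, right_cats)
            for p_order, predictor in enumerate(self.predictors):
                col = _as_str(X[predictor])[idx]
                observed = [lv for lv in _observed_order(predictor, col) if (col == lv).any()]
                if len(observed) < 2:
                    continue
                if scales.get(predictor, "nominal") == "ordinal":
                    partitions = [
                        (observed[: i + 1], observed[i + 1 :])
                        for i in range(len(observed) - 1)
                    ]
                else:
                    partitions = []
                    # left always holds the first category; the mask picks the
                    # rest, excluding the full set (2^(c-1) - 1 binary splits)
                    for mask in range((1 << (len(observed) - 1)) - 1):
                        left = [observed[0]] + [
                            observed[i]
                            for i in range(1, len(observed))
                            if mask >> (i - 1) & 1
                        ]
                        right = [lv for lv in observed if lv not in left]
                        partitions.append((left, right))
                for left, right in partitions:
                    lmask = col.isin(left).to_numpy()
                    yl, yr = yi[lmask], yi[~lmask]
                    if yl.size < self.min_child_n or yr.size < self.min_child_n:
                        continue
                    gain = parent_sse - sse(yl) - sse(yr)
                    key = (gain, -p_order)
                    if best is None or key > best[0]:
                        best = (key, predictor, tuple(left), tuple(right), gain)
            return best

        def new_node(idx, parent, depth, branch, label) -> TreeNode:
            nid = counter[0]
            counter[0] += 1
            yi = y[idx]
            node = TreeNode(
                id=nid, parent=parent, depth=depth, n=int(idx.sum()),
                mean=float(yi.mean()), median=float(np.median(yi)),
                branch_categories=branch, label=label,
            )
            nodes[nid] = node
            return node

        def grow(node: TreeNode, idx: np.ndarray):
            if node.depth >= self.max_depth or node.n < self.min_parent_n:
                return
            found = best_split(idx)
            if found is None or found[4] <= 0:
                return
            _, predictor, left, right, gain = found
            col = _as_str(X[predictor])
            node.split_var = predictor
            node.statistic = gain
            for cats in (left, right):
                cmask = idx & col.isin(cats).to_numpy()
                cond = _condition_label(predictor, cats)
                label = f"{node.label} & {cond}" if node.label else cond
                child = new_node(cmask, node.id, node.depth + 1, cats, label)
                node.children.append(child.id)
                grow(child, cmask)

        all_idx = np.ones(len(X), dtype=bool)
        root = new_node(all_idx, None, 0, None, "")
        grow(root, all_idx)
        model = TreeModel("cart", "total_cost", nodes)
        if self.ccp_alpha is not None:
            model = _prune_ccp(model, X, y, self.ccp_alpha)
        self.model_ = model
        self.leaf_assignment_ = self.model_.apply(X)
        return self


def _prune_ccp(model: TreeModel, X: pd.DataFrame, y: np.ndarray, alpha: float) -> TreeModel:
    """Weakest-link cost-complexity pruning: collapse internal nodes whose
    per-leaf SSE improvement is at most ``alpha``."""
    leaf_of = model.apply(X)

    def subtree_leaves(nid: int) -> list[int]:
        node = model.nodes[nid]
        if node.is_leaf:
            return [nid]
        return [l for cid in node.children for l in subtree_leaves(cid)]

    def node_mask(nid: int) -> np.ndarray:
        return np.isin(leaf_of, subtree_leaves(nid))

    def sse_of(mask: np.ndarray) -> float:
        v = y[mask]
        return float(((v - v.mean()) ** 2).sum()) if v.size else 0.0

    changed = True
    while changed:
        changed = False
        internal = [nid for nid in model.nodes if not model.nodes[nid].is_leaf]
        best = None
        for nid in internal:
            leaves = subtree_leaves(nid)
            mask = node_mask(nid)
            r_node = sse_of(mask)
            r_sub = sum(sse_of(leaf_of == l) for l in leaves)
            g = (r_node - r_sub) / max(len(leaves) - 1, 1)
            if best is None or g < best[0]:
                best = (g, nid)
        if best is not None and best[0] <= alpha and len(internal) > 0:
            _, nid = best
            for l in subtree_leaves(nid):
                leaf_of[leaf_of == l] = nid
            drop = set()

            def collect(x):
                for cid in model.nodes[x].children:
                    drop.add(cid)
                    collect(cid)

            collect(nid)
            node = model.nodes[nid]
            node.children = []
            node.split_var = None
            node.statistic = None
            node.p_adjusted = None
            for d in drop:
                del model.nodes[d]
            changed = True
    return model


# ---------------------------------------------------------------------------
# functional wrappers and model comparison


def grow_tree(cohort: pd.DataFrame, config: TreeConfig | None = None) -> TreeModel:
    """Fit an exhaustive-CHAID grouping tree on a cleaned cohort."""
    config = config or TreeConfig()
    est = CHAIDRegressor(
        alpha_split=config.alpha_split,
        bonferroni=config.bonferroni,
        max_depth=config.max_depth,
        min_parent_n=config.min_parent_n,
        min_child_n=config.min_child_n,
        predictors=config.predictors,
        scales=dict(config.scales),
        exhaustive_limit=config.exhaustive_limit,
    ).fit(cohort, cohort[config.target])
    return est.model_


def grow_cart(cohort: pd.DataFrame, config: TreeConfig | None = None) -> TreeModel:
    """Fit the CART baseline on a cleaned cohort."""
    config = config or TreeConfig(algorithm="cart")
    est = CARTRegressor(
        max_depth=config.max_depth,
        min_parent_n=config.min_parent_n,
        min_child_n=config.min_child_n,
        predictors=config.predictors,
        scales=dict(config.scales),
        ccp_alpha=config.ccp_alpha,
    ).fit(cohort, cohort[config.target])
    return est.model_


@dataclass(frozen=True)
class ModelComparison:
    """Training-sample agreement between leaf-mean predictions and costs."""

    model: str
    correlation: float
    mae: float
    error_sd: float
    n_groups: int
    degenerate: bool = False  # single leaf: correlation undefined, set to 0


def compare_models(
    models: Sequence[TreeModel], cohort: pd.DataFrame, target: str = "total_cost"
) -> list[ModelComparison]:
    """Pearson correlation, MAE, SD of errors and group count per model."""
    y = cohort[target].to_numpy(dtype=float)
    out = []
    for model in models:
        pred = model.predict(cohort)
        errors = y - pred
        degenerate = bool(np.std(pred) == 0)
        corr = 0.0 if degenerate else float(np.corrcoef(pred, y)[0, 1])
        out.append(
            ModelComparison(
                model=model.algorithm,
                correlation=corr,
                mae=float(np.abs(errors).mean()),
                error_sd=float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0,
                n_groups=model.n_leaves,
                degenerate=degenerate,
            )
        )
    return out


def comparison_table(comparisons: Sequence[ModelComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": c.model,
                "linear_correlation": round(c.correlation, 3),
                "mean_absolute_error": round(c.mae, 3),
                "error_sd": round(c.error_sd, 3),
                "n_groups": c.n_groups,
            }
            for c in comparisons
        ]
    )
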