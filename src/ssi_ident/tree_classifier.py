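"""Model 5: classification tree (CART) with minimal cost-complexity pruning.

Binary splits are chosen by Gini-impurity improvement over all variables and
all candidate thresholds (midpoints between consecutive distinct sorted
values); routing is "value <= threshold goes left". Growth stops at purity,
at the minimum-cases rules, or at the depth cap. Pruning is Breiman-style
weakest-link (minimal cost-complexity): internal nodes are collapsed in
order of g(t) = [R(t) - R(T_t)] / (|leaves(T_t)| - 1), where R is the
training misclassification count, producing a nested subtree family indexed
by strictly increasing complexity parameters alpha. The deployed subtree is
chosen by stratified V-fold cross-validation: each candidate alpha (geometric
means of consecutive alphas in the family) is evaluated by growing a tree on
each training fold, pruning it at that alpha, and scoring the held-out fold;
the alpha with minimal CV misclassification cost wins (a 1-SE rule is
available as an option).

Misclassification costs are equal for the two classes and priors are the
training-data class frequencies. All tie-breaks are fixed: equal-improvement
splits resolve by variable input order then smaller threshold; an equal-cost
leaf predicts non-SSI (the prevalent class); equal-CV-cost alphas resolve to
the largest alpha (smallest tree).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .claims_model import PatientEpisode, SecondLineCatalog
from .rule_classifiers import ClassifierResult

__all__ = [
    "GrowthParams",
    "CartNode",
    "CartTree",
    "PruningStep",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "cost_complexity_sequence",
    "prune_at",
    "select_subtree_cv",
    "predict_tree",
    "TREE_VARIABLES",
]

#: Variables offered to the tree: the same six continuous surrogate
#: variables as model 4; the fitted tree decides which matter.
TREE_VARIABLES = [
    "los",
    "antibiotic_types",
    "cefazolin_ddd",
    "vessels_obstructed",
    "antibiotic_ddd_total",
    "second_line",
]

_EPS = 1e-12


@dataclass(frozen=True)
class GrowthParams:
    """Stopping rules for tree growth (scaled for cohorts of ~1,000)."""

    min_split: int = 20   # minimum cases at a node to attempt a split
    min_leaf: int = 7     # minimum cases in each child
    max_depth: int = 5

    def __post_init__(self) -> None:
        if self.min_split < 2 or self.min_leaf < 1 or self.max_depth < 1:
            raise ValueError("invalid growth parameters")


@dataclass
class CartNode:
    node_id: int
    n: int
    class_counts: tuple[int, int]  # (non-SSI, SSI)
    split_variable: str | None = None
    split_threshold: float | None = None
    left: "CartNode | None" = None
    right: "CartNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def p_ssi(self) -> float:
        return self.class_counts[1] / self.n

    @property
    def predicted_class(self) -> int:
        # tie predicts non-SSI: the prevalent class under the cohort prior
        return int(self.class_counts[1] > self.class_counts[0])

    @property
    def resubstitution_cost(self) -> int:
        """Training misclassification count at this node as a leaf."""
        return min(self.class_counts)

    def leaves(self) -> list["CartNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["CartNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def subtree_cost(self) -> int:
        return sum(leaf.resubstitution_cost for leaf in self.leaves())

    def collapse(self) -> None:
        self.split_variable = None
        self.split_threshold = None
        self.left = None
        self.right = None


@dataclass
class PruningStep:
    alpha: float
    n_leaves: int
    cv_cost: float | None = None


@dataclass
class CartTree:
    root: CartNode
    variables: list[str]
    growth_params: GrowthParams
    pruning_sequence: list[PruningStep] = field(default_factory=list)
    selected_alpha: float | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def predict_row(self, values: dict[str, float]) -> CartNode:
        node = self.root
        while not node.is_leaf:
            if node.split_variable not in values:
                raise ValueError(f"missing split variable {node.split_variable!r}")
            v = values[node.split_variable]
            node = node.left if v <= node.split_threshold else node.right
        return node

    def predict_frame(self, design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(predictions, leaf SSI fractions) for every row of ``design``."""
        used = {n.split_variable for n in self.root.internal_nodes()}
        missing = sorted(v for v in used if v not in design.columns)
        if missing:
            raise ValueError(f"design is missing split variables: {missing}")
        preds = np.empty(len(design), dtype=int)
        scores = np.empty(len(design), dtype=float)
        cols = {v: np.asarray(design[v], dtype=float) for v in used}
        for i in range(len(design)):
            leaf = self.predict_row({v: cols[v][i] for v in used})
            preds[i] = leaf.predicted_class
            scores[i] = leaf.p_ssi
        return preds, scores

    # -- export ------------------------------------------------------------

    def to_dict(self) -> dict:
        def _node(n: CartNode) -> dict:
            d = {
                "node_id": n.node_id,
                "n": n.n,
                "class_counts": list(n.class_counts),
                "p_ssi": n.p_ssi,
                "predicted_class": n.predicted_class,
            }
            if not n.is_leaf:
                d["split_variable"] = n.split_variable
                d["split_threshold"] = n.split_threshold
                d["left"] = _node(n.left)
                d["right"] = _node(n.right)
            return d

        return {
            "variables": self.variables,
            "growth_params": {
                "min_split": self.growth_params.min_split,
                "min_leaf": self.growth_params.min_leaf,
                "max_depth": self.growth_params.max_depth,
            },
            "pruning_sequence": [
                {"alpha": s.alpha, "n_leaves": s.n_leaves, "cv_cost": s.cv_cost}
                for s in self.pruning_sequence
            ],
            "selected_alpha": self.selected_alpha,
            "root": _node(self.root),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_text(self) -> str:
        """Indented rendering comparable to published tree diagrams."""
        lines: list[str] = []

        def _walk(node: CartNode, depth: int, label: str) -> None:
            pad = "  " * depth
            cls = "SSI" if node.predicted_class == 1 else "non-SSI"
            lines.append(
                f"{pad}{label}node {node.node_id}: n={node.n} "
                f"[non-SSI={node.class_counts[0]}, SSI={node.class_counts[1]}] "
                f"p(SSI)={node.p_ssi:.3f} -> {cls}"
            )
            if not node.is_leaf:
                _walk(node.left, depth + 1, f"{node.split_variable} <= {node.split_threshold:g}: ")
                _walk(node.right, depth + 1, f"{node.split_variable} > {node.split_threshold:g}: ")

        _walk(self.root, 0, "")
        return "\n".join(lines)


def gini_impurity(class_counts: Sequence[int]) -> float:
    """Two-class Gini impurity 1 - sum(p_k^2), in [0, 0.5]."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    variables: Sequence[str],
    params: GrowthParams,
) -> tuple[str, float, float] | None:
    """Best (variable, threshold, Gini improvement), or None when no
    eligible split improves impurity.

    Thresholds are midpoints between consecutive distinct sorted values;
    children below ``min_leaf`` are ineligible; ties resolve by variable
    input order, then by smaller threshold.
    """
    n = len(y)
    counts = (int((y == 0).sum()), int((y == 1).sum()))
    parent_gini = gini_impurity(counts)
    if parent_gini <= 0.0 or n < params.min_split:
        return None

    best: tuple[str, float, float] | None = None
    pos_total = counts[1]
    for j, name in enumerate(variables):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        # boundaries between distinct consecutive values
        distinct = np.flatnonzero(xs[1:] != xs[:-1])
        if distinct.size == 0:
            continue
        nl = distinct + 1
        nr = n - nl
        eligible = (nl >= params.min_leaf) & (nr >= params.min_leaf)
        if not np.any(eligible):
            continue
        cum_pos = np.cumsum(ys)[distinct]
        left_pos = cum_pos
        right_pos = pos_total - left_pos
        gl = 1.0 - ((left_pos / nl) ** 2 + ((nl - left_pos) / nl) ** 2)
        gr = 1.0 - ((right_pos / nr) ** 2 + ((nr - right_pos) / nr) ** 2)
        improvement = parent_gini - (nl / n) * gl - (nr / n) * gr
        improvement[~eligible] = -np.inf
        k = int(np.argmax(improvement))  # first max => smallest threshold
        if improvement[k] <= _EPS:
            continue
        threshold = float((xs[distinct[k]] + xs[distinct[k] + 1]) / 2.0)
        if best is None or improvement[k] > best[2] + _EPS:
            best = (name, threshold, float(improvement[k]))
    return best


def grow_tree(
    data: pd.DataFrame,
    variables: Sequence[str] = tuple(TREE_VARIABLES),
    params: GrowthParams | None = None,
    outcome: str = "ssi_label",
) -> CartTree:
    """Grow an unpruned tree by recursive best-first Gini splitting."""
    if len(data) == 0:
        raise ValueError("data must be non-empty")
    params = params or GrowthParams()
    variables = [v for v in variables if v in data.columns]
    if not variables:
        raise ValueError("no usable split variables in data")
    X = np.asarray(data[variables], dtype=float)
    y = np.asarray(data[outcome], dtype=int)

    counter = {"next_id": 0}

    def _build(idx: np.ndarray, depth: int) -> CartNode:
        node_id = counter["next_id"]
        counter["next_id"] += 1
        yi = y[idx]
        counts = (int((yi == 0).sum()), int((yi == 1).sum()))
        node = CartNode(node_id=node_id, n=len(idx), class_counts=counts)
        if depth >= params.max_depth or min(counts) == 0 or len(idx) < params.min_split:
            return node
        split = best_split(X[idx], yi, variables, params)
        if split is None:
            return node
        name, threshold, _gain = split
        j = variables.index(name)
        go_left = X[idx, j] <= threshold
        node.split_variable = name
        node.split_threshold = threshold
        node.left = _build(idx[go_left], depth + 1)
        node.right = _build(idx[~go_left], depth + 1)
        return node

    root = _build(np.arange(len(y)), 0)
    return CartTree(root=root, variables=list(variables), growth_params=params)


# ---------------------------------------------------------------------------
# Minimal cost-complexity pruning
# ---------------------------------------------------------------------------

def _weakest_links(root: CartNode) -> tuple[float, list[CartNode]]:
    """Minimum g(t) over internal nodes and every node attaining it."""
    gs = []
    for node in root.internal_nodes():
        n_leaves = len(node.leaves())
        g = (node.resubstitution_cost - node.subtree_cost()) / (n_leaves - 1)
        gs.append((g, node))
    g_min = min(g for g, _ in gs)
    return g_min, [node for g, node in gs if g <= g_min + _EPS]


def _prune_tree_at(root: CartNode, alpha: float) -> None:
    """Collapse (in place) every weakest link with g <= alpha."""
    while not root.is_leaf:
        g_min, nodes = _weakest_links(root)
        if g_min > alpha + _EPS:
            break
        for node in nodes:
            if not node.is_leaf:  # may already be gone via an ancestor
                node.collapse()


def prune_at(tree: CartTree, alpha: float) -> CartTree:
    """The cost-complexity optimal subtree for penalty ``alpha`` (a copy)."""
    pruned = copy.deepcopy(tree)
    if not pruned.root.is_leaf:
        _prune_tree_at(pruned.root, alpha)
    return pruned


def cost_complexity_sequence(tree: CartTree) -> list[PruningStep]:
    """Weakest-link pruning schedule: one step per collapse event.

    Each step records the complexity parameter alpha at which the collapse
    happens and the number of leaves remaining afterwards. Alphas strictly
    increase and leaf counts strictly decrease; a root-only tree yields an
    empty schedule.
    """
    work = copy.deepcopy(tree.root)
    steps: list[PruningStep] = []
    while not work.is_leaf:
        g_min, _ = _weakest_links(work)
        _prune_tree_at(work, g_min)
        steps.append(PruningStep(alpha=float(g_min), n_leaves=len(work.leaves())))
    return steps


def _stratified_folds(y: np.ndarray, v: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..v-1) stratified by class, round-robin after shuffle."""
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % v
    return folds


def select_subtree_cv(
    data: pd.DataFrame,
    variables: Sequence[str] = tuple(TREE_VARIABLES),
    params: GrowthParams | None = None,
    v: int = 10,
    seed: int = 0,
    rule: str = "min",
    outcome: str = "ssi_label",
) -> CartTree:
    """Grow on all data, pick alpha by stratified V-fold CV, prune, return.

    ``rule='min'`` picks the alpha with minimal summed held-out
    misclassification cost (ties toward the larger alpha / smaller tree);
    ``rule='1se'`` picks the largest alpha within one standard error of the
    minimum CV error rate.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    if v < 2:
        raise ValueError("v must be >= 2")
    params = params or GrowthParams()
    y = np.asarray(data[outcome], dtype=int)
    n_min = min(int((y == 0).sum()), int((y == 1).sum()))
    if n_min < 2:
        raise ValueError("both classes must have at least 2 cases for cross-validation")
    if n_min < v:
        warnings.warn(
            f"reducing folds from {v} to {n_min} so every fold holds both classes",
            UserWarning,
        )
        v = n_min

    full = grow_tree(data, variables, params, outcome)
    steps = cost_complexity_sequence(full)
    full.pruning_sequence = steps
    if not steps:
        full.selected_alpha = 0.0
        return full

    alphas = [s.alpha for s in steps]
    candidates = [0.0]
    candidates += [float(np.sqrt(max(a, 0.0) * max(b, 0.0))) for a, b in zip(alphas, alphas[1:])]
    candidates.append(alphas[-1])
    candidates = sorted(set(candidates))

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, v, rng)
    cv_cost = np.zeros(len(candidates))
    n_total = len(data)
    for f in range(v):
        train = data[folds != f]
        test = data[folds == f]
        fold_tree = grow_tree(train, variables, params, outcome)
        y_test = np.asarray(test[outcome], dtype=int)
        for ci, alpha in enumerate(candidates):
            pruned = prune_at(fold_tree, alpha)
            preds, _ = pruned.predict_frame(test)
            cv_cost[ci] += int((preds != y_test).sum())

    best_cost = cv_cost.min()
    if rule == "min":
        chosen = max(a for a, c in zip(candidates, cv_cost) if c <= best_cost + _EPS)
    else:
        err = best_cost / n_total
        se = np.sqrt(err * (1.0 - err) / n_total) * n_total
        chosen = max(a for a, c in zip(candidates, cv_cost) if c <= best_cost + se + _EPS)

    pruned = prune_at(full, chosen)
    # attach CV costs to the pruning schedule at the matching intervals
    for step in steps:
        nearest = int(np.argmin([abs(a - step.alpha) for a in candidates]))
        step.cv_cost = float(cv_cost[nearest])
    pruned.pruning_sequence = steps
    pruned.selected_alpha = float(chosen)
    return pruned


def predict_tree(tree: CartTree, episode: PatientEpisode,
                 catalog: SecondLineCatalog | None = None) -> ClassifierResult:
    """Route one episode to its leaf; score is the leaf's SSI fraction."""
    if tree.root is None:
        raise ValueError("tree has no root")
    catalog = catalog or SecondLineCatalog()
    values = {
        "los": float(episode.los),
        "antibiotic_types": float(episode.antibiotic_types),
        "cefazolin_ddd": float(episode.cefazolin_ddd),
        "vessels_obstructed": float(episode.vessels_obstructed),
        "antibiotic_ddd_total": float(episode.antibiotic_ddd_total),
        "second_line": float(any(c in catalog.codes for c in episode.atc_codes_used)),
    }
    leaf = tree.predict_row(values)
    return ClassifierResult(episode.patient_id, leaf.predicted_class, "cart", score=leaf.p_ssi)
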