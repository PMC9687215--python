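"""Random-forest transcript selection: the four-step multi-session protocol.

A session winnows a transcript list in four steps: (1) grow a forest on all
features, (2) keep the top-ranked features by Gini importance, (3) grow a
larger forest on the survivors, (4) save the final top-ranked panel together
with the confusion matrix of the stage-3 forest on an independent test set.
Many sessions are run under distinct seeds and the session with the highest
test sensitivity (ties: higher specificity, then lower session index) is
selected.

Trees are standard CART classification trees: bootstrap of size n per tree,
at each node a random draw of f features without replacement (default
f = floor(sqrt(F))), Gini split criterion with midpoint thresholds, depth
cap, and a minimum leaf occupancy. Feature importance is the sum over nodes
splitting on the feature of (node in-bag fraction x impurity decrease),
averaged over trees. Out-of-bag majority votes give a generalization-error
diagnostic; no per-tree selection is performed.

Every quantity is a pure function of the data and the seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _tree
from .expression import ExpressionDataset

__all__ = [
    "SessionConfig",
    "Tree",
    "Forest",
    "ConfusionMatrix",
    "SessionResult",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "build_forest",
    "predict_majority",
    "feature_importance",
    "oob_error",
    "run_session",
    "run_selection",
    "select_best",
    "write_sessions_json",
    "write_panel_tsv",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SessionConfig:
    """Shape of one selection session and of the multi-session sweep.

    Defaults follow the full protocol (1000-tree screen, keep 500, 5000-tree
    refinement, keep 20, 100 sessions). ``reduced()`` gives a desk-scale
    profile with the same structure.
    """

    n_trees_stage1: int = 1000
    top_k_stage2: int = 500
    n_trees_stage3: int = 5000
    top_k_final: int = 20
    n_sessions: int = 100
    max_depth: int = 20
    min_leaf: int = 1
    feature_subset_rule: str = "sqrt"  # sqrt | log2 | fixed:<k>
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_trees_stage1",
            "top_k_stage2",
            "n_trees_stage3",
            "top_k_final",
            "n_sessions",
            "min_leaf",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.top_k_final > self.top_k_stage2:
            raise ValueError("top_k_final must not exceed top_k_stage2")
        self.subset_size(1_000_000)  # validates the rule string

    @classmethod
    def reduced(cls, **overrides) -> "SessionConfig":
        """Desk-scale profile: 200/100/500-tree stages, 10 sessions."""
        defaults = dict(
            n_trees_stage1=200, top_k_stage2=100, n_trees_stage3=500,
            top_k_final=20, n_sessions=10,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def subset_size(self, n_features: int) -> int:
        """Features drawn per node (f) for a total feature count F."""
        rule = self.feature_subset_rule
        if rule == "sqrt":
            f = int(math.floor(math.sqrt(n_features)))
        elif rule == "log2":
            f = int(math.floor(math.log2(n_features))) if n_features > 1 else 1
        elif rule.startswith("fixed:"):
            f = int(rule.split(":", 1)[1])
            if f < 1:
                raise ValueError("fixed feature subset size must be >= 1")
        else:
            raise ValueError(f"unknown feature_subset_rule {rule!r}")
        return max(1, min(f, n_features))


@dataclass
class Tree:
    """One grown tree as flat node arrays plus its in-bag sample counts."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    decrease: np.ndarray
    node_n: np.ndarray
    count0: np.ndarray
    count1: np.ndarray
    inbag: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_inbag(self) -> int:
        return int(self.inbag.sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _tree.predict_tree(
            self.feature, self.threshold, self.left, self.right,
            self.count0, self.count1, X,
        )

    def depth(self) -> int:
        depths = np.zeros(self.n_nodes, dtype=int)
        for node in range(self.n_nodes):
            if self.feature[node] >= 0:
                depths[self.left[node]] = depths[node] + 1
                depths[self.right[node]] = depths[node] + 1
        return int(depths.max())


@dataclass
class Forest:
    """Bagged ensemble over a fixed, ordered feature list."""

    trees: list[Tree]
    feature_ids: list[str]
    n_train: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def inbag_matrix(self) -> np.ndarray:
        return np.stack([t.inbag for t in self.trees])


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 accuracy tally with disease as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


@dataclass
class SessionResult:
    """Outcome of one four-step session: the saved panel and its test scores."""

    session_index: int
    seed: int
    panel: pd.DataFrame  # columns: feature_id, importance; ordered by rank
    confusion: ConfusionMatrix
    oob_error: float
    stage2_features: list[str]

    @property
    def panel_features(self) -> list[str]:
        return self.panel["feature_id"].tolist()

    @property
    def sensitivity(self) -> float:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> float:
        return self.confusion.specificity


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def gini_impurity(class_proportions) -> float:
    """Gini impurity 1 - sum(p_i^2) of a node's class proportions."""
    p = np.asarray(class_proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("class proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1 (got {p.sum()!r})")
    return float(1.0 - np.sum(p * p))


def best_split(values, labels, min_leaf: int = 1):
    """Best Gini split of one feature at a node, or ``None`` if unsplittable.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; the returned decrease is parent impurity minus the
    child-size-weighted mean child impurity. Both children must hold at
    least ``min_leaf`` samples.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    m = len(v)
    if m < 2 or len(np.unique(y)) < 2:
        return None
    order = np.argsort(v, kind="stable")
    v_sorted, y_sorted = v[order], (y[order] == y.max()).astype(int)
    ones = int(y_sorted.sum())
    p1 = ones / m
    g_parent = 2.0 * p1 * (1.0 - p1)
    best = None
    left_ones = 0
    for k in range(1, m):
        left_ones += y_sorted[k - 1]
        if v_sorted[k] <= v_sorted[k - 1]:
            continue
        if k < min_leaf or m - k < min_leaf:
            continue
        pl, pr = left_ones / k, (ones - left_ones) / (m - k)
        dec = g_parent - (k * 2 * pl * (1 - pl) + (m - k) * 2 * pr * (1 - pr)) / m
        if best is None or dec > best[1]:
            best = (0.5 * (v_sorted[k - 1] + v_sorted[k]), dec)
    if best is None or best[1] <= 0:
        return None
    return best


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    feature_subset_size: int,
    max_depth: int = 20,
    min_leaf: int = 1,
    seed: int = 0,
    bootstrap: bool = False,
) -> Tree:
    """Grow one tree on (samples x features) ``X``; pure function of ``seed``."""
    if len(X) == 0:
        raise ValueError("training subset is empty")
    arrays = _tree.build_tree_arrays(X, y, feature_subset_size, max_depth, min_leaf, seed, bootstrap)
    return Tree(*arrays)


def _as_matrix(data) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(data, ExpressionDataset):
        return data.X, data.y, list(map(str, data.probe_ids))
    raise TypeError("expected an ExpressionDataset")


def _tree_seeds(rng_or_seed, n: int) -> np.ndarray:
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    return rng.integers(0, _MAX_SEED, size=n)


def build_forest(train: ExpressionDataset, n_trees: int, config: SessionConfig, rng) -> Forest:
    """Bag ``n_trees`` trees, each on its own bootstrap of the training set.

    ``rng`` is an integer seed or a ``numpy.random.Generator``; per-tree
    seeds are derived from it, so the forest is reproducible.
    """
    X, y, feature_ids = _as_matrix(train)
    n0, n1 = train.class_counts()
    if n0 == 0 or n1 == 0:
        raise ValueError("training data must contain both classes")
    f = config.subset_size(X.shape[1])
    seeds = _tree_seeds(rng, n_trees)
    trees = [
        grow_tree(X, y, f, config.max_depth, config.min_leaf, seed=int(s), bootstrap=True)
        for s in seeds
    ]
    return Forest(trees=trees, feature_ids=feature_ids, n_train=len(X))


def predict_majority(forest: Forest, data) -> np.ndarray:
    """Modal vote over all trees; exact ties go to disease (class 1)."""
    if isinstance(data, ExpressionDataset):
        missing = [f for f in forest.feature_ids if f not in set(map(str, data.probe_ids))]
        if missing:
            raise KeyError(f"samples lack forest features: {missing[:10]}")
        X = data.subset_probes(forest.feature_ids).X
    else:
        X = np.asarray(data, dtype=float)
        if X.shape[1] != len(forest.feature_ids):
            raise KeyError(
                f"expected {len(forest.feature_ids)} features, got {X.shape[1]}"
            )
    votes = np.zeros(len(X), dtype=int)
    for tree in forest.trees:
        votes += tree.predict(X)
    return (2 * votes >= forest.n_trees).astype(np.int8)


def feature_importance(forest: Forest) -> pd.DataFrame:
    """Per-feature weighted Gini importance, ranked.

    Importance(feature) = sum over nodes splitting on it of
    (node in-bag fraction x impurity decrease), divided by the tree count.
    Ranking is by descending importance, ties broken by ascending feature
    ID, so the ordering is deterministic. ``n_splits`` counts the nodes
    that used the feature.
    """
    if forest.n_trees == 0:
        raise ValueError("forest is empty")
    n_features = len(forest.feature_ids)
    # per-tree contributions, combined with exact summation so the result is
    # independent of tree order
    per_tree = np.zeros((forest.n_trees, n_features))
    n_splits = np.zeros(n_features, dtype=int)
    for t, tree in enumerate(forest.trees):
        internal = tree.feature >= 0
        feats = tree.feature[internal]
        contrib = tree.node_n[internal] * tree.decrease[internal] / tree.n_inbag
        np.add.at(per_tree[t], feats, contrib)
        np.add.at(n_splits, feats, 1)
    imp = np.array([math.fsum(per_tree[:, j]) for j in range(n_features)])
    imp /= forest.n_trees
    table = pd.DataFrame(
        {"feature_id": forest.feature_ids, "importance": imp, "n_splits": n_splits}
    )
    table = table.sort_values(
        ["importance", "feature_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def oob_error(forest: Forest, train: ExpressionDataset) -> float:
    """Misclassification rate of out-of-bag majority votes on the training set.

    Each sample is voted on only by trees whose bootstrap excluded it;
    samples in-bag for every tree are skipped.
    """
    X, y, _ = _as_matrix(train)
    votes1 = np.zeros(len(X), dtype=int)
    votable = np.zeros(len(X), dtype=int)
    for tree in forest.trees:
        oob = tree.inbag == 0
        if not oob.any():
            continue
        pred = tree.predict(X[oob])
        votes1[oob] += pred
        votable[oob] += 1
    usable = votable > 0
    if not usable.any():
        raise ValueError("no sample is out-of-bag for any tree")
    pred = (2 * votes1[usable] >= votable[usable]).astype(int)
    return float(np.mean(pred != y[usable]))


# ---------------------------------------------------------------------------
# the four-step session protocol
# ---------------------------------------------------------------------------

def _top_features(importance: pd.DataFrame, k: int) -> list[str]:
    return importance["feature_id"].head(k).tolist()


def run_session(
    train: ExpressionDataset,
    test: ExpressionDataset,
    config: SessionConfig,
    session_seed: int,
    session_index: int = 0,
) -> SessionResult:
    """One four-step winnowing session, fully determined by ``session_seed``.

    (1) forest on all features; (2) keep the ``top_k_stage2`` by
    importance; (3) forest on the survivors; (4) save the ``top_k_final``
    by stage-3 importance plus the stage-3 forest's confusion matrix on
    the independent test set and its out-of-bag error.
    """
    if list(train.probe_ids) != list(test.probe_ids):
        raise ValueError("train and test must share an identical ordered feature list")
    rng = np.random.default_rng(session_seed)
    stage1 = build_forest(train, config.n_trees_stage1, config, rng)
    ranked1 = feature_importance(stage1)
    survivors = _top_features(ranked1, config.top_k_stage2)

    train3 = train.subset_probes(survivors)
    test3 = test.subset_probes(survivors)
    stage3 = build_forest(train3, config.n_trees_stage3, config, rng)
    ranked3 = feature_importance(stage3)

    panel = ranked3.head(config.top_k_final)[["feature_id", "importance"]].reset_index(drop=True)
    y_pred = predict_majority(stage3, test3)
    confusion = ConfusionMatrix.from_predictions(test3.y, y_pred)
    return SessionResult(
        session_index=session_index,
        seed=session_seed,
        panel=panel,
        confusion=confusion,
        oob_error=oob_error(stage3, train3),
        stage2_features=survivors,
    )


def select_best(sessions: list[SessionResult]) -> SessionResult:
    """Best session by test sensitivity; ties -> higher specificity, then lower index."""
    if not sessions:
        raise ValueError("no sessions to select from")
    return max(sessions, key=lambda s: (s.sensitivity, s.specificity, -s.session_index))


def run_selection(
    train: ExpressionDataset, test: ExpressionDataset, config: SessionConfig
) -> tuple[list[SessionResult], SessionResult]:
    """Run all sessions and pick the best by test sensitivity.

    Session i uses seed ``base_seed + i``; see :func:`select_best` for the
    tie rules.
    """
    sessions = [
        run_session(train, test, config, session_seed=config.base_seed + i, session_index=i)
        for i in range(config.n_sessions)
    ]
    return sessions, select_best(sessions)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_sessions_json(sessions: list[SessionResult], path) -> None:
    payload = [
        {
            "session_index": s.session_index,
            "seed": s.seed,
            "panel": [
                {"rank": i + 1, "feature_id": fid, "importance": float(imp)}
                for i, (fid, imp) in enumerate(
                    zip(s.panel["feature_id"], s.panel["importance"])
                )
            ],
            "confusion": s.confusion.as_dict(),
            "oob_error": s.oob_error,
        }
        for s in sessions
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_panel_tsv(result: SessionResult, path) -> None:
    out = result.panel.copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out[["rank", "feature_id"]].to_csv(path, sep="\t", index=False)
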