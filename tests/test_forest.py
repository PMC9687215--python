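import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodpanel.forest import (
    ConfusionMatrix,
    Forest,
    SessionConfig,
    SessionResult,
    Tree,
    best_split,
    build_forest,
    feature_importance,
    gini_impurity,
    grow_tree,
    oob_error,
    predict_majority,
    run_selection,
    run_session,
    select_best,
)
from bloodpanel.simulate import SimulationParams, generate_dataset

from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def gini_of(labels):
    labels = np.asarray(labels)
    g = 1.0
    for c in np.unique(labels):
        g -= (np.mean(labels == c)) ** 2
    return g


def exhaustive_best_split(X, y):
    """Brute-force search over every feature and midpoint threshold.

    Returns (best decrease, set of (feature, threshold) attaining it).
    """
    m = len(y)
    parent = gini_of(y)
    best_dec, argmax = 0.0, set()
    for j in range(X.shape[1]):
        v = X[:, j]
        for t in np.unique(v)[:-1]:
            upper = v[v > t].min()
            thr = 0.5 * (t + upper)
            left, right = y[v <= thr], y[v > thr]
            dec = parent - (len(left) * gini_of(left) + len(right) * gini_of(right)) / m
            if dec > best_dec + 1e-12:
                best_dec, argmax = dec, {(j, thr)}
            elif abs(dec - best_dec) <= 1e-12 and best_dec > 0:
                argmax.add((j, thr))
    return best_dec, argmax


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

class TestGini:
    @pytest.mark.parametrize(
        "proportions,expected",
        [
            ((1.0, 0.0), 0.0),
            ((0.5, 0.5), 0.5),
            ((0.7, 0.3), 0.42),
            ((0.25, 0.25, 0.25, 0.25), 0.75),
        ],
    )
    def test_matches_formula(self, proportions, expected):
        assert gini_impurity(proportions) == pytest.approx(expected, abs=1e-12)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((-0.1, 1.1))
        with pytest.raises(ValueError):
            gini_impurity((0.5, 0.4))


class TestBestSplit:
    def test_perfect_balanced_separation(self):
        thr, dec = best_split([1, 2, 9, 10], [0, 0, 1, 1])
        assert thr == 5.5 and dec == pytest.approx(0.5)

    def test_pure_node_and_constant_values_unsplittable(self):
        assert best_split([1, 2, 3], [0, 0, 0]) is None
        assert best_split([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]) is None

    def test_min_leaf_restricts_candidates(self):
        # only the middle split leaves >= 2 samples on both sides
        result = best_split([1, 2, 9, 10], [0, 0, 1, 1], min_leaf=2)
        assert result == (5.5, pytest.approx(0.5))

    @settings(max_examples=150, derandomize=True)
    @given(
        values=st.lists(st.integers(min_value=0, max_value=6), min_size=2, max_size=12),
        labels=st.lists(st.integers(min_value=0, max_value=1), min_size=2, max_size=12),
    )
    def test_matches_exhaustive_single_feature_oracle(self, values, labels):
        n = min(len(values), len(labels))
        v = np.array(values[:n], dtype=float)
        y = np.array(labels[:n])
        result = best_split(v, y)
        oracle_dec, argmax = exhaustive_best_split(v[:, None], y)
        if result is None:
            assert oracle_dec == pytest.approx(0.0, abs=1e-12)
        else:
            thr, dec = result
            assert dec == pytest.approx(oracle_dec, abs=1e-12)
            assert (0, thr) in argmax


class TestGrowTree:
    def test_perfect_feature_gives_depth_one_zero_error(self):
        X = np.array([[1.0], [2.0], [9.0], [10.0]])
        y = np.array([0, 0, 1, 1], dtype=np.int8)
        tree = grow_tree(X, y, feature_subset_size=1, seed=0)
        assert tree.depth() == 1
        assert (tree.predict(X) == y).all()

    def test_depth_zero_is_single_majority_leaf(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int8)
        tree = grow_tree(X, y, feature_subset_size=3, max_depth=0, seed=0)
        assert tree.n_nodes == 1
        assert (tree.predict(X) == 0).all()

    def test_same_seed_identical_trees(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 15))
        y = (rng.random(40) < 0.5).astype(np.int8)
        t1 = grow_tree(X, y, 4, seed=11, bootstrap=True)
        t2 = grow_tree(X, y, 4, seed=11, bootstrap=True)
        for a, b in zip(
            (t1.feature, t1.threshold, t1.inbag), (t2.feature, t2.threshold, t2.inbag)
        ):
            assert (a == b).all()

    def test_depth_and_leaf_occupancy_respected(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 8))
        y = (rng.random(120) < 0.5).astype(np.int8)
        tree = grow_tree(X, y, 3, max_depth=4, min_leaf=5, seed=2)
        assert tree.depth() <= 4
        leaves = tree.feature < 0
        assert (tree.node_n[leaves] >= 5).all()

    def test_root_split_equals_exhaustive_search(self):
        """Depth-1 tree with f = F reproduces the brute-force best split."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            X = rng.normal(size=(10, 20))
            y = np.r_[np.zeros(5), np.ones(5)].astype(np.int8)
            tree = grow_tree(X, y, feature_subset_size=20, max_depth=1, seed=int(rng.integers(1 << 30)))
            oracle_dec, argmax = exhaustive_best_split(X, y)
            assert tree.decrease[0] == pytest.approx(oracle_dec, abs=1e-12)
            assert (tree.feature[0], tree.threshold[0]) in argmax


def leaf_tree(c0, c1, n=2):
    """Hand-built single-leaf tree voting the majority of (c0, c1)."""
    return Tree(
        feature=np.array([-1], dtype=np.int64),
        threshold=np.zeros(1),
        left=np.array([-1], dtype=np.int64),
        right=np.array([-1], dtype=np.int64),
        decrease=np.zeros(1),
        node_n=np.array([n], dtype=np.int64),
        count0=np.array([c0], dtype=np.int64),
        count1=np.array([c1], dtype=np.int64),
        inbag=np.ones(n, dtype=np.int32),
    )


class TestForestVoting:
    def test_unanimous_and_majority_votes(self):
        forest = Forest(
            trees=[leaf_tree(0, 2), leaf_tree(2, 0), leaf_tree(0, 2)],
            feature_ids=["F1"],
            n_train=2,
        )
        assert predict_majority(forest, np.zeros((1, 1)))[0] == 1

    def test_exact_tie_goes_to_disease(self):
        forest = Forest(
            trees=[leaf_tree(2, 0), leaf_tree(0, 2)], feature_ids=["F1"], n_train=2
        )
        assert predict_majority(forest, np.zeros((1, 1)))[0] == 1

    def test_missing_features_named(self):
        forest = Forest(trees=[leaf_tree(1, 1)], feature_ids=["F1", "F2"], n_train=2)
        data = make_dataset([[1.0, 2.0]], [0, 1], probe_ids=["F1"])
        with pytest.raises(KeyError, match="F2"):
            predict_majority(forest, data)


@pytest.fixture(scope="module")
def forest_and_data():
    params = SimulationParams(n_control=50, n_disease=50, n_probes=40, n_informative=0, seed=12)
    data, _ = generate_dataset(params)
    config = SessionConfig.reduced()
    forest = build_forest(data, 150, config, rng=5)
    return forest, data


class TestBuildForest:

    def test_bootstrap_unique_fraction_near_0632(self, forest_and_data):
        """E[unique in-bag fraction] = 1 - (1 - 1/n)^n ~ 1 - e^-1."""
        forest, _ = forest_and_data
        inbag = forest.inbag_matrix()
        unique_frac = (inbag > 0).mean(axis=1)
        assert abs(unique_frac.mean() - (1 - np.exp(-1))) < 0.02

    def test_oob_frequency_near_e_inverse(self, forest_and_data):
        forest, _ = forest_and_data
        oob_frac = (forest.inbag_matrix() == 0).mean(axis=0)
        assert abs(oob_frac.mean() - np.exp(-1)) < 0.02

    def test_in_bag_multiset_size_is_n(self, forest_and_data):
        forest, data = forest_and_data
        assert (forest.inbag_matrix().sum(axis=1) == data.n_samples).all()

    def test_single_class_training_data_rejected(self):
        data = make_dataset(np.random.default_rng(0).normal(size=(5, 6)), [1] * 6)
        with pytest.raises(ValueError):
            build_forest(data, 5, SessionConfig.reduced(), rng=0)

    def test_single_tree_forest_equals_that_tree(self):
        params = SimulationParams(n_control=20, n_disease=20, n_probes=30, seed=4)
        data, _ = generate_dataset(params)
        forest = build_forest(data, 1, SessionConfig.reduced(), rng=9)
        assert (predict_majority(forest, data) == forest.trees[0].predict(data.X)).all()


class TestFeatureImportance:
    def test_perfect_depth_one_split_has_importance_half(self):
        X = np.array([[1.0], [2.0], [9.0], [10.0]])
        y = np.array([0, 0, 1, 1], dtype=np.int8)
        tree = grow_tree(X, y, 1, seed=0)
        forest = Forest(trees=[tree], feature_ids=["F1"], n_train=4)
        table = feature_importance(forest)
        assert table.loc[0, "importance"] == pytest.approx(0.5)

    def test_unused_features_have_zero_importance(self):
        X = np.c_[np.array([1.0, 2.0, 9.0, 10.0]), np.zeros(4)]
        y = np.array([0, 0, 1, 1], dtype=np.int8)
        tree = grow_tree(X, y, 2, seed=0)
        forest = Forest(trees=[tree], feature_ids=["A", "B"], n_train=4)
        table = feature_importance(forest).set_index("feature_id")
        assert table.loc["B", "importance"] == 0.0
        assert table.loc["B", "n_splits"] == 0

    def test_invariant_under_tree_order(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        y = (rng.random(30) < 0.5).astype(np.int8)
        trees = [grow_tree(X, y, 2, seed=s, bootstrap=True) for s in range(8)]
        ids = [f"F{i}" for i in range(6)]
        fwd = feature_importance(Forest(trees=trees, feature_ids=ids, n_train=30))
        rev = feature_importance(Forest(trees=trees[::-1], feature_ids=ids, n_train=30))
        assert fwd.equals(rev)

    def test_ties_break_by_ascending_feature_id(self):
        forest = Forest(trees=[leaf_tree(1, 1)], feature_ids=["B", "A"], n_train=2)
        table = feature_importance(forest)
        assert table["feature_id"].tolist() == ["A", "B"]

    def test_planted_feature_ranks_first_across_seeds(self):
        """A single 3-sigma planted transcript tops the ranking nearly always."""
        wins = 0
        for seed in range(20):
            params = SimulationParams(
                n_control=60, n_disease=60, n_probes=300, n_informative=1,
                effect_size=3.0, seed=1000 + seed,
            )
            data, truth = generate_dataset(params)
            forest = build_forest(data, 100, SessionConfig.reduced(), rng=seed)
            top = feature_importance(forest).loc[0, "feature_id"]
            wins += top in truth.informative_probe_ids
        assert wins >= 19

    def test_agrees_with_independent_forest_implementation(self):
        """scikit-learn's forest ranks the same strongly planted probes on top."""
        sklearn = pytest.importorskip("sklearn.ensemble")
        params = SimulationParams(
            n_control=60, n_disease=60, n_probes=100, n_informative=3,
            effect_size=3.0, seed=77,
        )
        data, truth = generate_dataset(params)
        ours = feature_importance(build_forest(data, 200, SessionConfig.reduced(), rng=1))
        top_ours = set(ours["feature_id"].head(3))
        clf = sklearn.RandomForestClassifier(n_estimators=200, random_state=1).fit(data.X, data.y)
        order = np.argsort(clf.feature_importances_)[::-1][:3]
        top_sklearn = {data.probe_ids[i] for i in order}
        assert top_ours == top_sklearn == truth.informative_probe_ids


class TestOOBError:
    def test_strong_signal_has_near_zero_oob_error(self):
        params = SimulationParams(
            n_control=50, n_disease=50, n_probes=50, n_informative=5,
            effect_size=5.0, seed=31,
        )
        data, _ = generate_dataset(params)
        forest = build_forest(data, 60, SessionConfig.reduced(), rng=2)
        assert oob_error(forest, data) < 0.05

    def test_permuted_labels_give_chance_level_oob_error(self):
        params = SimulationParams(
            n_control=50, n_disease=50, n_probes=50, n_informative=0,
            effect_size=0.0, seed=32,
        )
        data, _ = generate_dataset(params)
        forest = build_forest(data, 60, SessionConfig.reduced(), rng=3)
        assert 0.3 < oob_error(forest, data) < 0.7


class TestSessions:
    def test_stage_monotonicity_and_confusion_conservation(self, small_signal_data, tiny_config):
        train, test, _ = small_signal_data
        result = run_session(train, test, tiny_config, session_seed=5)
        panel = set(result.panel_features)
        stage2 = set(result.stage2_features)
        assert panel <= stage2 <= set(map(str, train.probe_ids))
        assert len(result.panel_features) == tiny_config.top_k_final
        n_control, n_disease = test.class_counts()
        c = result.confusion
        assert c.tp + c.fn == n_disease and c.tn + c.fp == n_control

    def test_session_is_pure_function_of_seed(self, small_signal_data, tiny_config):
        train, test, _ = small_signal_data
        r1 = run_session(train, test, tiny_config, session_seed=8)
        r2 = run_session(train, test, tiny_config, session_seed=8)
        assert r1.panel.equals(r2.panel)
        assert r1.confusion == r2.confusion
        assert r1.oob_error == r2.oob_error

    def test_feature_list_mismatch_rejected(self, small_signal_data, tiny_config):
        train, test, _ = small_signal_data
        with pytest.raises(ValueError, match="feature list"):
            run_session(train, test.subset_probes(list(test.probe_ids)[:-1]), tiny_config, 1)

    def test_planted_probes_dominate_the_panel(self, small_signal_data, tiny_config):
        train, test, truth = small_signal_data
        _, best = run_selection(train, test, tiny_config)
        hits = set(best.panel_features) & truth.informative_probe_ids
        assert len(hits) >= 6  # 8 planted at 2.5 sigma


def session_stub(index, sensitivity, specificity):
    return SessionResult(
        session_index=index,
        seed=index,
        panel=pd.DataFrame({"feature_id": ["F"], "importance": [1.0]}),
        confusion=ConfusionMatrix(
            tp=int(sensitivity * 100), fn=100 - int(sensitivity * 100),
            tn=int(specificity * 100), fp=100 - int(specificity * 100),
        ),
        oob_error=0.0,
        stage2_features=["F"],
    )


class TestSelection:
    def test_highest_sensitivity_wins(self):
        best = select_best([session_stub(0, 0.7, 0.9), session_stub(1, 0.9, 0.5)])
        assert best.session_index == 1

    def test_sensitivity_tie_broken_by_specificity(self):
        best = select_best([session_stub(0, 0.8, 0.6), session_stub(1, 0.8, 0.8)])
        assert best.session_index == 1

    def test_full_tie_prefers_lower_index(self):
        best = select_best([session_stub(0, 0.8, 0.8), session_stub(1, 0.8, 0.8)])
        assert best.session_index == 0

    def test_single_session_is_best(self, small_signal_data):
        train, test, _ = small_signal_data
        config = SessionConfig(
            n_trees_stage1=20, top_k_stage2=25, n_trees_stage3=30,
            top_k_final=5, n_sessions=1, base_seed=3,
        )
        sessions, best = run_selection(train, test, config)
        assert len(sessions) == 1 and best is sessions[0]


class TestSessionConfig:
    def test_subset_size_rules(self):
        assert SessionConfig(feature_subset_rule="sqrt").subset_size(2000) == 44
        assert SessionConfig(feature_subset_rule="log2").subset_size(1024) == 10
        assert SessionConfig(feature_subset_rule="fixed:7").subset_size(2000) == 7
        assert SessionConfig(feature_subset_rule="fixed:7").subset_size(3) == 3

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(top_k_final=600, top_k_stage2=500)
        with pytest.raises(ValueError):
            SessionConfig(n_sessions=0)
        with pytest.raises(ValueError):
            SessionConfig(feature_subset_rule="cubic")
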