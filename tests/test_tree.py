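"""Feature enumeration, encoding, and the entropy decision tree."""

import math

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from caaxscreen.motifs import enumerate_cxxx
from caaxscreen.tree import (LabeledMotifs, binarize_labels, encode,
                             enumerate_features, extract_rules, fit_tree,
                             fit_tree_motifs)

from conftest import make_ef_table


def _entropy(pos, n):
    if n == 0 or pos == 0 or pos == n:
        return 0.0
    q = pos / n
    return -(q * math.log2(q) + (1 - q) * math.log2(1 - q))


def oracle_root_split(X, y, min_samples):
    """Exhaustive information-gain search, first feature wins ties."""
    n = len(y)
    n_pos = int(y.sum())
    h_parent = _entropy(n_pos, n)
    best_j, best_gain = -1, 0.0
    for j in range(X.shape[1]):
        on = X[:, j].astype(bool)
        n1, n0 = int(on.sum()), n - int(on.sum())
        if min(n1, n0) < min_samples:
            continue
        p1 = int(y[on].sum())
        p0 = n_pos - p1
        gain = h_parent - (n1 * _entropy(p1, n1)
                           + n0 * _entropy(p0, n0)) / n
        if gain > best_gain:
            best_j, best_gain = j, gain
    return best_j, best_gain


class TestEnumerateFeatures:
    @pytest.mark.parametrize("size,count", [(1, 60), (2, 630), (5, 65097)])
    def test_known_counts(self, size, count):
        assert len(enumerate_features(size)) == count

    @pytest.mark.parametrize("size", range(1, 7))
    def test_closed_form(self, size):
        expected = 3 * sum(math.comb(20, k) for k in range(1, size + 1))
        specs = enumerate_features(size)
        assert len(specs) == expected
        assert len(set(specs)) == expected  # no duplicates

    def test_bounds(self):
        with pytest.raises(ValueError):
            enumerate_features(0)
        with pytest.raises(ValueError):
            enumerate_features(21)


class TestEncode:
    def test_singleton_block(self):
        specs = enumerate_features(1)
        X = encode(["CASQ"], specs)
        assert X.sum() == 3  # exactly one hot per position
        on = {str(specs[j]) for j in np.nonzero(X[0])[0]}
        assert on == {"a1 in {A}", "a2 in {S}", "x in {Q}"}

    def test_set_feature(self):
        specs = enumerate_features(5)
        j = next(i for i, s in enumerate(specs)
                 if s.position == "a2" and s.residues == frozenset("DEKR"))
        X = encode(["CASQ", "CAKA"], specs[j:j + 1])
        assert X[:, 0].tolist() == [0, 1]

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(5)
        motifs = list(rng.choice(enumerate_cxxx(), 40, replace=False))
        specs = enumerate_features(2)
        X = encode(motifs, specs)
        for i, m in enumerate(motifs):
            for j, spec in enumerate(specs):
                assert X[i, j] == int(spec.evaluate(m))


class TestBinarizeLabels:
    def test_extreme_thresholds(self, random_ef_table):
        low = binarize_labels(random_ef_table, -1.0)
        assert low.labels.all()
        high = binarize_labels(random_ef_table, float("inf"))
        assert not high.labels.any()

    def test_threshold_recorded(self, random_ef_table):
        labeled = binarize_labels(random_ef_table, 1.5)
        assert labeled.metadata["threshold"] == 1.5
        ef = random_ef_table.df["ef"].to_numpy()
        assert labeled.labels.sum() == (ef > 1.5).sum()


class TestFitTree:
    def test_perfectly_separable_depth_one(self):
        """Labels equal to the complement of one set feature: the root
        splits on it and the tree is depth 1 with 100% accuracy."""
        motifs = enumerate_cxxx()
        y = np.array([m[2] not in "DEKR" for m in motifs])
        labeled = LabeledMotifs(motifs=motifs, labels=y)
        model = fit_tree_motifs(labeled, max_set_size=5)
        assert str(model.root.spec) == "a2 in {D,E,K,R}"
        assert model.depth() == 1
        preds = np.array(model.predict_motifs(motifs)) == "positive"
        assert (preds == y).all()

    def test_single_class_single_leaf(self):
        X = np.zeros((100, 4), dtype=np.uint8)
        model = fit_tree(X, np.ones(100, dtype=bool), min_samples=5)
        assert model.root.is_leaf
        assert model.root.prediction == "positive"

    def test_constraints_respected(self, recovery_screen):
        _, table = recovery_screen
        model = fit_tree_motifs(binarize_labels(table, 1.0))
        assert model.depth() <= 3
        stack = [model.root]
        while stack:
            node = stack.pop()
            assert node.n_samples >= 50
            if not node.is_leaf:
                stack.extend([node.left, node.right])

    def test_simulated_screen_recovers_rules(self, recovery_screen):
        """Planted substrate rules come back: the root split is the a2
        charge restriction and the next split is the X-position K/P/R
        restriction, with the aliphatic-a2 rescue below it."""
        _, table = recovery_screen
        model = fit_tree_motifs(binarize_labels(table, 1.0))
        assert str(model.root.spec) == "a2 in {D,E,K,R}"
        assert str(model.root.left.spec) == "x in {K,P,R}"
        rules = "\n".join(extract_rules(model))
        assert "a2 in {I,L,M,V}" in rules

    def test_root_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        X = (rng.random((200, 100)) < 0.4).astype(np.uint8)
        y = X[:, 37].astype(bool) ^ (rng.random(200) < 0.1)
        model = fit_tree(X, y, max_depth=3, min_samples=10)
        oj, _ = oracle_root_split(X, y, min_samples=10)
        assert model.root.feature_index == oj == 37

    def test_fast_path_matches_generic(self):
        """The histogram fast path and the explicit-matrix path implement
        the same contract: identical trees on the same input."""
        rng = np.random.default_rng(23)
        motifs = list(rng.choice(enumerate_cxxx(), 600, replace=False))
        y = np.array([(m[2] in "DEKR") ^ (rng.random() < 0.15)
                      for m in motifs])
        specs = enumerate_features(2)
        X = encode(motifs, specs)
        generic = fit_tree(X, y, max_depth=3, min_samples=20, specs=specs)
        fast = fit_tree_motifs(LabeledMotifs(motifs=motifs, labels=y),
                               max_set_size=2, max_depth=3, min_samples=20)
        assert generic.root.feature_index == fast.root.feature_index
        assert generic.predict(X) == fast.predict_motifs(motifs)

    def test_feature_permutation_invariant_predictions(self):
        """Tie-free input (every feature has a distinct noise level, so
        distinct empirical gain): permuting feature order changes nothing."""
        rng = np.random.default_rng(31)
        n = 400
        y = rng.random(n) < 0.5
        cols = [y ^ (rng.random(n) < 0.05 + 0.028 * j) for j in range(15)]
        X = np.stack(cols, axis=1).astype(np.uint8)
        base = fit_tree(X, y, max_depth=2, min_samples=20)
        perm = rng.permutation(X.shape[1])
        permuted = fit_tree(X[:, perm], y, max_depth=2, min_samples=20)
        assert base.predict(X) == permuted.predict(X[:, perm])

    def test_agrees_with_sklearn_root(self):
        """Independent cross-check: scikit-learn's entropy tree picks the
        same root feature on a tie-free binary problem."""
        rng = np.random.default_rng(43)
        X = (rng.random((300, 50)) < 0.5).astype(np.uint8)
        y = X[:, 21].astype(bool) ^ (rng.random(300) < 0.15)
        ours = fit_tree(X, y, max_depth=1, min_samples=10)
        sk = DecisionTreeClassifier(criterion="entropy", max_depth=1,
                                    min_samples_leaf=10, random_state=0)
        sk.fit(X, y)
        assert ours.root.feature_index == sk.tree_.feature[0]


class TestExtractRules:
    def test_leaf_count(self, recovery_screen):
        _, table = recovery_screen
        model = fit_tree_motifs(binarize_labels(table, 1.0))
        rules = extract_rules(model)
        assert len(rules) == len(model.leaves())
        assert all(r.startswith("IF ") for r in rules)

    def test_depth_one_single_condition(self):
        motifs = enumerate_cxxx()
        y = np.array([m[3] in "KPR" for m in motifs])
        model = fit_tree_motifs(LabeledMotifs(motifs=motifs, labels=y),
                                max_set_size=3)
        rules = extract_rules(model)
        assert len(rules) == 2
        assert any("x in {K,P,R}" in r and "THEN positive" in r
                   for r in rules)
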