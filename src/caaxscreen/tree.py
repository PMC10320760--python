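"""Interpretable residue-rule extraction with an entropy decision tree.

Motifs are described by binary features of the form "residue at position p
is in set S", for every subset S of the 20-letter alphabet up to a maximum
size (5 by default: 3 * (C(20,1)+...+C(20,5)) = 65,097 features).  A
greedy binary tree maximizing information gain, depth-limited and with a
minimum sample count at every node, then reads out as a short list of
residue rules (e.g. "restrictive D/E/K/R at a2").

The tree is implemented against an explicit contract — entropy gain,
deterministic first-feature tie-break, min_samples on every node — so fits
are bit-reproducible across platforms.  Because every motif has exactly
one residue per position, the count of motifs carrying a set feature is
the sum of its per-residue counts; node statistics for all 65,097 features
therefore reduce to three 20-bin histograms and a sparse matrix product,
and the full feature matrix never needs to be materialized.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .enrichment import EFTable
from .motifs import AMINO_ACIDS, enumerate_cxxx

POSITION_ORDER = ("a1", "a2", "x")


@dataclass(frozen=True)
class FeatureSpec:
    """Binary feature: residue at ``position`` is a member of ``residues``."""

    position: str
    residues: frozenset

    def __str__(self) -> str:
        return f"{self.position} in {{{','.join(sorted(self.residues))}}}"

    def evaluate(self, motif: str) -> bool:
        offset = {"a1": 1, "a2": 2, "x": 3}[self.position]
        return motif[offset] in self.residues

    def to_dict(self) -> dict:
        return {"position": self.position,
                "residues": sorted(self.residues)}


def _residue_sets(max_set_size: int) -> list[frozenset]:
    """All residue subsets of size 1..max_set_size, size-major then
    lexicographic within size."""
    sets = []
    for k in range(1, max_set_size + 1):
        for combo in itertools.combinations(AMINO_ACIDS, k):
            sets.append(frozenset(combo))
    return sets


def enumerate_features(max_set_size: int = 5) -> list[FeatureSpec]:
    """All set-membership features, position-major (a1, a2, X) then
    size-major: 3 * sum_{k=1..s} C(20, k) specs, no duplicates."""
    if not 1 <= max_set_size <= 20:
        raise ValueError("max_set_size must be in 1..20")
    sets = _residue_sets(max_set_size)
    return [FeatureSpec(pos, s) for pos in POSITION_ORDER for s in sets]


def encode(motifs: Sequence[str],
           specs: Sequence[FeatureSpec]) -> np.ndarray:
    """Binary feature matrix (n_motifs x n_specs), dtype uint8."""
    X = np.zeros((len(motifs), len(specs)), dtype=np.uint8)
    for j, spec in enumerate(specs):
        X[:, j] = [spec.evaluate(m) for m in motifs]
    return X


@dataclass
class LabeledMotifs:
    """Binary prenylation labels over the full motif space."""

    motifs: list
    labels: np.ndarray  # bool, True = positive (enriched)
    metadata: dict = field(default_factory=dict)


def binarize_labels(table: EFTable, threshold: float = 1.0) -> LabeledMotifs:
    """Positive iff EF strictly exceeds ``threshold`` (enriched vs depleted).

    The screen yields continuous EFs; the training labels are a stated,
    logged choice recorded in the metadata.
    """
    table.require_full()
    ef = table.df.set_index("motif")["ef"].reindex(enumerate_cxxx())
    labels = (ef.to_numpy(dtype=float) > threshold)
    return LabeledMotifs(
        motifs=enumerate_cxxx(),
        labels=labels,
        metadata={"rule": f"ef > {threshold}", "threshold": threshold},
    )


# ---------------------------------------------------------------------------
# tree model

@dataclass
class TreeNode:
    depth: int
    n_samples: int
    n_positive: int
    feature_index: Optional[int] = None      # None for leaves
    spec: Optional[FeatureSpec] = None
    left: Optional["TreeNode"] = None        # feature == 0
    right: Optional["TreeNode"] = None       # feature == 1

    @property
    def is_leaf(self) -> bool:
        return self.feature_index is None

    @property
    def prediction(self) -> str:
        # majority class; exact tie -> negative (conservative)
        return ("positive"
                if self.n_positive * 2 > self.n_samples else "negative")

    @property
    def purity(self) -> float:
        n_major = max(self.n_positive, self.n_samples - self.n_positive)
        return n_major / self.n_samples if self.n_samples else float("nan")

    def to_dict(self) -> dict:
        d = {
            "depth": self.depth,
            "n_samples": self.n_samples,
            "class_counts": {
                "negative": self.n_samples - self.n_positive,
                "positive": self.n_positive,
            },
        }
        if self.is_leaf:
            d["leaf"] = self.prediction
        else:
            d["feature_index"] = self.feature_index
            d["feature"] = self.spec.to_dict() if self.spec else None
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


@dataclass
class DecisionTreeModel:
    root: TreeNode
    specs: Optional[list] = None  # FeatureSpec list, if motif-based
    params: dict = field(default_factory=dict)

    def predict_motifs(self, motifs: Sequence[str]) -> list[str]:
        if self.specs is None:
            raise ValueError("model was fit without feature specs")
        out = []
        for m in motifs:
            node = self.root
            while not node.is_leaf:
                node = (node.right if node.spec.evaluate(m) else node.left)
            out.append(node.prediction)
        return out

    def predict(self, X: np.ndarray) -> list[str]:
        out = []
        for row in np.asarray(X):
            node = self.root
            while not node.is_leaf:
                node = node.right if row[node.feature_index] else node.left
            out.append(node.prediction)
        return out

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out[::-1]

    def depth(self) -> int:
        def _d(node):
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"params": self.params,
                       "tree": self.root.to_dict()}, fh, indent=2)


def _entropy(n_pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy in bits, elementwise; 0 for empty or pure nodes."""
    n = np.asarray(n, dtype=float)
    n_pos = np.asarray(n_pos, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(n > 0, n_pos / np.maximum(n, 1), 0.0)
        h = -(np.where(q > 0, q * np.log2(q), 0.0)
              + np.where(q < 1, (1 - q) * np.log2(1 - q), 0.0))
    return np.where(n > 0, h, 0.0)


def _best_split(n1: np.ndarray, pos1: np.ndarray, n: int, n_pos: int,
                min_samples: int) -> tuple[int, float]:
    """Feature of maximal information gain from per-feature counts.

    ``n1``/``pos1`` are per-feature counts of samples (and positives) with
    the feature set, within the node.  Splits leaving a child below
    ``min_samples`` are infeasible.  Returns (feature_index, gain); index
    is -1 when no feasible split has strictly positive gain.  Ties go to
    the lowest feature index (np.argmax), making fits deterministic.
    """
    n1 = np.asarray(n1, dtype=np.int64)
    pos1 = np.asarray(pos1, dtype=np.int64)
    n0 = n - n1
    pos0 = n_pos - pos1
    h_parent = float(_entropy(np.array(n_pos), np.array(n)))
    child = (n1 * _entropy(pos1, n1) + n0 * _entropy(pos0, n0)) / n
    gain = h_parent - child
    feasible = (n1 >= min_samples) & (n0 >= min_samples)
    gain = np.where(feasible, gain, -np.inf)
    j = int(np.argmax(gain))
    if not np.isfinite(gain[j]) or gain[j] <= 0.0:
        return -1, 0.0
    return j, float(gain[j])


class _MotifCounter:
    """Per-node feature counts over the set-membership space, computed
    additively from residue histograms (see module docstring)."""

    def __init__(self, motifs: Sequence[str], max_set_size: int):
        self.residx = np.array(
            [[AMINO_ACIDS.index(m[1]), AMINO_ACIDS.index(m[2]),
              AMINO_ACIDS.index(m[3])] for m in motifs], dtype=np.int64)
        sets = _residue_sets(max_set_size)
        mask = np.zeros((len(sets), 20), dtype=np.float64)
        for i, s in enumerate(sets):
            for r in s:
                mask[i, AMINO_ACIDS.index(r)] = 1.0
        self.mask = mask
        self.n_sets = len(sets)

    def counts(self, idx: np.ndarray, y: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
        n1 = np.empty(3 * self.n_sets, dtype=np.int64)
        pos1 = np.empty_like(n1)
        sub = self.residx[idx]
        ysub = y[idx]
        for p in range(3):
            cnt = np.bincount(sub[:, p], minlength=20)
            pcnt = np.bincount(sub[ysub, p], minlength=20)
            sl = slice(p * self.n_sets, (p + 1) * self.n_sets)
            n1[sl] = np.rint(self.mask @ cnt).astype(np.int64)
            pos1[sl] = np.rint(self.mask @ pcnt).astype(np.int64)
        return n1, pos1


def _grow(idx: np.ndarray, y: np.ndarray, depth: int, max_depth: int,
          min_samples: int, count_fn, feature_mask_fn) -> TreeNode:
    n = len(idx)
    n_pos = int(y[idx].sum())
    node = TreeNode(depth=depth, n_samples=n, n_positive=n_pos)
    if depth >= max_depth or n_pos == 0 or n_pos == n or n < 2 * min_samples:
        return node
    n1, pos1 = count_fn(idx, y)
    j, _gain = _best_split(n1, pos1, n, n_pos, min_samples)
    if j < 0:
        return node
    node.feature_index = j
    right_mask = feature_mask_fn(idx, j)
    node.right = _grow(idx[right_mask], y, depth + 1, max_depth,
                       min_samples, count_fn, feature_mask_fn)
    node.left = _grow(idx[~right_mask], y, depth + 1, max_depth,
                      min_samples, count_fn, feature_mask_fn)
    return node


def fit_tree(
    X: np.ndarray,
    y: Sequence[bool] | np.ndarray,
    max_depth: int = 3,
    min_samples: int = 50,
    specs: Optional[Sequence[FeatureSpec]] = None,
) -> DecisionTreeModel:
    """Fit the entropy tree on an explicit binary feature matrix.

    Greedy binary splitting; at each node the feature maximizing
    information gain is chosen (first feature in enumeration order on
    ties), stopping when the depth limit binds, a child would fall below
    ``min_samples``, or no split has positive gain.  Single-class input
    yields a single-leaf tree.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=bool)
    if X.shape[0] != len(y):
        raise ValueError("X and y lengths differ")

    def count_fn(idx, yy):
        sub = X[idx]
        n1 = sub.sum(axis=0, dtype=np.int64)
        pos1 = sub[yy[idx]].sum(axis=0, dtype=np.int64)
        return n1, pos1

    def feature_mask_fn(idx, j):
        return X[idx, j].astype(bool)

    root = _grow(np.arange(len(y)), y, 0, max_depth, min_samples,
                 count_fn, feature_mask_fn)
    model = DecisionTreeModel(
        root=root, specs=list(specs) if specs is not None else None,
        params={"max_depth": max_depth, "min_samples": min_samples,
                "criterion": "entropy", "n_features": X.shape[1]})
    _attach_specs(model)
    return model


def fit_tree_motifs(
    labeled: LabeledMotifs,
    max_set_size: int = 5,
    max_depth: int = 3,
    min_samples: int = 50,
) -> DecisionTreeModel:
    """Fit over the full set-membership feature space without
    materializing the feature matrix (identical contract to
    :func:`fit_tree`; node statistics reduce to residue histograms)."""
    y = np.asarray(labeled.labels, dtype=bool)
    counter = _MotifCounter(labeled.motifs, max_set_size)
    specs = enumerate_features(max_set_size)

    def feature_mask_fn(idx, j):
        p, s = divmod(j, counter.n_sets)
        row = counter.mask[s].astype(bool)
        return row[counter.residx[idx, p]]

    root = _grow(np.arange(len(y)), y, 0, max_depth, min_samples,
                 counter.counts, feature_mask_fn)
    model = DecisionTreeModel(
        root=root, specs=specs,
        params={"max_depth": max_depth, "min_samples": min_samples,
                "criterion": "entropy", "max_set_size": max_set_size,
                "n_features": len(specs), **labeled.metadata})
    _attach_specs(model)
    return model


def _attach_specs(model: DecisionTreeModel) -> None:
    if model.specs is None:
        return
    stack = [model.root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            node.spec = model.specs[node.feature_index]
            stack.extend([node.left, node.right])


def extract_rules(model: DecisionTreeModel) -> list[str]:
    """One human-readable rule per leaf: the path conjunction, predicted
    class, sample count and node purity."""
    rules: list[str] = []

    def describe(spec: Optional[FeatureSpec], j: int) -> str:
        return str(spec) if spec is not None else f"feature[{j}]"

    def walk(node: TreeNode, conditions: list[str]) -> None:
        if node.is_leaf:
            cond = " AND ".join(conditions) if conditions else "always"
            rules.append(
                f"IF {cond} THEN {node.prediction} "
                f"(n={node.n_samples}, purity={node.purity:.3f})")
            return
        cond = describe(node.spec, node.feature_index)
        walk(node.left, conditions + [f"NOT ({cond})"])
        walk(node.right, conditions + [f"({cond})"])

    walk(model.root, [])
    return rules


def write_rules(rules: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(rules) + "\n")
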