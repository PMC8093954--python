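"""First fusion stage: accuracy ranking and greedy set-level search.

Feature blocks are first scored individually by a wrapper evaluator (train a
classifier on the training rows, measure accuracy on the test rows) and
ranked in descending order.  Two greedy searches over whole blocks follow:

* forward — start from the top-ranked block; try the remaining blocks in
  rank order; keep an addition only if it strictly improves accuracy;
* backward — start from all blocks; try removals from the lowest rank
  upward; keep a removal only if accuracy strictly improves, otherwise the
  block is restored.

Equal accuracy rejects a change, which biases toward smaller sets and makes
the search deterministic.  Candidate sets are cached by their (unordered)
block-name set so a set is never scored twice.

Trajectory entries carry FS-k-<tag>-<FW|BW> identifiers: FS-1 is the
starting set (the top block forward, all blocks backward) and FS-k is the
candidate at the (k-1)-th trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .autoencoder import AEConfig, train_autoencoder, encode
from .blocks import FeatureBlock
from .manifest import Split


class _GuardedQDA(ClassifierMixin, BaseEstimator):
    """QDA with regularization, preceded by a PCA projection whenever a
    class has no more samples than features (the per-class covariance would
    be singular beyond what the regularizer can absorb)."""

    def __init__(self, reg_param: float = 1e-4):
        self.reg_param = reg_param

    def fit(self, X, y):
        y = np.asarray(y)
        min_class = min(np.sum(y == c) for c in np.unique(y))
        self.pca_ = None
        if X.shape[1] >= min_class:
            self.pca_ = PCA(n_components=max(1, min(X.shape[1], min_class - 1,
                                                    X.shape[0] - 1)))
            X = self.pca_.fit_transform(X)
        self.qda_ = QuadraticDiscriminantAnalysis(reg_param=self.reg_param)
        self.qda_.fit(X, y)
        self.n_features_in_ = X.shape[1] if self.pca_ is None else self.pca_.n_features_in_
        return self

    def predict(self, X):
        if self.pca_ is not None:
            X = self.pca_.transform(X)
        return self.qda_.predict(X)


def make_member(kind: str, seed: int = 0, rf_trees: int = 100, qda_reg: float = 1e-4,
                svm_kernel: str = "rbf"):
    """Classifier factory shared by the search evaluator and the ensemble."""
    if kind == "svm":
        clf = SVC(kernel=svm_kernel, random_state=seed)
    elif kind == "rf":
        clf = RandomForestClassifier(n_estimators=rf_trees, random_state=seed)
    elif kind == "qda":
        clf = _GuardedQDA(reg_param=qda_reg)
    else:
        raise ValueError(f"unknown classifier {kind!r}")
    return make_pipeline(StandardScaler(), clf)


@dataclass
class Evaluator:
    """Wrapper accuracy of a feature matrix under a fixed train/test split."""

    split: Split
    classifier_choice: str = "svm"  # 'svm' | 'rf' | 'qda' | 'best_of_three'
    seed: int = 0
    use_ae_during_search: bool = False
    ae_config: AEConfig | None = None

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("feature matrix and labels are misaligned")
        tr, te = self.split.train_indices, self.split.test_indices
        Xtr, Xte = X[tr], X[te]
        if self.use_ae_during_search:
            cfg = self.ae_config or AEConfig.practical_profile(seed=self.seed)
            model = train_autoencoder(Xtr, cfg)
            Xtr, Xte = encode(model, Xtr), encode(model, Xte)
        kinds = (
            ("svm", "rf", "qda")
            if self.classifier_choice == "best_of_three"
            else (self.classifier_choice,)
        )
        accs = []
        for kind in kinds:
            clf = make_member(kind, seed=self.seed)
            clf.fit(Xtr, y[tr])
            accs.append(float(np.mean(clf.predict(Xte) == y[te])))
        return max(accs)


@dataclass
class FeatureSetRanking:
    ordered_blocks: list[str]
    accuracies: list[float]

    def __post_init__(self) -> None:
        if len(set(self.ordered_blocks)) != len(self.ordered_blocks):
            raise ValueError("duplicate block names in ranking")
        if any(b > a + 1e-12 for a, b in zip(self.accuracies, self.accuracies[1:])):
            raise ValueError("accuracies must be non-increasing")


@dataclass
class TrajectoryEntry:
    set_id: str
    block_tried: str
    candidate_set: list[str]
    accuracy: float
    decision: str  # 'kept' | 'rejected' | 'removed' | 'restored' | 'start'


@dataclass
class SearchResult:
    strategy: str
    selected_blocks: list[str]
    trajectory: list[TrajectoryEntry]
    final_accuracy: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "strategy": self.strategy,
                "selected_blocks": self.selected_blocks,
                "final_accuracy": self.final_accuracy,
                "trajectory": [vars(t) for t in self.trajectory],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


class _SetScorer:
    """Scores a named block set once; repeats hit the cache."""

    def __init__(self, blocks: list[FeatureBlock], labels: np.ndarray, evaluator):
        self.by_name = {b.name: b for b in blocks}
        self.labels = np.asarray(labels)
        self.evaluator = evaluator
        self.cache: dict[frozenset, float] = {}

    def __call__(self, names: list[str]) -> float:
        key = frozenset(names)
        if key not in self.cache:
            X = np.hstack([self.by_name[n].matrix for n in names])
            self.cache[key] = self.evaluator.score(X, self.labels)
        return self.cache[key]


def rank_blocks(blocks: list[FeatureBlock], labels: np.ndarray, evaluator) -> FeatureSetRanking:
    """Score each block individually; sort descending, ties by name."""
    if not blocks:
        raise ValueError("at least one block required")
    labels = np.asarray(labels)
    for b in blocks:
        if b.n_samples != labels.shape[0]:
            raise ValueError(f"block {b.name}: rows misaligned with labels")
    scores = {b.name: evaluator.score(b.matrix, labels) for b in blocks}
    order = sorted(scores, key=lambda n: (-scores[n], n))
    return FeatureSetRanking(order, [scores[n] for n in order])


def forward_search(
    ranking: FeatureSetRanking,
    blocks: list[FeatureBlock],
    labels: np.ndarray,
    evaluator,
    dataset_tag: str = "SYN",
) -> SearchResult:
    if not ranking.ordered_blocks:
        raise ValueError("empty ranking")
    scorer = _SetScorer(blocks, labels, evaluator)
    current = [ranking.ordered_blocks[0]]
    best = scorer(current)
    traj = [TrajectoryEntry(f"FS-1-{dataset_tag}-FW", current[0], list(current), best, "start")]
    for k, name in enumerate(ranking.ordered_blocks[1:], start=2):
        candidate = current + [name]
        acc = scorer(candidate)
        if acc > best:
            current, best, decision = candidate, acc, "kept"
        else:
            decision = "rejected"
        traj.append(TrajectoryEntry(f"FS-{k}-{dataset_tag}-FW", name, candidate, acc, decision))
    return SearchResult("forward", current, traj, best)


def backward_search(
    ranking: FeatureSetRanking,
    blocks: list[FeatureBlock],
    labels: np.ndarray,
    evaluator,
    dataset_tag: str = "SYN",
) -> SearchResult:
    if not ranking.ordered_blocks:
        raise ValueError("empty ranking")
    scorer = _SetScorer(blocks, labels, evaluator)
    current = list(ranking.ordered_blocks)
    best = scorer(current)
    traj = [TrajectoryEntry(f"FS-1-{dataset_tag}-BW", "", list(current), best, "start")]
    k = 2
    for name in reversed(ranking.ordered_blocks):  # lowest rank first
        if len(current) == 1:
            break
        if name not in current:
            continue
        candidate = [n for n in current if n != name]
        acc = scorer(candidate)
        if acc > best:
            current, best, decision = candidate, acc, "removed"
        else:
            decision = "restored"
        traj.append(TrajectoryEntry(f"FS-{k}-{dataset_tag}-BW", name, candidate, acc, decision))
        k += 1
    return SearchResult("backward", current, traj, best)


@dataclass
class FusedFeatures:
    matrix: np.ndarray
    component_names: list[str]
    component_dims: list[int]
    ae_reduced: bool = False

    def __post_init__(self) -> None:
        expected = sum(self.component_dims)
        if not self.ae_reduced and self.matrix.shape[1] != expected:
            raise ValueError("fused width must equal the sum of component dims")


def concat_blocks(blocks: list[FeatureBlock]) -> FusedFeatures:
    """Column-wise concatenation of row-aligned blocks, order preserved."""
    if not blocks:
        raise ValueError("no blocks to fuse")
    n = blocks[0].n_samples
    for b in blocks:
        if b.n_samples != n:
            raise ValueError(f"block {b.name}: row count {b.n_samples} != {n}")
    return FusedFeatures(
        matrix=np.hstack([b.matrix for b in blocks]),
        component_names=[b.name for b in blocks],
        component_dims=[b.dim for b in blocks],
    )


def ae_fuse(
    fused: FusedFeatures,
    train_rows: list[int] | np.ndarray,
    cfg: AEConfig | None = None,
) -> tuple[FusedFeatures, "object"]:
    """Train the autoencoder on training rows; encode every row."""
    cfg = cfg or AEConfig()
    model = train_autoencoder(fused.matrix[np.asarray(train_rows)], cfg)
    coded = encode(model, fused.matrix)
    out = FusedFeatures(
        matrix=coded,
        component_names=fused.component_names,
        component_dims=fused.component_dims,
        ae_reduced=True,
    )
    return out, model
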