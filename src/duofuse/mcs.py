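"""Second fusion stage: a majority-voting multiple classifier system.

Three members — an RBF support vector machine, a random forest, and
regularized quadratic discriminant analysis — are trained on the same fused
features and their predicted labels combined by plurality vote.  With three
members and binary labels no tie is possible; in the multiclass case a
three-way split is broken by the configured rule (default: the label from
the member with the highest recorded validation accuracy).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .search import make_member

MEMBER_ORDER = ("svm", "rf", "qda")


@dataclass
class MCSConfig:
    svm_kernel: str = "rbf"
    rf_trees: int = 100
    qda_reg: float = 1e-4
    tie_rule: str = "best_member"  # or 'first_member'
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tie_rule not in ("best_member", "first_member"):
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")


@dataclass
class MCSModel:
    members: dict[str, object]
    validation_accuracy: dict[str, float]
    tie_rule: str
    label_set: list[str]

    def save(self, directory: str | Path) -> None:
        import joblib

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, member in self.members.items():
            joblib.dump(member, d / f"{name}.joblib")
        (d / "metadata.json").write_text(
            json.dumps(
                {
                    "validation_accuracy": self.validation_accuracy,
                    "tie_rule": self.tie_rule,
                    "label_set": self.label_set,
                }
            )
        )

    @classmethod
    def load(cls, directory: str | Path) -> "MCSModel":
        import joblib

        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        members = {name: joblib.load(d / f"{name}.joblib") for name in MEMBER_ORDER}
        return cls(members, meta["validation_accuracy"], meta["tie_rule"], meta["label_set"])


def train_mcs(
    X: np.ndarray,
    y: np.ndarray,
    cfg: MCSConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> MCSModel:
    """Fit the three members and record per-member validation accuracy.

    Validation data may be supplied explicitly; otherwise a seeded
    stratified fraction of (X, y) is held out to measure each member, after
    which members are refit on all rows.
    """
    cfg = cfg or MCSConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("rows of X and y are misaligned")
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise ValueError("need at least 2 classes to train")

    if validation is None:
        Xtr, Xval, ytr, yval = train_test_split(
            X, y, test_size=cfg.validation_fraction, random_state=cfg.seed, stratify=y
        )
    else:
        Xtr, ytr = X, y
        Xval, yval = validation

    members: dict[str, object] = {}
    val_acc: dict[str, float] = {}
    for name in MEMBER_ORDER:
        probe = make_member(name, seed=cfg.seed, rf_trees=cfg.rf_trees,
                            qda_reg=cfg.qda_reg, svm_kernel=cfg.svm_kernel)
        probe.fit(Xtr, ytr)
        val_acc[name] = float(np.mean(probe.predict(Xval) == yval))
        final = make_member(name, seed=cfg.seed, rf_trees=cfg.rf_trees,
                            qda_reg=cfg.qda_reg, svm_kernel=cfg.svm_kernel)
        final.fit(X, y)
        members[name] = final
    return MCSModel(members, val_acc, cfg.tie_rule, [str(c) for c in classes])


def majority_vote(
    member_predictions: list[np.ndarray],
    model: MCSModel,
) -> np.ndarray:
    """Per-sample modal label across members; ties broken by the model's rule."""
    preds = [np.asarray(p) for p in member_predictions]
    n = preds[0].shape[0]
    for p in preds:
        if p.shape[0] != n:
            raise ValueError("prediction vectors differ in length")
    if model.tie_rule == "best_member":
        names = list(model.members)
        accs = [
            model.validation_accuracy.get(names[i], 0.0) if i < len(names) else 0.0
            for i in range(len(preds))
        ]
        tiebreak_member = int(np.argmax(accs))
    else:
        tiebreak_member = 0
    out = np.empty(n, dtype=preds[0].dtype)
    for i in range(n):
        votes = Counter(p[i] for p in preds)
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            out[i] = preds[tiebreak_member][i]
        else:
            out[i] = top[0][0]
    return out


def predict_mcs(model: MCSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0, dtype=object)
    width = model.members[MEMBER_ORDER[0]].n_features_in_
    if X.shape[1] != width:
        raise ValueError(f"X width {X.shape[1]} != training width {width}")
    preds = [np.asarray(model.members[name].predict(X)) for name in MEMBER_ORDER]
    return majority_vote(preds, model)
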