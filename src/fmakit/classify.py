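"""Per-test 3-class scoring classifiers and validation protocols.

Every test movement gets its own classifier mapping its feature vector to a
score in {0, 1, 2}.  Two classifier families are provided:

* ``svm`` — soft-margin linear-kernel SVMs with libsvm's default multiclass
  scheme: one binary machine per *pair* of scores, prediction by majority
  vote (ties broken by summed decision values, then toward the lower score).
  Pairwise machines matter here: the partial-execution class sits between
  the no-movement and faultless classes along the feature axes, so no single
  linear discriminant can separate it from the union of the other two.  The
  regularization constant is left at the library default (C = 1) and the
  features are not rescaled.
* ``bnn`` — a hand-written 3-layer backpropagation network: input layer sized
  to the feature dimension, three output nodes (one per score, argmax
  prediction), and a hidden layer about halfway between, ``round((d + 3)/2)``
  nodes.  Sigmoid activations, squared-error objective, full-batch gradient
  descent, seeded Xavier initialization.  The network standardizes its inputs
  internally (training mean/sd stored with the weights) so that raw-count
  features cannot saturate the sigmoids; this is a property of the network,
  not a pipeline step.

Validation follows the subject-wise protocol: each fold holds out every
recording of one subject and trains on the rest (leave-one-subject-out).
The default training regime samples 5 instances per class per test, the
size at which accuracy peaks before overfitting sets in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.svm import SVC

from .errors import ParameterError, TrainingError, ValidationError
from .features import FeatureVector

MODEL_FORMAT_VERSION = 1


@dataclass
class LabeledDataset:
    """Feature rows with true scores and subject ids for one test."""

    X: np.ndarray
    y: np.ndarray
    subjects: List[str]
    test_id: str
    feature_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D (rows of feature vectors)")
        if len(self.y) != len(self.X) or len(self.subjects) != len(self.X):
            raise ValidationError("X, y and subjects must have equal length")
        if not np.isin(self.y, (0, 1, 2)).all():
            raise ValidationError("labels must lie in {0, 1, 2}")

    @classmethod
    def from_rows(
        cls, rows: Sequence[Tuple[FeatureVector, int, str]], test_id: str
    ) -> "LabeledDataset":
        if not rows:
            raise ValidationError("empty dataset")
        names = rows[0][0].names
        for fv, _, _ in rows:
            if fv.names != names:
                raise ValidationError("inconsistent feature vectors in dataset")
        return cls(
            X=np.vstack([fv.values for fv, _, _ in rows]),
            y=np.array([label for _, label, _ in rows]),
            subjects=[subj for _, _, subj in rows],
            test_id=test_id,
            feature_names=list(names),
        )

    def __len__(self) -> int:
        return len(self.y)

    @property
    def dimension(self) -> int:
        return self.X.shape[1]

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            subjects=[self.subjects[i] for i in idx],
            test_id=self.test_id,
            feature_names=self.feature_names,
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def hidden_layer_size(n_inputs: int, n_outputs: int = 3) -> int:
    """Hidden-node count: halfway between input and output, half-up rounding."""
    return int(np.floor((n_inputs + n_outputs) / 2 + 0.5))


@dataclass
class ClassifierModel:
    """A fitted per-test scoring model (SVM or BNN), JSON-serializable."""

    kind: str
    test_id: str
    dimension: int
    params: dict
    meta: dict = field(default_factory=dict)

    def _x(self, x) -> np.ndarray:
        if isinstance(x, FeatureVector):
            if x.test_id != self.test_id:
                raise ValidationError(
                    f"feature vector for {x.test_id!r} fed to {self.test_id!r} model"
                )
            x = x.values
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dimension,):
            raise ValidationError(
                f"dimension mismatch: model expects {self.dimension}, got {x.shape}"
            )
        return x

    def decision_values(self, x) -> Tuple[np.ndarray, np.ndarray]:
        """(class labels, per-class decision values / output activations)."""
        x = self._x(x)
        if self.kind == "svm":
            classes = np.asarray(self.params["classes"], dtype=int)
            w = np.asarray(self.params["coef"], dtype=float)
            b = np.asarray(self.params["intercept"], dtype=float)
            decisions = w @ x + b  # one value per class pair, >0 favors pair[0]
            votes = np.zeros(len(classes))
            margin = np.zeros(len(classes))
            for (i, j), d in zip(self.params["pairs"], decisions):
                winner = i if d > 0 else j
                votes[winner] += 1
                margin[i] += d
                margin[j] -= d
            # ranking: vote count, then summed margins; argmax ties -> lowest
            return classes, votes + 1e-9 * np.tanh(margin)
        if self.kind == "bnn":
            w1 = np.asarray(self.params["W1"])
            b1 = np.asarray(self.params["b1"])
            w2 = np.asarray(self.params["W2"])
            b2 = np.asarray(self.params["b2"])
            mu = np.asarray(self.params["mu"])
            sd = np.asarray(self.params["sd"])
            h = _sigmoid((x - mu) / sd @ w1 + b1)
            o = _sigmoid(h @ w2 + b2)
            return np.arange(3), o
        raise ValidationError(f"unknown model kind {self.kind!r}")

    def predict(self, x) -> int:
        """Score in {0, 1, 2}; ties resolve to the lowest score."""
        classes, values = self.decision_values(x)
        return int(classes[int(np.argmax(values))])

    def to_obj(self) -> dict:
        def clean(v):
            return v.tolist() if isinstance(v, np.ndarray) else v

        return {
            "model_format_version": MODEL_FORMAT_VERSION,
            "kind": self.kind,
            "test_id": self.test_id,
            "dimension": self.dimension,
            "params": {k: clean(v) for k, v in self.params.items()},
            "meta": self.meta,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_obj(), fh)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("model_format_version") != MODEL_FORMAT_VERSION:
            raise ValidationError(f"{path}: unsupported model format")
        return cls(
            kind=obj["kind"],
            test_id=obj["test_id"],
            dimension=obj["dimension"],
            params=obj["params"],
            meta=obj.get("meta", {}),
        )


def _check_trainable(data: LabeledDataset) -> np.ndarray:
    classes = np.unique(data.y)
    if len(classes) < 2:
        raise TrainingError(
            f"test {data.test_id!r}: training data contains a single class"
        )
    return classes


def train_svm(data: LabeledDataset) -> ClassifierModel:
    """Fit pairwise linear-kernel SVMs (default C) on unscaled features.

    One binary machine per pair of present scores, libsvm's default
    multiclass arrangement; prediction is by majority vote.
    """
    classes = _check_trainable(data)
    pairs = []
    coef = []
    intercept = []
    for ia in range(len(classes)):
        for ib in range(ia + 1, len(classes)):
            ca, cb = classes[ia], classes[ib]
            mask = (data.y == ca) | (data.y == cb)
            clf = SVC(kernel="linear")
            # positive decision value must favor the pair's first class
            clf.fit(data.X[mask], (data.y[mask] == ca).astype(int))
            pairs.append([int(ia), int(ib)])
            coef.append(clf.coef_[0].tolist())
            intercept.append(float(clf.intercept_[0]))
    n_per_class = {int(c): int((data.y == c).sum()) for c in classes}
    return ClassifierModel(
        kind="svm",
        test_id=data.test_id,
        dimension=data.dimension,
        params={
            "classes": classes.tolist(),
            "pairs": pairs,
            "coef": coef,
            "intercept": intercept,
        },
        meta={"n_per_class": n_per_class},
    )


def train_bnn(
    data: LabeledDataset,
    seed: int = 0,
    epochs: int = 2000,
    learning_rate: float = 1.0,
) -> ClassifierModel:
    """Train the 3-layer backpropagation network; deterministic given seed."""
    if epochs <= 0:
        raise ParameterError("epochs must be > 0")
    if learning_rate <= 0:
        raise ParameterError("learning_rate must be > 0")
    _check_trainable(data)
    d = data.dimension
    h = hidden_layer_size(d)
    rng = np.random.default_rng(seed)
    lim1 = np.sqrt(6.0 / (d + h))
    lim2 = np.sqrt(6.0 / (h + 3))
    w1 = rng.uniform(-lim1, lim1, size=(d, h))
    b1 = np.zeros(h)
    w2 = rng.uniform(-lim2, lim2, size=(h, 3))
    b2 = np.zeros(3)

    mu = data.X.mean(axis=0)
    sd = data.X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    xn = (data.X - mu) / sd
    t = np.zeros((len(data), 3))
    t[np.arange(len(data)), data.y] = 1.0

    n = len(data)
    for _ in range(epochs):
        hid = _sigmoid(xn @ w1 + b1)
        out = _sigmoid(hid @ w2 + b2)
        delta_o = (out - t) * out * (1.0 - out)
        delta_h = (delta_o @ w2.T) * hid * (1.0 - hid)
        w2 -= learning_rate * hid.T @ delta_o / n
        b2 -= learning_rate * delta_o.sum(axis=0) / n
        w1 -= learning_rate * xn.T @ delta_h / n
        b1 -= learning_rate * delta_h.sum(axis=0) / n

    n_per_class = {int(c): int((data.y == c).sum()) for c in np.unique(data.y)}
    return ClassifierModel(
        kind="bnn",
        test_id=data.test_id,
        dimension=d,
        params={"W1": w1, "b1": b1, "W2": w2, "b2": b2, "mu": mu, "sd": sd},
        meta={
            "n_per_class": n_per_class,
            "seed": int(seed),
            "epochs": int(epochs),
            "learning_rate": float(learning_rate),
            "hidden": int(h),
        },
    )


TRAINERS = {"svm": train_svm, "bnn": train_bnn}


def _train(trainer: str, data: LabeledDataset, **kwargs) -> ClassifierModel:
    if trainer not in TRAINERS:
        raise ParameterError(f"unknown trainer {trainer!r}")
    return TRAINERS[trainer](data, **kwargs)


def accuracy(predictions: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of movements classified at their true score."""
    if len(predictions) != len(truth):
        raise ParameterError("predictions and truth must have equal length")
    if len(predictions) == 0:
        raise ParameterError("accuracy of empty lists is undefined")
    return float(np.mean(np.asarray(predictions) == np.asarray(truth)))


@dataclass
class CrossValResult:
    per_subject: Dict[str, float]
    skipped: Dict[str, str] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    @property
    def n_folds(self) -> int:
        return len(self.per_subject) + len(self.skipped)


def _subsample_per_class(
    data: LabeledDataset, per_class: int, rng: np.random.Generator
) -> LabeledDataset:
    idx: List[int] = []
    for c in np.unique(data.y):
        members = np.flatnonzero(data.y == c)
        if len(members) < per_class:
            raise ParameterError(
                f"class {c}: only {len(members)} examples, need {per_class}"
            )
        idx.extend(rng.choice(members, size=per_class, replace=False))
    return data.subset(np.array(sorted(idx)))


def crossval_by_subject(
    data: LabeledDataset,
    trainer: str = "svm",
    instances_per_class: Optional[int] = None,
    seed: int = 0,
    **trainer_kwargs,
) -> CrossValResult:
    """Leave-one-subject-out validation (the subject-wise v-fold protocol).

    Each fold tests on all recordings of one subject and trains on everyone
    else's, optionally subsampling ``instances_per_class`` training rows per
    score (seeded).  Folds whose training partition collapses to one class
    are skipped with a warning.
    """
    subjects = list(dict.fromkeys(data.subjects))
    if len(subjects) < 2:
        raise ValidationError("subject-wise cross-validation needs >= 2 subjects")
    if trainer == "bnn":
        trainer_kwargs.setdefault("seed", seed)
    subj_arr = np.array(data.subjects)
    per_subject: Dict[str, float] = {}
    skipped: Dict[str, str] = {}
    for k, held_out in enumerate(subjects):
        test_mask = subj_arr == held_out
        train = data.subset(~test_mask)
        if instances_per_class is not None:
            rng = np.random.default_rng([seed, k])
            train = _subsample_per_class(train, instances_per_class, rng)
        if len(np.unique(train.y)) < 2:
            msg = f"fold {held_out!r}: single-class training partition"
            warnings.warn(msg)
            skipped[held_out] = msg
            continue
        model = _train(trainer, train, **trainer_kwargs)
        test = data.subset(test_mask)
        preds = [model.predict(x) for x in test.X]
        per_subject[held_out] = accuracy(preds, test.y)
    return CrossValResult(per_subject=per_subject, skipped=skipped)


def training_curve(
    data: LabeledDataset,
    instances_per_class: Sequence[int],
    reps: int = 10,
    seed: int = 0,
    trainer: str = "svm",
    **trainer_kwargs,
) -> Dict[int, float]:
    """Held-out accuracy as a function of training instances per class.

    For each size ``m``: sample ``m`` rows per score (seeded), train, score
    the remaining rows, and average over ``reps`` repetitions.  When every
    row lands in the training sample the model is evaluated on it (plain
    training accuracy).
    """
    result: Dict[int, float] = {}
    for m in instances_per_class:
        accs = []
        for r in range(reps):
            rng = np.random.default_rng([seed, int(m), r])
            train = _subsample_per_class(data, m, rng)
            used = set(map(tuple, train.X))
            mask = np.array([tuple(row) not in used for row in data.X])
            test = data.subset(mask) if mask.any() else train
            model = _train(trainer, train, **trainer_kwargs)
            preds = [model.predict(x) for x in test.X]
            accs.append(accuracy(preds, test.y))
        result[int(m)] = float(np.mean(accs))
    return result
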