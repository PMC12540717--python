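"""Classifier harness: temporal split, backend registry, metrics, diagnostics.

The featured classifier is the extremely-randomized-trees ensemble (Extra
Trees), trained on the window-feature matrix.  Data are split temporally —
the first ``train_frac`` of each gesture's contiguous window block goes to
training, the remainder to test, with no shuffling — so evaluation respects
the order the windows were recorded in.

Precision/recall/F1 are support-weighted averages of per-class values;
under weighted averaging recall is identical to accuracy, which the
reporting relies on.

The ``split_score`` diagnostic scores one candidate tree split as the
entropy-normalized mutual information between split outcome and class:

    S_c(s, S) = 2 * I(split; class) / (H_split + H_class)

with entropies in bits; 1 for a pure balanced binary split, 0 for a split
independent of the labels.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as scipy_stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    DegenerateVarianceError,
    RegistryError,
    SplitError,
    ValidationError,
)
from .features import FeatureMatrix
from .space import HyperparamSpace, default_et_space

__all__ = [
    "EvalReport",
    "LabelPartition",
    "TrainedModel",
    "BACKENDS",
    "temporal_split",
    "train_classifier",
    "predict",
    "evaluate",
    "report_from_predictions",
    "split_score",
    "paired_ttest",
    "cross_session_eval",
]


# ---------------------------------------------------------------------------
# temporal split
# ---------------------------------------------------------------------------

def temporal_split(
    m: FeatureMatrix, train_frac: float = 0.7, per_class: bool = True
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Order-preserving train/test split.

    With ``per_class=True`` (default) the split is applied within each
    gesture's block of rows (in row order), so every class appears in both
    parts: the first floor(train_frac * n_class) rows of each class train.
    ``per_class=False`` splits the matrix globally at one cut point.
    """
    if not 0 < train_frac < 1:
        raise SplitError(f"train_frac must lie strictly in (0, 1), got {train_frac}")
    n = m.n_rows
    if per_class:
        train_idx, test_idx = [], []
        for cls in m.classes:
            rows = np.flatnonzero(m.gesture == cls)
            if rows.size < 2:
                raise SplitError(f"class {cls!r} has {rows.size} window(s); need >= 2")
            k = int(np.floor(train_frac * rows.size))
            if k == 0 or k == rows.size:
                raise SplitError(
                    f"train_frac {train_frac} leaves class {cls!r} empty on one side"
                )
            train_idx.append(rows[:k])
            test_idx.append(rows[k:])
        train_idx = np.sort(np.concatenate(train_idx))
        test_idx = np.sort(np.concatenate(test_idx))
    else:
        if n < 2:
            raise SplitError("need at least 2 rows to split")
        k = int(np.floor(train_frac * n))
        train_idx = np.arange(k)
        test_idx = np.arange(k, n)
    return m.take(train_idx), m.take(test_idx)


# ---------------------------------------------------------------------------
# backend registry
# ---------------------------------------------------------------------------

def _make_et(hp: dict, seed: int):
    return ExtraTreesClassifier(random_state=seed, n_jobs=1, **hp)


#: name -> (estimator factory(hp, seed), declared hyperparameter space or None)
BACKENDS: dict[str, tuple] = {
    "ET": (_make_et, "et_space"),
    "DT": (lambda hp, seed: DecisionTreeClassifier(random_state=seed, **hp), None),
    "RF": (lambda hp, seed: RandomForestClassifier(random_state=seed, n_jobs=1, **hp), None),
    "ADB": (lambda hp, seed: AdaBoostClassifier(random_state=seed, **hp), None),
    "BAG": (lambda hp, seed: BaggingClassifier(random_state=seed, n_jobs=1, **hp), None),
    "GB": (lambda hp, seed: GradientBoostingClassifier(random_state=seed, **hp), None),
    "KNN": (lambda hp, seed: KNeighborsClassifier(**hp), None),
    "LR": (lambda hp, seed: LogisticRegression(random_state=seed, max_iter=1000, **hp), None),
    "NB": (lambda hp, seed: GaussianNB(**hp), None),
    "SVM": (lambda hp, seed: SVC(random_state=seed, **hp), None),
}


@dataclass
class TrainedModel:
    """A fitted backend plus the column schema it was trained on."""

    backend: str
    estimator: object
    columns: list[str]
    classes: list[str]
    hp: dict = field(default_factory=dict)


def backend_space(name: str, n_features: int = 34) -> HyperparamSpace | None:
    entry = BACKENDS.get(name)
    if entry is None:
        raise RegistryError(
            f"unknown backend {name!r}; registered: {sorted(BACKENDS)}"
        )
    return default_et_space(n_features) if entry[1] == "et_space" else None


def train_classifier(
    backend_name: str, hp: dict, train: FeatureMatrix, seed: int = 0
) -> TrainedModel:
    """Fit a registered backend on a feature matrix; deterministic given seed."""
    if backend_name not in BACKENDS:
        raise RegistryError(
            f"unknown backend {backend_name!r}; registered: {sorted(BACKENDS)}"
        )
    space = backend_space(backend_name, n_features=len(train.columns))
    if space is not None:
        space.validate(hp)
    factory = BACKENDS[backend_name][0]
    est = factory(dict(hp), int(seed))
    est.fit(train.values, train.gesture.astype(str))
    return TrainedModel(
        backend=backend_name,
        estimator=est,
        columns=list(train.columns),
        classes=[str(c) for c in est.classes_],
        hp=dict(hp),
    )


def predict(model: TrainedModel, m: FeatureMatrix) -> np.ndarray:
    if list(m.columns) != model.columns:
        raise ValidationError("feature matrix columns do not match the trained schema")
    return np.asarray(model.estimator.predict(m.values), dtype=object)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Accuracy, support-weighted precision/recall/F1, confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    labels: list[str]
    per_class: dict[str, dict[str, float]]
    inference_time_ms: float = 0.0

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": round(100 * self.accuracy, 2),
            "precision_pct": round(100 * self.precision, 2),
            "recall_pct": round(100 * self.recall, 2),
            "f1_pct": round(100 * self.f1, 2),
            "labels": self.labels,
            "confusion": [[int(v) for v in row] for row in self.confusion],
            "per_class": self.per_class,
            "inference_time_ms": round(self.inference_time_ms, 3),
        }


def report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, inference_time_ms: float = 0.0
) -> EvalReport:
    """Compute the full metric set from label vectors.

    Confusion rows are true classes.  Per-class precision uses 0 for classes
    never predicted; the weighted averages weight per-class values by true
    support, which makes weighted recall equal accuracy exactly.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0:
        raise SplitError("empty test set")
    labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    total = cm.sum()
    diag = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)       # true counts per class
    predicted = cm.sum(axis=0).astype(float)     # predicted counts per class

    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(predicted > 0, diag / predicted, 0.0)
        rec_c = np.where(support > 0, diag / support, 0.0)
        denom = prec_c + rec_c
        f1_c = np.where(denom > 0, 2 * prec_c * rec_c / denom, 0.0)

    w = support / total
    per_class = {
        lab: {
            "precision": float(prec_c[i]),
            "recall": float(rec_c[i]),
            "f1": float(f1_c[i]),
            "support": int(support[i]),
        }
        for i, lab in enumerate(labels)
    }
    return EvalReport(
        accuracy=float(diag.sum() / total),
        precision=float((w * prec_c).sum()),
        recall=float((w * rec_c).sum()),
        f1=float((w * f1_c).sum()),
        confusion=cm,
        labels=[str(x) for x in labels],
        per_class=per_class,
        inference_time_ms=inference_time_ms,
    )


def evaluate(model: TrainedModel, test: FeatureMatrix) -> EvalReport:
    """Predict on a test matrix and compute the metric set."""
    t0 = time.perf_counter()
    y_pred = predict(model, test)
    dt_ms = (time.perf_counter() - t0) * 1000.0
    return report_from_predictions(test.gesture, y_pred, inference_time_ms=dt_ms)


# ---------------------------------------------------------------------------
# split-score diagnostic
# ---------------------------------------------------------------------------

@dataclass
class LabelPartition:
    """Class counts of a parent node and its two children after a split."""

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right class-count vectors must align")
        if np.any(self.left < 0) or np.any(self.right < 0):
            raise ValueError("class counts must be non-negative")
        if self.left.sum() == 0 or self.right.sum() == 0:
            raise ValueError("both children must be non-empty")

    @property
    def parent(self) -> np.ndarray:
        return self.left + self.right


def _entropy_bits(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def split_score(p: LabelPartition) -> float:
    """Normalized information gain of a binary split, in [0, 1].

    S_c = 2 I(split; class) / (H_split + H_class), entropies in bits.
    """
    parent = p.parent
    total = parent.sum()
    if total < 2:
        raise ValueError("parent must hold at least 2 items")
    h_class = _entropy_bits(parent)
    h_split = _entropy_bits(np.array([p.left.sum(), p.right.sum()]))
    cond = (p.left.sum() / total) * _entropy_bits(p.left) + (
        p.right.sum() / total
    ) * _entropy_bits(p.right)
    info = h_class - cond
    denom = h_class + h_split
    if denom == 0:
        return 0.0
    s = 2.0 * info / denom
    # clip tiny negative rounding noise
    return float(min(max(s, 0.0), 1.0))


# ---------------------------------------------------------------------------
# paired t-test and cross-session protocol
# ---------------------------------------------------------------------------

def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on matched accuracy vectors.

    Antisymmetric in argument order; raises
    :class:`DegenerateVarianceError` when the paired differences have zero
    sample variance (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and the same length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.var(d, ddof=1) == 0:
        raise DegenerateVarianceError(
            "paired differences are constant; t statistic undefined"
        )
    res = scipy_stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def cross_session_eval(
    features: FeatureMatrix,
    train_session: str,
    test_sessions: list[str],
    backend: str = "ET",
    hp: dict | None = None,
    seed: int = 0,
) -> list[tuple[str, EvalReport]]:
    """Train on one session's windows, evaluate on each held-out session.

    Returns ``[(test_session, EvalReport), ...]`` in the order given; no test
    row is ever drawn from the training session.
    """
    hp = hp or {}
    present = set(features.session.tolist())
    for sid in [train_session, *test_sessions]:
        if sid not in present:
            raise SplitError(f"session {sid!r} not present in the feature matrix")
    train = features.take(np.flatnonzero(features.session == train_session))
    model = train_classifier(backend, hp, train, seed=seed)
    reports = []
    for sid in test_sessions:
        if sid == train_session:
            raise SplitError("test session equals the training session")
        test = features.take(np.flatnonzero(features.session == sid))
        reports.append((sid, evaluate(model, test)))
    return reports
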