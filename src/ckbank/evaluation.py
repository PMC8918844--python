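"""Metrics, ROC/AUC, cross-validation, and the head-imbalance comparison.

Binary metrics follow the clinical convention: class 1 is the positive
class (the infection/ischaemia analogue), sensitivity is the
true-positive rate and specificity the true-negative rate.  Any 0/0
metric is reported as undefined with a reason — never silently zero.

AUC uses the rank (Mann-Whitney) formulation — the probability that a
random positive outscores a random negative, ties counted one half —
with ROC points from scikit-learn; trapezoidal area over those points
equals the rank value, and a test holds the two routes to each other.

The imbalance comparison trains the knowledge-bank head and a plain
linear + cross-entropy head on identical data streams (matched seeds,
same encoder/projection treatment) and reports each head's
|sensitivity - specificity| gap: a head that collapses onto the
majority class shows a large gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, DataError
from .model import CKBModel
from .synthetic import SyntheticSpec, generate_features
from .training import TrainingConfig

__all__ = [
    "ConfusionCounts", "MetricReport", "confusion_counts", "compute_metrics",
    "roc_auc", "evaluate_model", "crossval", "imbalance_comparison",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Scalar metrics in [0, 1]; ``None`` where undefined (see ``undefined``).

    Cross-validation fills ``per_fold`` (one row per fold) and
    ``mean``/``sd`` dictionaries.
    """

    accuracy: float | None = None
    sensitivity: float | None = None
    precision: float | None = None
    specificity: float | None = None
    f_measure: float | None = None
    auc: float | None = None
    n_samples: int = 0
    undefined: dict[str, str] = field(default_factory=dict)
    per_fold: pd.DataFrame | None = None
    mean: dict[str, float] | None = None
    sd: dict[str, float] | None = None

    _METRICS = ("accuracy", "sensitivity", "precision", "specificity", "f_measure", "auc")

    def to_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        out = {m: (None if getattr(self, m) is None else scale * getattr(self, m))
               for m in self._METRICS}
        out["n_samples"] = self.n_samples
        if self.undefined:
            out["undefined"] = dict(self.undefined)
        if self.mean is not None:
            out["mean"] = {k: scale * v for k, v in self.mean.items()}
            out["sd"] = {k: scale * v for k, v in self.sd.items()}
        return out

    def to_text(self, percent: bool = False) -> str:
        lines = []
        for key, value in self.to_dict(percent=percent).items():
            if isinstance(value, dict):
                for k, v in value.items():
                    lines.append(f"{key}.{k} = {v}")
            else:
                lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"


def confusion_counts(predictions, labels, positive: int = 1) -> ConfusionCounts:
    """Tally a binary confusion matrix from prediction/label pairs."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise DataError("predictions and labels differ in length")
    pos_pred = predictions == positive
    pos_true = labels == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
    )


def _ratio(num: int, den: int, name: str, reason: str, undefined: dict):
    if den == 0:
        undefined[name] = reason
        return None
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, precision, specificity, F-measure from counts."""
    if counts.total == 0:
        raise DataError("no evaluated samples")
    undefined: dict[str, str] = {}
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity",
                  "no positive samples (tp + fn = 0)", undefined)
    prec = _ratio(counts.tp, counts.tp + counts.fp, "precision",
                  "no positive predictions (tp + fp = 0)", undefined)
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity",
                  "no negative samples (tn + fp = 0)", undefined)
    if sens is None or prec is None:
        undefined["f_measure"] = "sensitivity or precision undefined"
        f_measure = None
    elif sens + prec == 0:
        undefined["f_measure"] = "precision + sensitivity = 0"
        f_measure = None
    else:
        f_measure = 2 * prec * sens / (prec + sens)
    return MetricReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        sensitivity=sens, precision=prec, specificity=spec, f_measure=f_measure,
        n_samples=counts.total, undefined=undefined,
    )


def roc_auc(scores, labels, positive: int = 1):
    """Rank-formulation AUC plus the ROC curve.

    Returns ``(auc, points)`` where ``points`` is a DataFrame with
    columns ``fpr``, ``tpr``, ``threshold``.  AUC is the probability a
    positive's score exceeds a negative's, ties counted one half; the
    trapezoidal area under the returned points equals it.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("ROC/AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = roc_curve(pos.astype(int), scores, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return float(auc), points


def evaluate_model(model: CKBModel, X, y, positive: int = 1) -> MetricReport:
    """Confusion metrics plus AUC for a fitted model on held-out data.

    AUC uses the positive-class softmax probability as the score; for a
    single-class evaluation set AUC is reported as undefined rather than
    failing the whole report.
    """
    y = np.asarray(y)
    proba = model.predict_proba(X)
    predictions = np.argmax(proba, axis=-1)
    if model.head.n_classes == 2:
        report = compute_metrics(confusion_counts(predictions, y, positive=positive))
        try:
            report.auc, _ = roc_auc(proba[:, positive], y, positive=positive)
        except DataError as exc:
            report.undefined["auc"] = str(exc)
    else:
        report = MetricReport(accuracy=float(np.mean(predictions == y)),
                              n_samples=len(y),
                              undefined={m: "binary-only metric"
                                         for m in ("sensitivity", "precision",
                                                   "specificity", "f_measure", "auc")})
    return report


def _aggregate(per_fold: pd.DataFrame) -> MetricReport:
    metrics = [m for m in MetricReport._METRICS if m in per_fold.columns]
    mean = {m: float(per_fold[m].mean()) for m in metrics}
    sd = {m: float(per_fold[m].std(ddof=1)) for m in metrics}
    report = MetricReport(n_samples=int(per_fold["n_samples"].sum()),
                          per_fold=per_fold, mean=mean, sd=sd)
    for m in metrics:
        setattr(report, m, mean[m])
    return report


def crossval(data, config: TrainingConfig, n_folds: int = 5, seed: int = 0,
             model_builder=None, positive: int = 1) -> MetricReport:
    """Stratified k-fold cross-validation of the full pipeline.

    ``data`` is ``(X, y)``; a fresh model is built and trained per fold.
    ``model_builder(n_classes) -> CKBModel`` overrides the default
    (identity encoder on feature vectors).  Fold assignment is a pure
    function of ``seed``.
    """
    X, y = data
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise DataError(
            f"every class needs >= {n_folds} samples; smallest has {counts.min()}"
        )
    n_classes = int(classes.max()) + 1
    if model_builder is None:
        def model_builder(n_cls):
            return CKBModel.build(input_shape=X.shape[1:], n_classes=n_cls,
                                  config=config, encoder_kind="identity")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = model_builder(n_classes)
        model.fit(X[train_idx], y[train_idx])
        report = evaluate_model(model, X[test_idx], y[test_idx], positive=positive)
        row = {"fold": fold, "n_samples": report.n_samples}
        for m in MetricReport._METRICS:
            value = getattr(report, m)
            if value is not None:
                row[m] = value
        rows.append(row)
    return _aggregate(pd.DataFrame(rows))


def imbalance_comparison(spec: SyntheticSpec, config: TrainingConfig,
                         seeds, n_train: int = 1459, n_test: int = 1459) -> pd.DataFrame:
    """Bank head vs. linear head under class imbalance, matched seed by seed.

    For each seed, one train/test draw from ``spec`` is shared by both
    heads; both use the identity encoder and projection bypass so the
    heads see the very same representations.  Returns a tidy frame with
    one row per (seed, head) holding sensitivity, specificity and the
    balance gap |sensitivity - specificity|.
    """
    if spec.image_mode or spec.n_classes != 2:
        raise ConfigurationError("imbalance comparison expects a binary feature spec")
    rows = []
    for seed in seeds:
        seed = int(seed)
        X_train, y_train = generate_features(spec, n_train, seed=seed)
        X_test, y_test = generate_features(spec, n_test, seed=seed + 10_000)
        if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
            raise DataError(f"seed {seed}: a class is absent from the draw")
        run_config = config.replace(seed=seed, dim=spec.feature_dim)
        for head_kind in ("ckb", "linear"):
            model = CKBModel.build(input_shape=(spec.feature_dim,), n_classes=2,
                                   config=run_config, encoder_kind="identity",
                                   head_kind=head_kind, projection_bypass=True)
            model.fit(X_train, y_train)
            report = evaluate_model(model, X_test, y_test)
            sens = report.sensitivity if report.sensitivity is not None else 0.0
            spec_ = report.specificity if report.specificity is not None else 0.0
            rows.append({
                "seed": seed, "head": head_kind,
                "accuracy": report.accuracy,
                "sensitivity": sens, "specificity": spec_,
                "gap": abs(sens - spec_),
            })
    return pd.DataFrame(rows)


def median_gaps(comparison: pd.DataFrame) -> dict[str, float]:
    """Median |sensitivity - specificity| per head from a comparison frame."""
    return {head: float(g["gap"].median())
            for head, g in comparison.groupby("head")}
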