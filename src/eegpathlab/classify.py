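"""Gradient-boosted classification and the evaluation metrics.

The learners are consumed off-the-shelf behind a minimal fit/predict
registry — the contribution of this package is the feature engineering, not
the boosting machinery.  Registered backends: ``xgboost``, ``lightgbm``,
``sklearn`` (HistGradientBoosting) and, when the optional package is
installed, ``catboost``.  Per-backend default hyperparameters follow the
reference configuration: 1080 estimators; max depth 4 (catboost),
6 (xgboost), 4 (lightgbm); learning rate 0.03 / 0.02 / 0.04.

The positive class is *abnormal*.  Metrics: accuracy (TP+TN)/total,
F1 = 2TP/(2TP+FP+FN), and the G-mean, the geometric mean of sensitivity
TP/(TP+FN) and specificity TN/(TN+FP).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .recording import ABNORMAL, NORMAL

logger = logging.getLogger(__name__)

#: backend -> (max_depth, learning_rate) reference defaults
BACKEND_DEFAULTS: dict[str, tuple[int, float]] = {
    "catboost": (4, 0.03),
    "xgboost": (6, 0.02),
    "lightgbm": (4, 0.04),
    "sklearn": (4, 0.03),
}
DEFAULT_N_ESTIMATORS = 1080

_LABEL_CODE = {NORMAL: 0, ABNORMAL: 1}


def encode_labels(y) -> np.ndarray:
    try:
        return np.asarray([_LABEL_CODE[v] for v in y], dtype=int)
    except KeyError as exc:
        raise ValidationError("y", f"unknown class label {exc.args[0]!r}") from exc


def decode_labels(codes: np.ndarray) -> list[str]:
    inv = {v: k for k, v in _LABEL_CODE.items()}
    return [inv[int(c)] for c in codes]


@dataclass
class ClassifierConfig:
    """Backend choice plus the hyperparameters that are pinned per backend."""

    backend: str = "xgboost"
    n_estimators: int = DEFAULT_N_ESTIMATORS
    max_depth: int | None = None
    learning_rate: float | None = None
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def resolved(self) -> tuple[int, float]:
        if self.backend not in BACKEND_DEFAULTS:
            raise ValidationError("backend", f"unregistered backend {self.backend!r}")
        d_depth, d_lr = BACKEND_DEFAULTS[self.backend]
        depth = self.max_depth if self.max_depth is not None else d_depth
        lr = self.learning_rate if self.learning_rate is not None else d_lr
        if self.n_estimators < 1 or depth < 1 or lr <= 0:
            raise ValidationError("classifier", "hyperparameters must be positive")
        return depth, lr


def make_estimator(cfg: ClassifierConfig):
    """Instantiate the configured backend (fit/predict interface)."""
    depth, lr = cfg.resolved()
    if cfg.backend == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=cfg.n_estimators,
            max_depth=depth,
            learning_rate=lr,
            random_state=cfg.seed,
            tree_method="hist",
            eval_metric="logloss",
            **cfg.extra,
        )
    if cfg.backend == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=cfg.n_estimators,
            max_depth=depth,
            learning_rate=lr,
            random_state=cfg.seed,
            verbose=-1,
            **cfg.extra,
        )
    if cfg.backend == "sklearn":
        from sklearn.ensemble import HistGradientBoostingClassifier

        return HistGradientBoostingClassifier(
            max_iter=cfg.n_estimators,
            max_depth=depth,
            learning_rate=lr,
            random_state=cfg.seed,
            **cfg.extra,
        )
    if cfg.backend == "catboost":
        try:
            from catboost import CatBoostClassifier
        except ImportError as exc:
            raise ImportError(
                "the 'catboost' backend requires the optional catboost package; "
                "use 'xgboost', 'lightgbm' or 'sklearn' instead"
            ) from exc
        return CatBoostClassifier(
            iterations=cfg.n_estimators,
            depth=depth,
            learning_rate=lr,
            random_seed=cfg.seed,
            verbose=False,
            **cfg.extra,
        )
    raise ValidationError("backend", f"unregistered backend {cfg.backend!r}")


def train(x: np.ndarray, y, cfg: ClassifierConfig):
    """Fit the configured estimator on encoded labels (abnormal = 1)."""
    x = np.asarray(x, dtype=float)
    codes = encode_labels(y)
    if x.ndim != 2 or x.shape[0] != len(codes):
        raise ValidationError("x", "need a (samples x features) matrix matching y")
    if len(np.unique(codes)) < 2:
        raise ValidationError("y", "training labels contain a single class")
    est = make_estimator(cfg)
    est.fit(x, codes)
    return est


def predict(model, x: np.ndarray) -> list[str]:
    return decode_labels(np.asarray(model.predict(np.asarray(x, dtype=float))))


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with abnormal as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str = ABNORMAL

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Accuracy, F1 and G-mean as proportions in [0, 1], plus the counts."""

    accuracy: float
    f1: float
    g_mean: float
    confusion: ConfusionMatrix

    @property
    def sensitivity(self) -> float:
        c = self.confusion
        return c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0

    @property
    def specificity(self) -> float:
        c = self.confusion
        return c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0

    @property
    def false_negative_rate(self) -> float:
        c = self.confusion
        return c.fn / (c.tp + c.fn) if c.tp + c.fn else 0.0

    @property
    def false_positive_rate(self) -> float:
        c = self.confusion
        return c.fp / (c.tn + c.fp) if c.tn + c.fp else 0.0

    def as_dict(self) -> dict:
        c = self.confusion
        return {
            "confusion": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
            "accuracy": self.accuracy,
            "f1": self.f1,
            "g_mean": self.g_mean,
        }


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Compute accuracy, F1 and G-mean directly from confusion counts."""
    if cm.total == 0:
        raise ValidationError("confusion", "empty confusion matrix")
    if min(cm.tp, cm.fp, cm.fn, cm.tn) < 0:
        raise ValidationError("confusion", "counts must be non-negative")
    accuracy = (cm.tp + cm.tn) / cm.total
    f1_denom = 2 * cm.tp + cm.fp + cm.fn
    f1 = 2 * cm.tp / f1_denom if f1_denom else 0.0
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    if pos == 0 or neg == 0:
        logger.warning("a class is absent from the evaluation set; G-mean recall set to 0")
    sens = cm.tp / pos if pos else 0.0
    spec = cm.tn / neg if neg else 0.0
    return MetricsReport(accuracy=accuracy, f1=f1, g_mean=math.sqrt(sens * spec), confusion=cm)


def evaluate(y_true, y_pred) -> MetricsReport:
    """Confusion matrix and metrics for string labels (abnormal positive)."""
    t = list(y_true)
    p = list(y_pred)
    if len(t) == 0 or len(t) != len(p):
        raise ValidationError("y_true", "need equal-length, non-empty label sequences")
    valid = set(_LABEL_CODE)
    if not set(t) <= valid or not set(p) <= valid:
        raise ValidationError("y_true", f"labels must be in {sorted(valid)}")
    tp = sum(1 for a, b in zip(t, p) if a == ABNORMAL and b == ABNORMAL)
    fn = sum(1 for a, b in zip(t, p) if a == ABNORMAL and b == NORMAL)
    fp = sum(1 for a, b in zip(t, p) if a == NORMAL and b == ABNORMAL)
    tn = sum(1 for a, b in zip(t, p) if a == NORMAL and b == NORMAL)
    return metrics_from_confusion(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
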