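"""Kruskal-Wallis significance screening of fused features.

Each feature column is tested independently against the class labels with
the rank-based Kruskal-Wallis H test (mid-ranks, standard tie correction,
chi-square upper-tail p with groups-1 degrees of freedom).  Features with
p < alpha (strict; default alpha = 0.01) are retained.  No multiple-testing
correction is applied by default — the screening is per-feature marginal —
but a Benjamini-Hochberg option is available.

The H statistic is implemented here because it is a named pipeline stage;
only the chi-square survival function is delegated to scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


def _kw_from_ranks(ranks: np.ndarray, groups: list[np.ndarray], n: int) -> np.ndarray:
    """Vectorized H over columns of a (n, p) rank matrix with tie correction."""
    h = np.zeros(ranks.shape[1]) if ranks.ndim == 2 else 0.0
    expected = (n + 1) / 2.0
    acc = 0.0
    for idx in groups:
        mean_rank = ranks[idx].mean(axis=0)
        acc = acc + len(idx) * (mean_rank - expected) ** 2
    h = 12.0 / (n * (n + 1)) * acc
    # tie correction: 1 - sum(t^3 - t)/(n^3 - n), per column
    sorted_r = np.sort(ranks, axis=0)
    if ranks.ndim == 1:
        sorted_r = sorted_r[:, None]
        h = np.atleast_1d(h)
    correction = np.ones(sorted_r.shape[1])
    for j in range(sorted_r.shape[1]):
        _, counts = np.unique(sorted_r[:, j], return_counts=True)
        correction[j] = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(correction > 0, h / np.where(correction > 0, correction, 1.0), 0.0)
    return h


def kruskal_wallis(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H test of one feature against group labels.

    Returns ``(H, p)``.  All-tied input degenerates to ``(0, 1)`` by
    convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.ndim != 1 or values.shape != labels.shape:
        raise ValidationError("values", "values and labels must be equal-length 1-D")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("labels", "need at least 2 groups")
    groups = [np.flatnonzero(labels == g) for g in uniq]
    if any(len(g) == 0 for g in groups):
        raise ValidationError("labels", "every group needs at least one observation")
    n = len(values)
    if n < 3:
        raise ValidationError("values", "need at least 3 observations in total")
    if np.all(values == values[0]):
        return 0.0, 1.0
    ranks = rankdata(values)
    h = float(_kw_from_ranks(ranks, groups, n)[0])
    p = float(chi2.sf(h, df=len(uniq) - 1))
    return h, p


@dataclass
class KWSelection:
    """Per-feature test results and the retained-feature mask."""

    h: np.ndarray
    p: np.ndarray
    alpha: float
    keep_mask: np.ndarray
    feature_names: list[str]

    @property
    def n_selected(self) -> int:
        return int(self.keep_mask.sum())


def fit_selection(
    x_train: np.ndarray,
    y_train: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    feature_names: list[str] | None = None,
    fdr: bool = False,
    fallback_k: int | None = None,
) -> KWSelection:
    """Test every feature column against the training labels; keep p < alpha.

    ``fdr=True`` switches to Benjamini-Hochberg control at level alpha.
    When nothing survives, the default is an error; ``fallback_k`` keeps the
    best k features instead (with a warning).
    """
    x = np.asarray(x_train, dtype=float)
    y = np.asarray(y_train)
    if x.ndim != 2 or x.shape[0] != len(y):
        raise ValidationError("x_train", "need a 2-D (samples x features) matrix matching y")
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise ValidationError("y_train", "need at least one sample per class")
    names = feature_names or [f"f{i}" for i in range(x.shape[1])]
    if len(names) != x.shape[1]:
        raise ValidationError("feature_names", "one name per feature column required")

    n = x.shape[0]
    groups = [np.flatnonzero(y == g) for g in uniq]
    ranks = rankdata(x, axis=0)
    h = _kw_from_ranks(ranks, groups, n)
    constant = np.all(x == x[0], axis=0)
    h[constant] = 0.0
    p = chi2.sf(h, df=len(uniq) - 1)
    p[constant] = 1.0

    if fdr:
        order = np.argsort(p)
        m = len(p)
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = p[order] <= thresh
        keep = np.zeros(m, dtype=bool)
        if passed.any():
            keep[order[: np.max(np.flatnonzero(passed)) + 1]] = True
    else:
        keep = p < alpha

    if not keep.any():
        if fallback_k is None:
            raise ValidationError(
                "alpha", f"no feature reached p < {alpha}; lower alpha or set fallback_k"
            )
        logger.warning("no feature reached p < %g; keeping best %d by p-value", alpha, fallback_k)
        keep = np.zeros(len(p), dtype=bool)
        keep[np.argsort(p)[:fallback_k]] = True

    return KWSelection(h=h, p=p, alpha=alpha, keep_mask=keep, feature_names=list(names))


def apply_selection(sel: KWSelection, x: np.ndarray) -> np.ndarray:
    """Subset any feature table by the trained mask, preserving order."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(sel.keep_mask):
        raise ValidationError("x", f"expected {len(sel.keep_mask)} feature columns")
    return x[:, sel.keep_mask]


def selection_report(sel: KWSelection) -> "pandas.DataFrame":  # noqa: F821
    """Tabular report: feature name, H, p, kept flag."""
    import pandas as pd

    return pd.DataFrame(
        {"feature": sel.feature_names, "H": sel.h, "p": sel.p, "kept": sel.keep_mask}
    )
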