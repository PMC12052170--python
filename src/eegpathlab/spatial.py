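"""Common Spatial Patterns on the time-frequency feature space.

CSP learns a channel-space projection that maximizes the variance of one
class while minimizing the other's.  Here the "trials" are not raw EEG but
each recording's C x (L*24) wavelet-statistics matrix, so the class
covariances are C x C over all time-frequency feature columns.

Fit procedure (two classes k = 1, 2):

1. Averaged normalized covariance per class,
   ``R̄_k = mean_i  F_i F_i' / trace(F_i F_i')``,
   with a small ridge on the diagonal for rank-deficient feature matrices.
2. Composite covariance ``R = R̄_1 + R̄_2 = U Λ U'`` (eigendecomposition,
   eigenvalues descending) and whitening ``P = Λ^(-1/2) U'``.
3. Whitened class covariances ``S_k = P R̄_k P'`` share eigenvectors ``B``
   and their eigenvalue diagonals satisfy ``E_1 + E_2 = I``; ``B`` is taken
   from ``S_1`` with eigenvalues sorted descending.
4. Spatial filters ``W = B' P``; the ``m`` first and ``m`` last rows (the
   extremes of the E_1 spectrum) are retained, 2m = 8 by default.

A recording is projected as ``Z = W_sel F`` and summarized by normalized
log-variances ``f_i = log(var(Z_i) / Σ_j var(Z_j))`` (natural log,
population variance), which are scale-invariant and sum to 1 after
exponentiation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .timefreq import TimeFreqFeatureMatrix

DEFAULT_N_COMPONENTS = 8


@dataclass
class CSPModel:
    """Fitted CSP filters and the intermediate whitening artifacts."""

    W: np.ndarray                 # full C x C filter matrix, rows = filters
    selected_rows: np.ndarray     # indices of the 2m retained filters
    R1: np.ndarray                # class-averaged normalized covariances
    R2: np.ndarray
    P: np.ndarray                 # whitening matrix
    B: np.ndarray                 # shared eigenvector matrix
    E1: np.ndarray                # class-1 eigenvalues (descending)
    E2: np.ndarray
    n1: int                       # training trial counts per class
    n2: int
    n_features: int               # training feature-column count

    @property
    def n_components(self) -> int:
        return len(self.selected_rows)

    @property
    def W_selected(self) -> np.ndarray:
        return self.W[self.selected_rows]

    def save(self, path: str | Path) -> None:
        payload = {
            "schema_version": 1,
            "n1": self.n1,
            "n2": self.n2,
            "n_features": self.n_features,
            "selected_rows": self.selected_rows.tolist(),
        }
        for name in ("W", "R1", "R2", "P", "B", "E1", "E2"):
            payload[name] = getattr(self, name).tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CSPModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema_version") != 1:
            raise ValidationError("schema_version", "unsupported CSP model schema")
        kwargs = {k: np.asarray(payload[k]) for k in ("W", "R1", "R2", "P", "B", "E1", "E2")}
        return cls(
            selected_rows=np.asarray(payload["selected_rows"], dtype=int),
            n1=payload["n1"],
            n2=payload["n2"],
            n_features=payload["n_features"],
            **kwargs,
        )


def _normalized_covariance(F: np.ndarray, reg_eps: float) -> np.ndarray:
    cov = F @ F.T
    tr = np.trace(cov)
    if tr <= 0:
        raise ValidationError("F", "feature matrix has zero energy")
    cov = cov / tr
    return cov + reg_eps * np.eye(cov.shape[0])


def fit_csp(
    train: list[tuple[TimeFreqFeatureMatrix, int]],
    n_components: int = DEFAULT_N_COMPONENTS,
    reg_eps: float = 1e-10,
) -> CSPModel:
    """Fit CSP from labeled training feature matrices.

    Parameters
    ----------
    train : list of (TimeFreqFeatureMatrix, k)
        Class codes k in {1, 2}.
    n_components : int
        Number of retained filters 2m (even, <= channel count).
    reg_eps : float
        Diagonal ridge added to each unit-trace class covariance.
    """
    if n_components % 2 or n_components < 2:
        raise ValidationError("n_components", "must be a positive even number")
    by_class: dict[int, list[np.ndarray]] = {1: [], 2: []}
    shapes = set()
    for m, k in train:
        if k not in (1, 2):
            raise ValidationError("train", f"class code must be 1 or 2, got {k!r}")
        f = np.asarray(m.F, dtype=float)
        shapes.add(f.shape)
        by_class[k].append(f)
    if len(shapes) != 1:
        raise ValidationError("train", f"inconsistent feature-matrix shapes {shapes}")
    if not by_class[1] or not by_class[2]:
        raise ValidationError("train", "need at least one trial in each class")
    c, n_feat = shapes.pop()
    if n_components > c:
        raise ValidationError("n_components", f"{n_components} filters > {c} channels")

    r1 = np.mean([_normalized_covariance(f, reg_eps) for f in by_class[1]], axis=0)
    r2 = np.mean([_normalized_covariance(f, reg_eps) for f in by_class[2]], axis=0)

    r = r1 + r2
    lam, u = np.linalg.eigh(r)
    lam, u = lam[::-1], u[:, ::-1]  # descending
    if lam[-1] <= 1e-14 * lam[0]:
        raise np.linalg.LinAlgError(
            "composite covariance is singular; increase reg_eps to regularize"
        )
    p = (u / np.sqrt(lam)).T  # Λ^(-1/2) U'

    s1 = p @ r1 @ p.T
    s1 = (s1 + s1.T) / 2
    e1, b = np.linalg.eigh(s1)
    e1, b = e1[::-1], b[:, ::-1]  # descending

    w = b.T @ p
    # deterministic sign: largest-magnitude entry of each filter positive
    signs = np.sign(w[np.arange(c), np.abs(w).argmax(axis=1)])
    signs[signs == 0] = 1.0
    w = w * signs[:, None]

    m_half = n_components // 2
    selected = np.concatenate([np.arange(m_half), np.arange(c - m_half, c)])
    return CSPModel(
        W=w,
        selected_rows=selected,
        R1=r1,
        R2=r2,
        P=p,
        B=b,
        E1=e1,
        E2=1.0 - e1,
        n1=len(by_class[1]),
        n2=len(by_class[2]),
        n_features=n_feat,
    )


@dataclass
class SpatialFeatureVector:
    """Normalized log-variance CSP features for one recording."""

    f: np.ndarray
    recording_id: str


def apply_csp(model: CSPModel, m: TimeFreqFeatureMatrix) -> SpatialFeatureVector:
    """Project a feature matrix through the selected filters and return the
    2m normalized log-variance features (label-free; safe on held-out data)."""
    f = np.asarray(m.F, dtype=float)
    if f.ndim != 2 or f.shape[1] != model.n_features or f.shape[0] != model.W.shape[0]:
        raise ValidationError(
            "F", f"shape {f.shape} incompatible with fitted ({model.W.shape[0]}, {model.n_features})"
        )
    z = model.W_selected @ f
    var = z.var(axis=1)  # population variance per projected row
    total = var.sum()
    if total <= 0:
        raise ValidationError("F", "projected variance is zero")
    return SpatialFeatureVector(f=np.log(var / total), recording_id=m.recording_id)
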