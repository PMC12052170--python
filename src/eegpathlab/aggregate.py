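"""Multi-view aggregation across segments and multi-domain fusion.

Each (channel, band, statistic) trajectory across the L segments is
collapsed by three Hjorth-style aggregators — activity, mobility and
complexity — turning the C x L x 24 time-frequency features into three
C x 24 matrices.  These are fused with the CSP spatial features and the
patient's age into one vector of length ``3*C*24 + n_csp + 1``.

Two aggregator conventions are provided:

``"paper"`` (default)
    activity = arithmetic mean of the trajectory;
    mobility = var(first difference) / var(series);
    complexity = mobility(first difference) / mobility(series).
``"classical"``
    Hjorth's original definitions: activity = variance, and mobility takes
    the square root of the variance ratio (complexity composes accordingly).

Variances are population (1/n); any 0/0 degenerate case is defined as 0, so
aggregated features are always finite.  The first difference is unit-spaced
(segments are equispaced).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .spatial import SpatialFeatureVector
from .timefreq import N_BAND_STATS, RETAINED_BANDS, STAT_NAMES, TimeFreqFeatureMatrix

CONVENTIONS = ("paper", "classical")


def _check_series(series: np.ndarray, min_len: int, op: str) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or s.size < min_len:
        raise ValidationError("series", f"{op} needs a 1-D series of length >= {min_len}")
    return s


def _var(x: np.ndarray, axis=-1) -> np.ndarray:
    return np.asarray(x).var(axis=axis)


def hjorth_activity(series: np.ndarray, convention: str = "paper") -> float:
    """Activity aggregator: mean of the trajectory ("paper" convention) or
    its variance ("classical")."""
    s = _check_series(series, 1, "activity")
    return float(s.mean()) if convention == "paper" else float(_var(s))


def hjorth_mobility(series: np.ndarray, convention: str = "paper") -> float:
    """Mobility aggregator: var(diff)/var ("paper") or its square root
    ("classical"); 0 when the series is constant."""
    s = _check_series(series, 2, "mobility")
    v = _var(s)
    if v <= 0:
        return 0.0
    ratio = _var(np.diff(s)) / v
    return float(ratio) if convention == "paper" else float(np.sqrt(ratio))


def hjorth_complexity(series: np.ndarray, convention: str = "paper") -> float:
    """Complexity aggregator: mobility(diff)/mobility(series); 0 on any
    degenerate (zero-mobility) input."""
    s = _check_series(series, 3, "complexity")
    denom = hjorth_mobility(s, convention)
    if denom == 0.0:
        return 0.0
    return float(hjorth_mobility(np.diff(s), convention) / denom)


def _mobility_lastaxis(t: np.ndarray) -> np.ndarray:
    v = _var(t)
    vd = _var(np.diff(t, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(v > 0, vd / np.where(v > 0, v, 1.0), 0.0)


@dataclass
class AggregatedFeatures:
    """The three C x 24 segment-aggregated views of one recording."""

    activity: np.ndarray
    mobility: np.ndarray
    complexity: np.ndarray
    recording_id: str


def aggregate(m: TimeFreqFeatureMatrix, convention: str = "paper") -> AggregatedFeatures:
    """Collapse the segment axis of a C x (L*24) feature matrix with the
    three aggregators, yielding three C x 24 matrices."""
    if convention not in CONVENTIONS:
        raise ValidationError("convention", f"must be one of {CONVENTIONS}")
    f = np.asarray(m.F, dtype=float)
    c = f.shape[0]
    n_seg = m.n_segments
    if f.shape[1] != n_seg * N_BAND_STATS:
        raise ValidationError("F", "column count inconsistent with segment count")
    if n_seg < 3:
        raise ValidationError("F", "need at least 3 segments (complexity undefined)")
    # (C, L, 24) -> trajectories along the segment axis
    traj = f.reshape(c, n_seg, N_BAND_STATS).transpose(0, 2, 1)  # (C, 24, L)
    if convention == "paper":
        act = traj.mean(axis=-1)
        mob = _mobility_lastaxis(traj)
        mob_d = _mobility_lastaxis(np.diff(traj, axis=-1))
    else:
        act = _var(traj)
        mob = np.sqrt(_mobility_lastaxis(traj))
        mob_d = np.sqrt(_mobility_lastaxis(np.diff(traj, axis=-1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        cplx = np.where(mob > 0, mob_d / np.where(mob > 0, mob, 1.0), 0.0)
    return AggregatedFeatures(activity=act, mobility=mob, complexity=cplx, recording_id=m.recording_id)


@dataclass
class FusedFeatureVector:
    """Final per-recording feature vector with aligned names."""

    x: np.ndarray
    feature_names: list[str]
    recording_id: str
    label: str = "unknown"
    age_included: bool = True


def _agg_names(prefix: str, n_channels: int, channel_labels: list[str]) -> list[str]:
    chans = channel_labels if len(channel_labels) == n_channels else [str(i) for i in range(n_channels)]
    return [
        f"{prefix}_{ch}_{band}_{stat}"
        for ch in chans
        for band in RETAINED_BANDS
        for stat in STAT_NAMES
    ]


def fuse(
    agg: AggregatedFeatures | None,
    spatial: SpatialFeatureVector | None,
    age_years: float | None,
    raw: TimeFreqFeatureMatrix | None = None,
    aggregators: tuple[str, ...] = ("activity", "mobility", "complexity"),
    impute_age: float | None = None,
) -> FusedFeatureVector:
    """Concatenate [aggregated views | spatial | age] into one named vector.

    Ablation handles: ``aggregators`` selects which views enter;
    ``spatial=None`` drops the CSP block; ``agg=None`` with ``raw`` set
    fuses the un-aggregated (flattened C*L*24) features instead.  A missing
    age uses ``impute_age`` when given, otherwise raises.
    """
    parts: list[np.ndarray] = []
    names: list[str] = []
    rid = None
    if agg is not None:
        rid = agg.recording_id
        views = {"activity": agg.activity, "mobility": agg.mobility, "complexity": agg.complexity}
        for name in aggregators:
            if name not in views:
                raise ValidationError("aggregators", f"unknown aggregator {name!r}")
            mat = views[name]
            parts.append(mat.ravel())
            names.extend(_agg_names(name[:3], mat.shape[0], []))
    elif raw is not None:
        rid = raw.recording_id
        f = np.asarray(raw.F, dtype=float)
        parts.append(f.ravel())
        names.extend(f"tf_{i}" for i in range(f.size))
    else:
        raise ValidationError("agg", "need aggregated features or a raw feature matrix")
    if spatial is not None:
        if rid is not None and spatial.recording_id != rid:
            raise ValidationError("spatial", "recording_id mismatch between blocks")
        parts.append(np.asarray(spatial.f, dtype=float))
        names.extend(f"csp_{i}" for i in range(len(spatial.f)))
    if age_years is None:
        if impute_age is None:
            raise ValidationError("age_years", "age missing and imputation disabled")
        age_years = impute_age
    parts.append(np.array([float(age_years)]))
    names.append("age")
    return FusedFeatureVector(
        x=np.concatenate(parts), feature_names=names, recording_id=rid or "", age_included=True
    )


def fused_length(n_channels: int, n_csp: int = 8, n_aggregators: int = 3) -> int:
    """Closed-form fused-vector length: n_agg*C*24 + n_csp + 1."""
    return n_aggregators * n_channels * N_BAND_STATS + n_csp + 1
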