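"""Time-frequency statistical features from a dyadic wavelet decomposition.

Each 5-second segment is decomposed with a level-5 discrete wavelet
transform using the order-6 Symlet (an orthogonal 12-tap filter pair).  At a
250 Hz sampling rate the retained sub-bands map onto the classical EEG
rhythms:

=======  ==================  ===============
band     frequency range     rhythm
=======  ==================  ===============
D3       15.625 - 31.25 Hz   beta
D4       7.8125 - 15.625 Hz  alpha
D5       3.90625 - 7.8125    theta
A5       0 - 3.90625 Hz      delta
=======  ==================  ===============

D1 and D2 (high-frequency residue) are discarded.  Six statistics are taken
per retained coefficient vector — mean, mean absolute deviation, standard
deviation, mean absolute value, skewness and kurtosis — giving 24 values per
(channel, segment) and a C x (L*24) feature matrix per recording, which is
then z-scored feature-wise using training-set statistics only.

Moment conventions: population (1/n) moments throughout; skewness is the
third standardized moment; kurtosis is the Pearson (non-excess) fourth
standardized moment, so a Gaussian scores ~3.  A constant vector has
skewness and kurtosis 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import DecompositionError, ValidationError
from .recording import SegmentedRecording

WAVELET = "sym6"
LEVEL = 5
PAD_MODE = "symmetric"
RETAINED_BANDS: tuple[str, ...] = ("D3", "D4", "D5", "A5")
STAT_NAMES: tuple[str, ...] = ("mean", "mad", "std", "mav", "skew", "kurt")
N_BAND_STATS = len(RETAINED_BANDS) * len(STAT_NAMES)  # 24


def band_range(band: str, fs: float) -> tuple[float, float]:
    """Frequency range (Hz) covered by a dyadic DWT sub-band.

    ``Dj`` spans (fs/2^(j+1), fs/2^j); ``A5`` spans (0, fs/2^6).
    """
    if not fs > 0:
        raise ValidationError("fs", "sampling rate must be positive")
    if band == "A5":
        return 0.0, fs / 2**6
    if band.startswith("D") and band[1:].isdigit():
        j = int(band[1:])
        if 1 <= j <= 5:
            return fs / 2 ** (j + 1), fs / 2**j
    raise ValidationError("band", f"unknown sub-band {band!r}")


def dwt_decompose(
    x: np.ndarray,
    wavelet: str = WAVELET,
    level: int = LEVEL,
    mode: str = PAD_MODE,
) -> dict[str, np.ndarray]:
    """Level-``level`` DWT of a segment, keeping D3, D4, D5 and A5.

    Works on a single vector or batched along the last axis of a 2-D array.
    Raises :class:`DecompositionError` when the input is too short to
    support the requested depth without the boundary dominating.
    """
    x = np.asarray(x, dtype=float)
    wav = pywt.Wavelet(wavelet)
    n = x.shape[-1]
    if pywt.dwt_max_level(n, wav.dec_len) < level:
        raise DecompositionError(
            f"input of {n} samples too short for a level-{level} {wavelet} decomposition"
        )
    coeffs = pywt.wavedec(x, wav, mode=mode, level=level, axis=-1)
    # wavedec order: [A5, D5, D4, D3, D2, D1]
    a5, d5, d4, d3 = coeffs[0], coeffs[1], coeffs[2], coeffs[3]
    return {"D3": d3, "D4": d4, "D5": d5, "A5": a5}


def _stats_lastaxis(c: np.ndarray) -> np.ndarray:
    """Six population statistics along the last axis; output shape (..., 6)."""
    mean = c.mean(axis=-1)
    dev = c - mean[..., None]
    var = np.mean(dev**2, axis=-1)
    std = np.sqrt(var)
    mad = np.mean(np.abs(dev), axis=-1)
    mav = np.mean(np.abs(c), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(std > 0, np.mean(dev**3, axis=-1) / np.where(std > 0, std, 1) ** 3, 0.0)
        kurt = np.where(var > 0, np.mean(dev**4, axis=-1) / np.where(var > 0, var, 1) ** 2, 0.0)
    return np.stack([mean, mad, std, mav, skew, kurt], axis=-1)


def stat_features(c: np.ndarray) -> np.ndarray:
    """(mean, mean abs deviation, std, mean abs value, skewness, kurtosis)
    of one coefficient vector."""
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValidationError("c", "need a non-empty 1-D coefficient vector")
    return _stats_lastaxis(c)


@dataclass
class TimeFreqFeatureMatrix:
    """Per-recording C x (L*24) statistical feature matrix.

    Column layout is segment-major: for segment l, band q (D3, D4, D5, A5)
    and statistic s (mean, mad, std, mav, skew, kurt), the column index is
    ``(l * 4 + q) * 6 + s``.
    """

    recording_id: str
    F: np.ndarray
    n_segments: int
    channel_labels: list[str] = field(default_factory=list)
    label: str = "unknown"
    age_years: float | None = None

    @property
    def n_channels(self) -> int:
        return self.F.shape[0]

    @staticmethod
    def column_index(segment: int, band: int, stat: int) -> int:
        return (segment * len(RETAINED_BANDS) + band) * len(STAT_NAMES) + stat

    @staticmethod
    def column_descriptor(col: int) -> tuple[int, str, str]:
        """Inverse layout map: column -> (segment, band name, stat name)."""
        stat = col % len(STAT_NAMES)
        band = (col // len(STAT_NAMES)) % len(RETAINED_BANDS)
        seg = col // N_BAND_STATS
        return seg, RETAINED_BANDS[band], STAT_NAMES[stat]


def build_feature_matrix(
    seg: SegmentedRecording,
    wavelet: str = WAVELET,
    level: int = LEVEL,
    mode: str = PAD_MODE,
) -> TimeFreqFeatureMatrix:
    """Wavelet-decompose every (channel, segment) and assemble the feature
    matrix: C x (L*24) with the segment-major layout."""
    c, n_seg, s = seg.segments.shape
    flat = np.asarray(seg.segments, dtype=float).reshape(c * n_seg, s)
    bands = dwt_decompose(flat, wavelet=wavelet, level=level, mode=mode)
    blocks = [_stats_lastaxis(bands[b]) for b in RETAINED_BANDS]  # each (C*L, 6)
    stats = np.stack(blocks, axis=1)  # (C*L, 4, 6)
    f = stats.reshape(c, n_seg * N_BAND_STATS)
    return TimeFreqFeatureMatrix(
        recording_id=seg.recording_id,
        F=f,
        n_segments=n_seg,
        channel_labels=list(seg.channel_labels),
        label=seg.label,
        age_years=seg.age_years,
    )


@dataclass
class ZScoreModel:
    """Feature-wise standardization statistics learned from training data.

    One (mean, sd) pair per feature cell of the C x (L*24) matrix; applying
    the model to held-out data uses training statistics only.  Zero-variance
    features map to 0.
    """

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, F: np.ndarray) -> np.ndarray:
        if F.shape != self.mean.shape:
            raise ValidationError("F", f"shape {F.shape} != fitted shape {self.mean.shape}")
        out = F - self.mean
        nz = self.sd > 0
        out[nz] /= self.sd[nz]
        out[~nz] = 0.0
        return out


def zscore_fit(train: list[TimeFreqFeatureMatrix]) -> ZScoreModel:
    """Fit per-feature mean and (population) sd over the training matrices."""
    if len(train) < 2:
        raise ValidationError("train", "need at least 2 training matrices")
    stack = np.stack([np.asarray(m.F, dtype=float) for m in train])
    return ZScoreModel(mean=stack.mean(axis=0), sd=stack.std(axis=0))


def zscore_apply(model: ZScoreModel, m: TimeFreqFeatureMatrix) -> TimeFreqFeatureMatrix:
    """Standardize one feature matrix with training statistics."""
    return TimeFreqFeatureMatrix(
        recording_id=m.recording_id,
        F=model.transform(np.asarray(m.F, dtype=float)),
        n_segments=m.n_segments,
        channel_labels=list(m.channel_labels),
        label=m.label,
        age_years=m.age_years,
    )
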