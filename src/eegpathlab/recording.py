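"""Core recording containers and the canonical 10-20 montage.

An :class:`EEGRecording` holds a multi-channel scalp EEG signal in microvolts
together with its sampling rate, channel labels, the patient's age and the
normal/abnormal diagnosis.  A :class:`SegmentedRecording` is the same signal
cut channel-wise into contiguous, non-overlapping fixed-length windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

NORMAL = "normal"
ABNORMAL = "abnormal"
UNKNOWN = "unknown"
LABELS = (NORMAL, ABNORMAL)

#: Default 21-electrode 10-20 montage (19 scalp sites plus both ear
#: references), in canonical order.  Configurable everywhere it is used.
CANONICAL_MONTAGE: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "T3", "C3", "CZ", "C4", "T4",
    "T5", "P3", "PZ", "P4", "T6",
    "O1", "O2", "A1", "A2",
)

_LABEL_PREFIX = re.compile(r"^EEG[ _]+", re.IGNORECASE)
_LABEL_SUFFIX = re.compile(r"-(REF|LE)$", re.IGNORECASE)


def normalize_label(raw: str) -> str:
    """Normalize a clinical EDF channel label to its bare 10-20 site name.

    Uppercases, strips an ``"EEG "`` prefix and a ``"-REF"``/``"-LE"``
    reference suffix, e.g. ``"EEG FP1-REF" -> "FP1"``.
    """
    lab = raw.strip()
    lab = _LABEL_PREFIX.sub("", lab)
    lab = _LABEL_SUFFIX.sub("", lab.strip())
    return lab.strip().upper()


@dataclass
class EEGRecording:
    """A labeled multi-channel EEG recording.

    Attributes
    ----------
    recording_id : str
        Unique identifier.
    signal : ndarray, shape (C, T)
        Samples in microvolts, one row per channel.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, one per signal row.
    age_years : float or None
        Patient age in years; ``None`` when unknown.
    label : str
        ``"normal"``, ``"abnormal"`` or ``"unknown"``.
    """

    recording_id: str
    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    age_years: float | None = None
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValidationError("signal", "must be a 2-D (channels x samples) array")
        c, t = self.signal.shape
        if len(self.channel_labels) != c:
            raise ValidationError(
                "channel_labels",
                f"{len(self.channel_labels)} labels for {c} signal rows",
            )
        if len(set(self.channel_labels)) != c:
            raise ValidationError("channel_labels", "labels must be unique")
        if t < 1:
            raise ValidationError("signal", "needs at least one sample")
        if not self.fs > 0:
            raise ValidationError("fs", "sampling rate must be positive")
        if self.age_years is not None and self.age_years < 0:
            raise ValidationError("age_years", "age must be non-negative")
        if self.label not in LABELS + (UNKNOWN,):
            raise ValidationError("label", f"unknown class label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SegmentedRecording:
    """A recording windowed into L non-overlapping segments of S samples.

    ``segments`` has shape (C, L, S); segments are contiguous, in temporal
    order, and concatenating them reproduces the first ``L*S`` samples of the
    source signal exactly.
    """

    recording_id: str
    segments: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    age_years: float | None = None
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments)
        if self.segments.ndim != 3:
            raise ValidationError("segments", "must be a 3-D (C, L, S) array")

    @property
    def n_channels(self) -> int:
        return self.segments.shape[0]

    @property
    def n_segments(self) -> int:
        return self.segments.shape[1]

    @property
    def segment_samples(self) -> int:
        return self.segments.shape[2]
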