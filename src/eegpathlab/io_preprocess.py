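"""EDF input and the three-stage preprocessing front end.

Stages: (1) select the canonical 21-channel 10-20 montage, (2) downsample to
250 Hz with an anti-aliasing polyphase filter, (3) cut each channel into 100
non-overlapping 5-second windows taken from the start of the recording.
"""

from __future__ import annotations

import csv
import logging
import re
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .errors import (
    EDFParseError,
    InsufficientDurationError,
    UnsupportedInputError,
    UpsamplingRefusedError,
    ValidationError,
)
from .recording import (
    CANONICAL_MONTAGE,
    UNKNOWN,
    EEGRecording,
    SegmentedRecording,
    normalize_label,
)

logger = logging.getLogger(__name__)

TARGET_FS = 250.0
WINDOW_S = 5.0
MAX_SEGMENTS = 100

_AGE_RE = re.compile(r"Age[:=]\s*([0-9]+(?:\.[0-9]+)?)", re.IGNORECASE)


def _edf_header_meta(path: Path) -> tuple[float | None, list[int]]:
    """Pull the patient age and per-signal samples-per-record directly from
    the EDF header (fields the high-level reader does not surface)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFParseError(f"{path}: truncated EDF header")
        patient = head[8:88].decode("ascii", errors="replace")
        try:
            record_dur = float(head[244:252])
            n_sig = int(head[252:256])
        except ValueError as exc:
            raise EDFParseError(f"{path}: malformed EDF header") from exc
        sig_head = fh.read(256 * n_sig)
        if len(sig_head) < 256 * n_sig:
            raise EDFParseError(f"{path}: truncated EDF signal headers")
    m = _AGE_RE.search(patient)
    age = float(m.group(1)) if m else None
    off = 216 * n_sig  # samples-per-record block offset within signal headers
    labels_raw = [sig_head[16 * i : 16 * (i + 1)].decode("ascii", "replace") for i in range(n_sig)]
    spr = []
    for i in range(n_sig):
        if "annotation" in labels_raw[i].lower():
            continue
        try:
            spr.append(int(sig_head[off + 8 * i : off + 8 * (i + 1)]))
        except ValueError as exc:
            raise EDFParseError(f"{path}: malformed samples-per-record field") from exc
    if record_dur <= 0:
        raise EDFParseError(f"{path}: non-positive record duration")
    return age, spr


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts).

    Channel labels are normalized to bare 10-20 names; the patient age is
    parsed from an ``Age:<years>`` token in the header patient field when
    present.  The diagnosis label is not stored in EDF and is left
    ``"unknown"`` (see :func:`load_labels_csv`).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise EDFParseError(f"{path}: no such file")
    age, spr = _edf_header_meta(path)
    if len(set(spr)) > 1:
        raise UnsupportedInputError(
            f"{path}: heterogeneous sampling rates across signals ({sorted(set(spr))})"
        )
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except EDFParseError:
        raise
    except Exception as exc:
        raise EDFParseError(f"{path}: not readable as EDF ({exc})") from exc
    picks = [i for i, ch in enumerate(raw.ch_names) if "annotation" not in ch.lower()]
    labels = [normalize_label(raw.ch_names[i]) for i in picks]
    signal = raw.get_data(picks=picks) * 1e6  # mne returns volts for EEG
    return EEGRecording(
        recording_id=path.stem,
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        age_years=age,
        label=UNKNOWN,
    )


def load_labels_csv(path: str | Path) -> dict[str, tuple[str, float | None]]:
    """Read a sidecar labels table (recording_id, label, age_years)."""
    out: dict[str, tuple[str, float | None]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            age = row.get("age_years", "")
            out[row["recording_id"]] = (row["label"], float(age) if age else None)
    return out


def attach_labels(rec: EEGRecording, table: dict[str, tuple[str, float | None]]) -> EEGRecording:
    """Fill in diagnosis and age from a sidecar table, in place."""
    if rec.recording_id in table:
        label, age = table[rec.recording_id]
        rec.label = label
        if rec.age_years is None:
            rec.age_years = age
    return rec


def select_channels(
    rec: EEGRecording, montage: tuple[str, ...] | list[str] = CANONICAL_MONTAGE
) -> EEGRecording:
    """Keep exactly the montage channels, reordered to canonical order.

    Raises :class:`MissingChannelError` naming the first absent label.
    """
    from .errors import MissingChannelError

    normalized = [normalize_label(lab) for lab in rec.channel_labels]
    index = {}
    for i, lab in enumerate(normalized):
        index.setdefault(lab, i)
    order = []
    for lab in montage:
        key = normalize_label(lab)
        if key not in index:
            raise MissingChannelError(key)
        order.append(index[key])
    return EEGRecording(
        recording_id=rec.recording_id,
        signal=rec.signal[order],
        fs=rec.fs,
        channel_labels=[normalize_label(lab) for lab in montage],
        age_years=rec.age_years,
        label=rec.label,
    )


def resample_to(rec: EEGRecording, target_fs: float = TARGET_FS) -> EEGRecording:
    """Downsample to ``target_fs`` with a Kaiser-windowed polyphase filter.

    A recording already at the target rate is returned unchanged; a rate
    below the target raises :class:`UpsamplingRefusedError` (the pipeline
    never upsamples).
    """
    if rec.fs == target_fs:
        return rec
    if rec.fs < target_fs:
        raise UpsamplingRefusedError(
            f"{rec.recording_id}: fs {rec.fs} Hz below target {target_fs} Hz"
        )
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = resample_poly(
        np.asarray(rec.signal, dtype=float),
        frac.numerator,
        frac.denominator,
        axis=1,
        window=("kaiser", 5.0),
    )
    return EEGRecording(
        recording_id=rec.recording_id,
        signal=out,
        fs=target_fs,
        channel_labels=list(rec.channel_labels),
        age_years=rec.age_years,
        label=rec.label,
    )


def segment(
    rec: EEGRecording,
    window_s: float = WINDOW_S,
    max_segments: int = MAX_SEGMENTS,
    allow_short: bool = False,
) -> SegmentedRecording:
    """Cut the first ``max_segments`` non-overlapping windows of ``window_s``
    seconds from the start of each channel.

    With ``allow_short`` the available (fewer) windows are kept and a
    warning logged; otherwise a short recording raises
    :class:`InsufficientDurationError`.
    """
    s_float = window_s * rec.fs
    s = int(round(s_float))
    if abs(s - s_float) > 1e-9:
        raise ValidationError("window_s", f"window of {window_s}s x {rec.fs}Hz is not integer samples")
    n_avail = rec.n_samples // s
    if n_avail < max_segments:
        if not allow_short:
            raise InsufficientDurationError(
                f"{rec.recording_id}: only {n_avail} windows of {window_s}s available, "
                f"{max_segments} required"
            )
        logger.warning(
            "%s: keeping %d segments (%d requested)", rec.recording_id, n_avail, max_segments
        )
    n_keep = min(max_segments, n_avail)
    if n_keep < 1:
        raise InsufficientDurationError(f"{rec.recording_id}: shorter than one window")
    segs = np.asarray(rec.signal)[:, : n_keep * s].reshape(rec.n_channels, n_keep, s)
    return SegmentedRecording(
        recording_id=rec.recording_id,
        segments=segs,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        age_years=rec.age_years,
        label=rec.label,
    )


def preprocess(
    rec: EEGRecording,
    montage: tuple[str, ...] | None = CANONICAL_MONTAGE,
    target_fs: float = TARGET_FS,
    window_s: float = WINDOW_S,
    max_segments: int = MAX_SEGMENTS,
    allow_short: bool = False,
) -> SegmentedRecording:
    """Full front end: montage selection, downsampling, segmentation."""
    if montage is not None:
        rec = select_channels(rec, montage)
    rec = resample_to(rec, target_fs)
    return segment(rec, window_s=window_s, max_segments=max_segments, allow_short=allow_short)
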