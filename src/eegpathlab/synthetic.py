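"""Synthetic multi-channel EEG with controllable class structure.

The generator emulates the kind of clinical corpus the pipeline targets:
two diagnostic classes (normal / abnormal) that differ in their rhythm-band
power composition and in their channel-space covariance, with per-patient age
metadata.  Each recording is a sum of band-limited filtered-noise components
(one per classical EEG rhythm band), mixed through the matrix square root of
a per-class target channel covariance, plus additive white sensor noise.
Because every downstream feature is band-power or covariance driven, this is
the minimal signal model that exercises the whole pipeline.

Band conventions used by the generator (Hz): delta 0-4, theta 4-8,
alpha 8-13, beta 13-30, gamma 30-fs/2.  These are the generator's controls
only; the analysis pipeline works in dyadic wavelet sub-bands.

Fixtures can be written out as 16-bit EDF plus a sidecar labels table
(``labels.csv``: recording_id, label, age_years).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .recording import ABNORMAL, CANONICAL_MONTAGE, NORMAL, EEGRecording

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")
#: (low, high) band edges; ``None`` means DC or Nyquist.
BAND_EDGES: dict[str, tuple[float | None, float | None]] = {
    "delta": (None, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, None),
}

#: Typical scalp EEG amplitude scale, microvolts RMS of the unit-power model.
_AMPLITUDE_UV = 30.0


def default_band_profile(cls: str) -> dict[str, float]:
    """Per-class relative band-power profiles used as generator defaults.

    The normal profile is alpha-dominant, as in awake eyes-closed adult EEG.
    The abnormal profile quadruples the delta share (diffuse slowing, the
    most common correlate of encephalopathy) and rescales the remaining
    bands proportionally so the weights still sum to one.
    """
    normal = {"delta": 0.15, "theta": 0.20, "alpha": 0.35, "beta": 0.20, "gamma": 0.10}
    if cls == NORMAL:
        return dict(normal)
    delta = normal["delta"] * 4.0
    rest = 1.0 - delta
    scale = rest / (1.0 - normal["delta"])
    out = {b: w * scale for b, w in normal.items() if b != "delta"}
    out["delta"] = delta
    return out


def default_spatial_covariance(cls: str, n_channels: int) -> np.ndarray | str:
    """Default per-class channel covariance targets.

    Normal recordings use an identity covariance (spatially unstructured);
    abnormal recordings use an exponentially decaying neighbour-correlation
    structure, giving the two classes clearly distinct spatial signatures.
    """
    if cls == NORMAL:
        return "identity"
    idx = np.arange(n_channels)
    return 0.6 ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-class EEG dataset.

    ``separation`` scales the abnormal class's contrast with the normal
    class: 0 makes the two classes identically distributed (null model),
    1 applies the configured abnormal profile and covariance in full.
    Identical spec + seed always yields a bit-identical dataset.
    """

    n_channels: int = 21
    fs: float = 250.0
    duration_s: float = 600.0
    n_per_class: int = 10
    band_power_profile: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: default_band_profile(c) for c in (NORMAL, ABNORMAL)}
    )
    spatial_mixing: dict[str, np.ndarray | str] = field(default_factory=dict)
    separation: float = 1.0
    age_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {NORMAL: (45.0, 15.0), ABNORMAL: (55.0, 15.0)}
    )
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ValidationError("n_channels", "need at least 2 channels")
        if not self.fs > 0:
            raise ValidationError("fs", "sampling rate must be positive")
        if self.duration_s < 5:
            raise ValidationError("duration_s", "need at least 5 s of signal")
        if self.n_per_class < 1:
            raise ValidationError("n_per_class", "need at least 1 recording per class")
        if self.separation < 0:
            raise ValidationError("separation", "must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd", "must be >= 0")
        if self.n_channels > len(CANONICAL_MONTAGE):
            raise ValidationError(
                "n_channels",
                f"at most {len(CANONICAL_MONTAGE)} channels (canonical 10-20 labels)",
            )
        for cls in (NORMAL, ABNORMAL):
            prof = self.band_power_profile.get(cls)
            if not prof:
                raise ValidationError("band_power_profile", f"missing class {cls!r}")
            if any(b not in BAND_NAMES for b in prof):
                raise ValidationError("band_power_profile", f"unknown band in {cls} profile")
            if any(w < 0 for w in prof.values()) or sum(prof.values()) <= 0:
                raise ValidationError("band_power_profile", "weights must be >= 0, sum > 0")


def _target_covariance(spec: SyntheticSpec, cls: str) -> np.ndarray:
    raw = spec.spatial_mixing.get(cls, default_spatial_covariance(cls, spec.n_channels))
    if isinstance(raw, str):
        if raw != "identity":
            raise ValidationError("spatial_mixing", f"unknown descriptor {raw!r}")
        return np.eye(spec.n_channels)
    cov = np.asarray(raw, dtype=float)
    if cov.shape != (spec.n_channels, spec.n_channels):
        raise ValidationError("spatial_mixing", f"{cls} covariance must be C x C")
    if not np.allclose(cov, cov.T):
        raise ValidationError("spatial_mixing", f"{cls} covariance must be symmetric")
    return cov


def _effective_class_params(spec: SyntheticSpec, cls: str) -> tuple[dict[str, float], np.ndarray]:
    """Interpolate the abnormal class toward the normal one by ``separation``."""
    prof_n = {b: spec.band_power_profile[NORMAL].get(b, 0.0) for b in BAND_NAMES}
    cov_n = _target_covariance(spec, NORMAL)
    if cls == NORMAL:
        prof, cov = prof_n, cov_n
    else:
        prof_a = {b: spec.band_power_profile[ABNORMAL].get(b, 0.0) for b in BAND_NAMES}
        s = spec.separation
        prof = {b: max(prof_n[b] + s * (prof_a[b] - prof_n[b]), 0.0) for b in BAND_NAMES}
        cov = cov_n + s * (_target_covariance(spec, ABNORMAL) - cov_n)
    total = sum(prof.values())
    prof = {b: w / total for b, w in prof.items()}
    return prof, cov


def _sqrtm_psd(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 1e-9, None)
    return (v * np.sqrt(w)) @ v.T


def _band_sos(band: str, fs: float):
    # order-8 Butterworth: steep enough that a dominant band (e.g. 4x delta)
    # leaks <1.5% of its power into its neighbours
    lo, hi = BAND_EDGES[band]
    nyq = fs / 2.0
    if lo is None:
        return sps.butter(8, min(hi, nyq * 0.99) / nyq, btype="low", output="sos")
    if hi is None or hi >= nyq:
        return sps.butter(8, lo / nyq, btype="high", output="sos")
    return sps.butter(8, [lo / nyq, hi / nyq], btype="band", output="sos")


def _synthesize_class_signal(
    rng: np.random.Generator,
    profile: dict[str, float],
    mixing_sqrt: np.ndarray,
    n_channels: int,
    n_samples: int,
    fs: float,
    noise_sd: float,
) -> np.ndarray:
    x = np.zeros((n_channels, n_samples))
    for band in BAND_NAMES:
        w = profile.get(band, 0.0)
        if w <= 0:
            continue
        comp = sps.sosfiltfilt(_band_sos(band, fs), rng.standard_normal((n_channels, n_samples)), axis=1)
        # exact unit power per channel before weighting, so realized band
        # ratios track the requested profile
        comp /= comp.std(axis=1, keepdims=True)
        x += math.sqrt(w) * comp
    y = mixing_sqrt @ x
    if noise_sd > 0:
        y += noise_sd * rng.standard_normal(y.shape)
    return _AMPLITUDE_UV * y


def generate_dataset(spec: SyntheticSpec) -> list[EEGRecording]:
    """Generate ``2 * n_per_class`` labeled recordings per the spec.

    Returns normal recordings first, then abnormal, each with canonical
    10-20 channel labels and an age drawn from the class age distribution.
    Signals are float32 microvolts.
    """
    spec.validate()
    n_samples = int(round(spec.duration_s * spec.fs))
    labels = list(CANONICAL_MONTAGE[: spec.n_channels])
    root = np.random.SeedSequence(spec.seed)
    recs: list[EEGRecording] = []
    for cls in (NORMAL, ABNORMAL):
        profile, cov = _effective_class_params(spec, cls)
        mix = _sqrtm_psd(cov)
        mu, sd = spec.age_distribution[cls]
        for i in range(spec.n_per_class):
            rng = np.random.default_rng(root.spawn(1)[0])
            sig = _synthesize_class_signal(
                rng, profile, mix, spec.n_channels, n_samples, spec.fs, spec.noise_sd
            ).astype(np.float32)
            age = float(max(rng.normal(mu, sd), 0.0))
            recs.append(
                EEGRecording(
                    recording_id=f"{cls}-{i:03d}",
                    signal=sig,
                    fs=spec.fs,
                    channel_labels=list(labels),
                    age_years=age,
                    label=cls,
                )
            )
    return recs


def estimate_band_power_ratios(rec: EEGRecording) -> dict[str, float]:
    """Welch-PSD estimate of the recording's relative power per rhythm band.

    Averages the PSD over channels, integrates it over each generator band
    and normalizes to proportions.  Used to verify spectral control.
    """
    nper = int(min(rec.fs * 8, rec.n_samples))
    f, pxx = sps.welch(np.asarray(rec.signal, dtype=float), fs=rec.fs, nperseg=nper, axis=1)
    mean_psd = pxx.mean(axis=0)
    out = {}
    for band in BAND_NAMES:
        lo, hi = BAND_EDGES[band]
        lo = 0.0 if lo is None else lo
        hi = rec.fs / 2.0 if hi is None else hi
        mask = (f >= lo) & (f < hi)
        out[band] = float(np.trapezoid(mean_psd[mask], f[mask]))
    total = sum(out.values())
    return {b: p / total for b, p in out.items()}


# ---------------------------------------------------------------------------
# EDF fixture output
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write one recording as a 16-bit EDF file.

    Uses 1-second data records (the signal is truncated to whole seconds),
    per-channel physical ranges taken from the data, and clinical-style
    channel labels (``"EEG FP1-REF"``).  The patient field carries the age
    as an ``Age:<years>`` token.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValidationError("fs", "EDF fixture writer requires an integer sampling rate")
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValidationError("signal", "need at least 1 s of signal for EDF output")
    c = rec.n_channels
    data = np.asarray(rec.signal[:, : n_records * spr], dtype=float)

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    age = "X" if rec.age_years is None else f"Age:{rec.age_years:.2f}"
    patient = f"{rec.recording_id} X X X {age}"
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(patient, 80),
            _edf_field(f"Startdate 01-JAN-2000 {rec.recording_id}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + c)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(c), 4),
        ]
    )
    labels = [f"EEG {lab}-REF" for lab in rec.channel_labels]
    sig_header = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in labels),
            b"".join(_edf_field("", 80) for _ in range(c)),
            b"".join(_edf_field("uV", 8) for _ in range(c)),
            b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_min),
            b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_max),
            b"".join(_edf_field(str(_EDF_DIG_MIN), 8) for _ in range(c)),
            b"".join(_edf_field(str(_EDF_DIG_MAX), 8) for _ in range(c)),
            b"".join(_edf_field("", 80) for _ in range(c)),
            b"".join(_edf_field(str(spr), 8) for _ in range(c)),
            b"".join(_edf_field("", 32) for _ in range(c)),
        ]
    )
    # record-major, signal-contiguous sample layout
    records = digital.reshape(c, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(np.ascontiguousarray(records).tobytes())
    return path


def write_fixture_edf(recordings: list[EEGRecording], out_dir: str | Path) -> list[Path]:
    """Write EDF files plus a ``labels.csv`` sidecar; returns the EDF paths."""
    if not recordings:
        raise ValidationError("recordings", "must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    with open(out_dir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["recording_id", "label", "age_years"])
        for rec in recordings:
            paths.append(write_edf(rec, out_dir / f"{rec.recording_id}.edf"))
            age = "" if rec.age_years is None else f"{rec.age_years:.6f}"
            writer.writerow([rec.recording_id, rec.label, age])
    return paths


def null_spec(**overrides) -> SyntheticSpec:
    """A spec whose two classes are identically distributed (separation 0)."""
    spec = SyntheticSpec(separation=0.0, **overrides)
    spec.age_distribution = {NORMAL: (50.0, 15.0), ABNORMAL: (50.0, 15.0)}
    return spec


def separable_spec(**overrides) -> SyntheticSpec:
    """The separable study condition: abnormal delta power x4 and a distinct
    abnormal spatial covariance (full contrast unless overridden)."""
    overrides.setdefault("separation", 1.0)
    return replace(SyntheticSpec(), **overrides)
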