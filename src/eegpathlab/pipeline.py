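"""End-to-end orchestration: preprocess -> wavelet statistics -> z-score ->
CSP -> Hjorth aggregation -> fusion -> Kruskal-Wallis selection ->
gradient-boosted classification -> metrics.

Every stateful stage (z-score statistics, CSP filters, feature selection,
the classifier, age imputation) is fitted on the training split only and
applied unchanged to held-out data; train and test recording identifiers
must be disjoint.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import classify, io_preprocess, selection, spatial, timefreq
from .aggregate import aggregate as _aggregate
from .aggregate import fuse as _fuse
from .errors import LeakageError, ValidationError
from .recording import ABNORMAL, CANONICAL_MONTAGE, NORMAL, EEGRecording

logger = logging.getLogger(__name__)

ALL_AGGREGATORS = ("activity", "mobility", "complexity")

#: Named aggregation configurations for the ablation grid.  Case 1 skips
#: aggregation entirely (raw flattened time-frequency features); cases 2-4
#: add Hjorth views one at a time; "full" is the complete method.
ABLATION_CASES: dict[str, tuple[str, ...] | None] = {
    "case1_no_aggregation": None,
    "case2_activity": ("activity",),
    "case3_activity_mobility": ("activity", "mobility"),
    "case4_activity_complexity": ("activity", "complexity"),
    "full": ALL_AGGREGATORS,
}


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, defaulting to the reference settings."""

    montage: tuple[str, ...] = CANONICAL_MONTAGE
    fs_target: float = 250.0
    window_s: float = 5.0
    max_segments: int = 100
    allow_short: bool = False
    wavelet: str = "sym6"
    level: int = 5
    n_csp: int = 8
    csp_reg_eps: float = 1e-10
    aggregators: tuple[str, ...] = ALL_AGGREGATORS
    use_aggregation: bool = True
    use_spatial: bool = True
    hjorth_convention: str = "paper"
    alpha: float = 0.01
    selection_fallback_k: int | None = None
    classifier: classify.ClassifierConfig = field(default_factory=classify.ClassifierConfig)
    seed: int = 0

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["montage"] = list(self.montage)
        payload["aggregators"] = list(self.aggregators)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        import yaml

        payload = asdict(self)
        payload["montage"] = list(self.montage)
        payload["aggregators"] = list(self.aggregators)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        clf = classify.ClassifierConfig(**payload.pop("classifier", {}))
        payload["montage"] = tuple(payload.get("montage", CANONICAL_MONTAGE))
        payload["aggregators"] = tuple(payload.get("aggregators", ALL_AGGREGATORS))
        return cls(classifier=clf, **payload)


@dataclass
class PipelineResult:
    """Evaluation report plus the fitted artifacts of one pipeline run."""

    report: classify.MetricsReport
    n_features_fused: int
    n_features_selected: int
    config_hash: str
    zscore: timefreq.ZScoreModel
    csp: spatial.CSPModel | None
    selection: selection.KWSelection
    model: object
    timings_s: dict[str, float]

    def report_dict(self) -> dict:
        out = self.report.as_dict()
        out["n_features_selected"] = self.n_features_selected
        out["config_hash"] = self.config_hash
        return out


def extract_features(
    recs: list[EEGRecording], cfg: PipelineConfig
) -> list[timefreq.TimeFreqFeatureMatrix]:
    """Preprocess each recording and build its time-frequency feature matrix.

    Recordings already matching the montage/target rate pass through the
    corresponding stages unchanged.
    """
    out = []
    for rec in recs:
        seg = io_preprocess.preprocess(
            rec,
            montage=cfg.montage,
            target_fs=cfg.fs_target,
            window_s=cfg.window_s,
            max_segments=cfg.max_segments,
            allow_short=cfg.allow_short,
        )
        out.append(timefreq.build_feature_matrix(seg, wavelet=cfg.wavelet, level=cfg.level))
    if out:
        m = out[0]
        logger.info(
            "extracted %d x %d x %d = %d time-frequency scalars per recording",
            m.n_channels, m.n_segments, timefreq.N_BAND_STATS,
            m.n_channels * m.n_segments * timefreq.N_BAND_STATS,
        )
    return out


def _fuse_split(
    mats: list[timefreq.TimeFreqFeatureMatrix],
    csp_model: spatial.CSPModel | None,
    cfg: PipelineConfig,
    impute_age: float | None,
) -> tuple[np.ndarray, list[str], list[str]]:
    rows, names, labels = [], None, []
    for m in mats:
        sp = spatial.apply_csp(csp_model, m) if csp_model is not None else None
        if cfg.use_aggregation:
            fv = _fuse(
                _aggregate(m, convention=cfg.hjorth_convention),
                sp,
                m.age_years,
                aggregators=cfg.aggregators,
                impute_age=impute_age,
            )
        else:
            fv = _fuse(None, sp, m.age_years, raw=m, impute_age=impute_age)
        rows.append(fv.x)
        names = fv.feature_names
        labels.append(m.label)
    return np.vstack(rows), names, labels


def run_pipeline(
    train_recs: list[EEGRecording],
    test_recs: list[EEGRecording],
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Fit the full pipeline on the training recordings and evaluate on the
    held-out ones.  Raises :class:`LeakageError` on overlapping IDs."""
    cfg = cfg or PipelineConfig()
    if not train_recs or not test_recs:
        raise ValidationError("splits", "train and test splits must both be non-empty")
    overlap = {r.recording_id for r in train_recs} & {r.recording_id for r in test_recs}
    if overlap:
        raise LeakageError(f"recording IDs shared between train and test: {sorted(overlap)}")

    timings: dict[str, float] = {}

    def _timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0
                logger.info("stage %-12s %.2f s", name, timings[name])

        return _T()

    with _timed("features"):
        train_f = extract_features(train_recs, cfg)
        test_f = extract_features(test_recs, cfg)

    with _timed("zscore"):
        zmodel = timefreq.zscore_fit(train_f)
        train_z = [timefreq.zscore_apply(zmodel, m) for m in train_f]
        test_z = [timefreq.zscore_apply(zmodel, m) for m in test_f]

    csp_model = None
    if cfg.use_spatial:
        with _timed("csp"):
            labeled = [(m, 1 if m.label == NORMAL else 2) for m in train_z]
            if any(m.label not in (NORMAL, ABNORMAL) for m in train_z):
                raise ValidationError("train", "every training recording needs a class label")
            csp_model = spatial.fit_csp(labeled, n_components=cfg.n_csp, reg_eps=cfg.csp_reg_eps)

    with _timed("fuse"):
        ages = [m.age_years for m in train_z if m.age_years is not None]
        impute_age = float(np.median(ages)) if ages else None
        x_train, names, y_train = _fuse_split(train_z, csp_model, cfg, impute_age)
        x_test, _, y_test = _fuse_split(test_z, csp_model, cfg, impute_age)
        logger.info("fused feature vector length: %d", x_train.shape[1])

    with _timed("selection"):
        sel = selection.fit_selection(
            x_train, np.asarray(y_train), alpha=cfg.alpha,
            feature_names=names, fallback_k=cfg.selection_fallback_k,
        )
        logger.info("selected %d / %d features at alpha=%g", sel.n_selected, len(names), cfg.alpha)

    with _timed("classify"):
        clf_cfg = replace(cfg.classifier, seed=cfg.seed)
        model = classify.train(selection.apply_selection(sel, x_train), y_train, clf_cfg)
        y_pred = classify.predict(model, selection.apply_selection(sel, x_test))

    report = classify.evaluate(y_test, y_pred)
    return PipelineResult(
        report=report,
        n_features_fused=x_train.shape[1],
        n_features_selected=sel.n_selected,
        config_hash=cfg.config_hash(),
        zscore=zmodel,
        csp=csp_model,
        selection=sel,
        model=model,
        timings_s=timings,
    )


def split_recordings(
    recs: list[EEGRecording], test_fraction: float = 0.3, seed: int = 0
) -> tuple[list[EEGRecording], list[EEGRecording]]:
    """Stratified recording-level train/test split."""
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction", "must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in (NORMAL, ABNORMAL):
        members = [r for r in recs if r.label == cls]
        order = rng.permutation(len(members))
        n_test = max(1, int(round(test_fraction * len(members)))) if members else 0
        for pos, idx in enumerate(order):
            (test if pos < n_test else train).append(members[idx])
    return train, test


def run_ablation(
    train_recs: list[EEGRecording],
    test_recs: list[EEGRecording],
    cfg: PipelineConfig | None = None,
    cases: dict[str, tuple[str, ...] | None] | None = None,
    spatial_options: tuple[bool, ...] = (True, False),
) -> "pandas.DataFrame":  # noqa: F821
    """Run the aggregation-cases x spatial-on/off grid; one metrics row per
    configuration.  Wall-clock time is recorded but carries no guarantees."""
    import pandas as pd

    cfg = cfg or PipelineConfig()
    cases = cases if cases is not None else ABLATION_CASES
    rows = []
    for case_name, aggregators in cases.items():
        for use_spatial in spatial_options:
            sub = replace(
                cfg,
                use_aggregation=aggregators is not None,
                aggregators=aggregators or ALL_AGGREGATORS,
                use_spatial=use_spatial,
            )
            t0 = time.perf_counter()
            res = run_pipeline(train_recs, test_recs, sub)
            rows.append(
                {
                    "case": case_name,
                    "spatial": use_spatial,
                    "accuracy": res.report.accuracy,
                    "f1": res.report.f1,
                    "g_mean": res.report.g_mean,
                    "n_features_fused": res.n_features_fused,
                    "n_features_selected": res.n_features_selected,
                    "wall_s": time.perf_counter() - t0,
                }
            )
    return pd.DataFrame(rows)
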