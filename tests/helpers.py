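import numpy as np

import eegpathlab as epl


def make_segmented(n_channels, n_segments, n_samples=1250, seed=0, label="unknown", age=50.0):
    """Random segmented recording for feature-stage tests."""
    gen = np.random.default_rng(seed)
    return epl.SegmentedRecording(
        recording_id=f"synth-{seed}",
        segments=gen.standard_normal((n_channels, n_segments, n_samples)),
        fs=250.0,
        channel_labels=list(epl.CANONICAL_MONTAGE[:n_channels]),
        label=label,
        age_years=age,
    )


def random_feature_matrix(n_channels, n_cols, seed=0, label="unknown", cov=None, rid=None):
    """Feature matrix whose rows have a prescribed channel covariance."""
    gen = np.random.default_rng(seed)
    x = gen.standard_normal((n_channels, n_cols))
    if cov is not None:
        w, v = np.linalg.eigh(cov)
        x = (v * np.sqrt(np.clip(w, 0, None))) @ v.T @ x
    return epl.TimeFreqFeatureMatrix(
        recording_id=rid or f"fm-{seed}", F=x,
        n_segments=max(n_cols // 24, 1), label=label,
    )
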