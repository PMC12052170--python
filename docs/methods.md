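# Methods

## Pipeline model and assumptions

The pipeline treats pathology detection as a two-class problem over whole
recordings.  Its core assumption is that class information lives in (a) the
distribution of signal energy across classical rhythm bands, (b) the
spatial covariance structure across electrodes, and (c) slow demographic
covariates (age).  Every stage is a deterministic function of its inputs
given the configured seed.

Stages and their stateful artifacts:

| stage | artifact fitted on training split |
|---|---|
| z-score normalization | per-feature mean/sd over training recordings |
| CSP | class covariances, whitening, filters |
| Kruskal–Wallis screening | keep mask (p < α) |
| classifier | gradient-boosted ensemble |
| age imputation | training-set median |

Held-out data only ever passes through `transform`-style application of
these artifacts; `run_pipeline` refuses overlapping train/test recording
IDs outright.

## Preprocessing

* **Montage.** The 21-label 10–20 set (19 scalp sites + A1/A2 ear
  references): FP1 FP2 F7 F3 FZ F4 F8 T3 C3 CZ C4 T4 T5 P3 PZ P4 T6 O1 O2
  A1 A2.  Clinical EDF dialects are normalized by uppercasing and stripping
  the `EEG ` prefix and `-REF`/`-LE` suffixes.  The montage is a config
  field, not a constant.
* **Resampling** to 250 Hz uses `scipy.signal.resample_poly` with a Kaiser
  (β = 5) anti-aliasing window.  Upsampling is refused; recordings already
  at 250 Hz pass through untouched.
* **Windowing** takes the first 100 non-overlapping 5-s windows (1250
  samples at 250 Hz) from the start of the recording, no skip, no overlap.
  Shorter recordings error unless `allow_short` is set.

## Time–frequency features

Level-5 `sym6` DWT (PyWavelets), symmetric boundary padding (configurable).
Retained bands D3–D5, A5; D1/D2 (31.25–125 Hz residue) are discarded as
dominated by muscle/line noise.  Statistics use population (1/n) moments;
skewness is the third standardized moment and kurtosis the Pearson
(non-excess) fourth, so a Gaussian scores ≈ 3; constant vectors define
skewness = kurtosis = 0.  These conventions are deliberate, documented
choices — rank-based selection downstream is invariant to the biased-vs-
unbiased scaling anyway.

A note on energy checks: the DWT is orthogonal, but symmetric padding adds
redundant boundary coefficients, so exact Parseval equality holds only
under periodization padding; the test suite checks Parseval in that mode
and perfect reconstruction in the default mode.

Z-scoring is per feature *cell* (channel × column) across training
recordings; zero-variance cells map to 0.

## CSP on the feature space

CSP consumes the z-scored C × (L·24) matrices: the class covariance of
Eq-style `F Fᵀ/trace(F Fᵀ)` is C × C over all time–frequency columns,
which is the only shape under which trace normalization and the whitening
algebra are well-formed.  Numerical choices:

* whitening uses Λ^(−1/2)Uᵀ (required for W(R̄₁+R̄₂)Wᵀ = I, which the
  tests enforce to 1e-8);
* a ridge of `reg_eps`·trace is added to each unit-trace covariance
  (default 1e-10) against collinear feature columns;
* the eigenbasis is taken from the whitened class-1 covariance, eigenvalues
  sorted descending; m = n_csp/2 filters from each end;
* each filter's sign is fixed so its largest-magnitude entry is positive,
  making results reproducible across linear-algebra backends;
* Eq-style log-variance features use natural log and population variance.

## Aggregation and fusion

The `paper` convention (default) defines activity as the trajectory *mean*
and mobility as the plain variance ratio without square root; the
`classical` convention (activity = variance, mobility = √ratio) is a config
switch.  Both are exposed because the printed formulas diverge from
Hjorth's textbook definitions; the default follows the printed form rather
than silently "fixing" it.  First differences are unit-spaced.  All 0/0
degenerate cases are defined as 0, so fused vectors are always finite.
Missing age imputes the training median (configurable to a hard error).
Age is appended unscaled; tree ensembles are monotone-transform invariant.

## Feature selection

The Kruskal–Wallis H (mid-ranks, standard tie correction, χ² tail with
groups−1 df) is implemented in-repo as a named pipeline stage; only
`chi2.sf` comes from scipy.  Retention is strict `p < α`, α = 0.01, per
feature, with no multiple-testing correction by default (a
Benjamini–Hochberg switch exists).  A practical floor worth knowing: a
two-group rank test with g observations per group cannot reach p < 0.01
until g ≥ 6, so training splits need at least six recordings per class at
the default α.

## Classification

Learners are consumed behind a fit/predict registry with the reference
hyperparameters (1080 estimators; depth 4/6/4 and learning rate
0.03/0.02/0.04 for the catboost/xgboost/lightgbm entries).  The default
backend is **xgboost**: the sklearn and lightgbm histogram learners carry a
20-sample minimum-leaf default that collapses to the majority class on
small training sets, while xgboost degrades gracefully from tens to
thousands of samples and is deterministic per seed.  catboost is registered
but optional; a clear `ImportError` names the alternatives when it is
absent.  The positive class is *abnormal* throughout; metrics recomputed
from the emitted confusion matrix always reproduce the reported scalars.

## Synthetic data: what it does and does not emulate

Each recording is Σ_bands √w_b · n_b(t) mixed through Σ^{1/2} plus white
sensor noise, where n_b is unit-variance order-8 Butterworth-filtered
Gaussian noise in band b (delta 0–4, theta 4–8, alpha 8–13, beta 13–30,
gamma 30–fs/2 Hz) and Σ is the per-class target channel covariance.
Defaults: 21 channels, 250 Hz, 600 s, alpha-dominant normal profile
(0.15/0.20/0.35/0.20/0.10), abnormal = delta ×4 renormalized (diffuse
slowing), normal covariance identity vs abnormal 0.6^|i−j| neighbour
correlation, ages N(45,15²) vs N(55,15²) years clipped at 0, noise sd 0.05
of unit signal power.  `separation` linearly interpolates the abnormal
class toward the normal one (0 = identical classes, the null model).
Filter order 8 keeps cross-band leakage small enough that realized band
ratios track the requested profile within ~7% even when one band dominates.

The generator reproduces exactly the statistical structure the features
measure — stationary band power and spatial covariance.  It does **not**
emulate artifacts, eye blinks, sleep staging, nonstationarity, or
age–signal coupling (age is sampled independently so its feature
contribution can be isolated).  Passing end-to-end tests therefore
demonstrate that the implementation recovers the class structure it claims
to measure, not clinical-grade performance on real EEG.

## Problem sizes used in validation

End-to-end recovery runs 40 recordings per class, 21 channels, 500 s at
250 Hz (exactly 100 segments), with a 70/30 recording-level split — chosen
as the smallest configuration that exercises every stage at its reference
dimensionality (50 400 scalars, 1521 fused features).  The ablation
direction check (full method vs no-aggregation/no-spatial) runs five seeds
at a reduced operating point — 10 channels, 100 s (20 segments), 12 per
class, separation 0.3 — because at full separation every variant saturates
at 100% accuracy and no direction is measurable; at 0.3 the full method
averaged ~12–15 percentage points above the ablated variant across seeds.

## Known limitations

* EDF writing supports the subset needed for fixtures (16-bit, 1-s records,
  integer sampling rates, uniform rate across channels).
* Binary classes only; no multi-class CSP or ordinal severity.
* The χ² approximation of the Kruskal–Wallis p is used at all sample
  sizes; no exact small-sample tables.
* Cross-backend prediction equality is not promised — only per-backend
  determinism at fixed seed.
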