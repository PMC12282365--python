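# Methods

This note records what `egmst` computes, the parameter values it fixes, what
the synthetic study generator does and does not emulate, and the numerical
choices behind the implementation. It makes no empirical claims beyond what
the test suite and `scripts/acceptance.py` compute.

## Problem setting

Ventricular tachycardia (VT) after myocardial infarction is sustained by
critical sites — entry, isthmus, and exit regions of slow diastolic
conduction through scar. Substrate mapping records intracardiac electrograms
(EGMs) on the ventricular surface *without* inducing the arrhythmia, in sinus
rhythm (SR) or under right-/left-/bi-ventricular pacing (RV/LV/BIV). The task
is to classify each mapping point as a *potential ablation target*: a point
within a fixed distance (default 6 mm) of a VT critical site.

## Signal model and feature inventory

Each mapping point carries two channels: a unipolar EGM (electrode against a
distant reference; contains far-field and repolarization information) and a
bipolar EGM (difference of adjacent poles; local, high-pass in character).
Unipolar signals are band-passed 0.5–20 Hz, bipolar 0.5–40 Hz (4th-order
Butterworth, zero-phase forward–backward). Each trace is analyzed in two
windows: the QRS (ventricular activation) window and the post-QRS window
(T-wave window for unipolar, trace remainder for bipolar).

The registry defines **46 features**:

- **Functional (19)** — local activation time (LAT, latest deflection above
  20 % of QRS peak-to-peak on the bipolar channel); repolarization time (RT,
  maximum upslope of the unipolar T-wave, the Wyatt method); activation
  recovery interval (ARI = RT − LAT); EGM durations (20 % threshold on the
  rectified, 10-ms-smoothed signal); peak-to-peak amplitudes per
  channel/window; deflection counts (negative peaks with prominence above
  20 % of window amplitude); and max/mean |dV/dt| per channel/window.
- **Spatial (3)** — gradients of activation time, repolarization time, and
  ARI: per point, the mean of |Δvalue|/distance over all neighbours within a
  10-mm closed ball, computed from the pipeline's own annotations.
- **Spectral (4)** — central (PSD-weighted mean) frequency and spectral peak
  count per channel, from a Hann periodogram.
- **Time–frequency (20)** — a Smoothed Pseudo Wigner-Ville distribution
  (SPWVD) per channel; per window the total energy and the energy fractions
  in four contiguous bands tiling the channel's range (bipolar: 0–160 Hz in
  40-Hz bands; unipolar: 0–80 Hz in 20-Hz bands) — the 2 × 4 = 8 region
  tiling per channel.

Channel attribution: 20 features are bipolar-only, 24 unipolar-only, and 2
(LAT and the activation-time gradient) are general, giving the 22-feature
bipolar model and 26-feature unipolar model (22 + 26 − 2 = 46).

### SPWVD implementation

The distribution is computed from the analytic signal (Hilbert transform,
which suppresses cross-terms between positive and negative frequencies) as
the FFT over lags of the time-smoothed instantaneous autocorrelation
r(t, m) = z(t+m)·z*(t−m). Its three parameters (0.03, 0.15, 0.25) are read
as: time-smoothing window length and lag window length as fractions of the
signal length, and the Gaussian width of both windows as a fraction of their
length. The distribution is renormalized so that its integral equals the
signal energy Σx²/fs exactly; band energies are non-negativity-clipped per
band before fractions are formed (the SPWVD has small negative side-lobes).
For speed the signal is FIR-decimated to ≈ 3.2× the channel's top analysis
frequency before the transform (never below 64 samples), and the time axis is
evaluated at ~128 columns. Acceptance of the transform rests on energy
conservation (≤ 2 %) and single-tone localization (≤ 1 bin), not on
kernel-exact values.

## Labeling and leakage control

A point is positive when its 3-D distance to the nearest VT critical site is
≤ radius (closed ball, default 6 mm; sensitivity sweep 3–10 mm, under which
the positive sets are nested and prevalence is non-decreasing). Every
positive point is grouped by its nearest critical site; these **VT-site
groups are never split** across the train/test split or across
cross-validation folds. Negatives are grouped by map and split at row level.
Duplicated points (same coordinates within 0.01 mm *and* byte-identical
traces) are collapsed before labeling.

## Association analysis

Features are normalized on training rows only: features with |skewness| > 2
get `log1p` after a shift to positive support, then all are z-scored with
training statistics. Each feature is screened with a univariable
random-intercept (per-map) logistic regression; the marginal likelihood is
integrated with 15-node *adaptive* Gauss–Hermite quadrature (nodes re-centred
at each map's posterior mode and scaled by its Laplace curvature, as in
`glmer`'s nAGQ scheme — a fixed node grid under-resolves the sharply peaked
per-map integrand) and maximized by L-BFGS-B with finite-difference
gradients; Wald standard errors come from the numerical Hessian at the
optimum. Significance uses the Bonferroni threshold
0.05/46 ≈ 0.0011. Significant features are pruned by iteratively dropping
the worst variance inflation factor until all VIF ≤ 10, then jointly fitted
in a multivariable random-intercept model with map-type indicator covariates
(fixed effects, not reported). The estimator is cross-checked in the test
suite against a pooled GLM at zero random-effect variance and against R's
`lme4::glmer` (nAGQ = 15).

## Classification protocol

- **Split:** 80/20; positive VT-site groups kept whole, negatives row-level.
- **Cross-validation:** 10-fold, repeated 10 times; positives assigned to
  folds by group, negatives re-randomized per repeat.
- **Class imbalance:** optional stratified-by-map undersampling of negatives
  to 1:1 or 1:5 (all positives kept; exact counts).
- **Algorithms:** random forest (100 trees, min leaf 1), SVM (RBF, C = 1;
  decision-function scores for ROC), k-NN (k = 10, Euclidean), and logistic
  regression, all from scikit-learn; the protocol around them is bespoke.
- **Operating point:** ROC threshold closest to the (0, 1) corner on each
  validation fold; the CV iteration with the highest AUC supplies the model
  and threshold applied once to the held-out test rows. Metrics: AUC,
  F1 (%), PPV (%), sensitivity (%), specificity (%); CIs are percentile
  bootstraps (1000 resamples) over CV iterations.
- **Feature selection:** permutation importance of an RF on a stratified
  held-out quarter of the training rows (an explicit holdout rather than
  out-of-bag scoring), sequential
  addition from most to least important, default top-20 selection. A PCA
  baseline retains the smallest component set explaining ≥ 90 % variance
  (loadings from training rows only).
- **Model suite:** 10 configurations — both channels × {all, SR, LV, RV
  maps} plus unipolar-only × {SR, LV, RV} and bipolar-only × {SR, LV, RV};
  BIV maps are never modelled alone. "All maps" configurations add the four
  map-type indicator columns.
- **Benchmarks:** single-feature ROC/AUC of the activation-gradient,
  ARI-gradient, and voltage (bipolar QRS amplitude), oriented so AUC ≥ 0.5.

## Synthetic study generator

The generator emulates the *statistical structure* the analysis relies on,
not cardiac biophysics. Its defaults define the simulated study conditions;
they were fixed before the statistical tests were written and are not tuned
to test outcomes (the one spec-prescribed calibration is the 6-mm labelled
prevalence, targeted at 7.31 % with a ±30 % guard band, achieved by sizing
the shell axes).

Per subject (6 by default): an ellipsoidal shell (semi-axes 18, 18, 25 mm)
carrying one SR map at double point density plus RV/LV/BIV paced maps (120
points each); a spherical-cap scar covering 25 % of the surface; 3 VTs × 2
critical sites placed along short channels through the scar. Ground-truth
fields: LAT from origin distance at 0.7 mm/ms plus 1.2 ms/mm of scar depth;
ARI as a smooth large-scale field plus a 15-ms scar offset and a 40-ms
Gaussian bump (3.5-mm scale) at critical sites; RT = LAT + ARI exactly.
Unipolar EGMs are a derivative-of-Gaussian QRS at LAT plus a Gaussian T-wave
whose maximum upslope falls exactly at RT; bipolar EGMs are the difference of
two 3-mm-offset unipolar sources (the far-field T-wave cancels). Site-
proximal distortions follow the known substrate signatures with a Gaussian
spatial weight (5-mm scale): QRS amplitude reduced to 50 %, T-wave flattened
by 55 %, extra narrow QRS deflections (fractionation), and post-QRS 45–100 Hz
low-amplitude bursts (late potentials) whose log-odds rise by 3.0 at a site
and carry a per-map N(0, 0.5²) random intercept — the ground-truth random
effect the mixed model recovers. White noise (0.02 mV) is added to both
channels. Each subject lives in its own coordinate frame (500-mm offsets) so
labeling never crosses subjects. All randomness flows from one seeded
generator; a fixed seed reproduces the study bit-for-bit.

**Not emulated:** wavefront physics, anisotropic conduction, electrode
geometry effects, far-field QRS morphology diversity, atrial activity,
mapping-system annotation error models.

## Numerical choices

- Filters: `scipy.signal.sosfiltfilt` with even-extension padding.
- Spatial gradients: `cKDTree.query_pairs` closed-ball neighbour search with
  symmetric pair accumulation; an all-pairs brute-force twin is kept as a
  test oracle and the two agree exactly (≤ 1e-12) on ≤ 200-point clouds.
- Mixed logistic: hand-written adaptive Gauss–Hermite marginal likelihood
  (statsmodels has no random-intercept GLM); the per-map posterior mode is
  found by a Newton iteration vectorized over maps; optimized in (β, log σ)
  with log σ bounded in [−8, 5]; a non-converged fit is retried once with a
  σ² ridge and flagged, never raised.
- VIF: least-squares R² per feature; perfect collinearity reports ∞.
- Missing features: training-fold median imputation.
- Seeds: a root seed is fanned out per stage via `numpy.random.SeedSequence`
  (children reduced mod 2³¹).

## Limitations

- Results on synthetic studies say nothing quantitative about animal or
  human data; the generator is built so the pipeline's qualitative claims
  (discriminability, signal-type ordering, prevalence sensitivity) are
  testable, and its separability is stronger than real mapping data.
- LAT/RT detectors are deliberately simple (threshold/extremum rules on
  filtered signals) and are validated on clean synthetic morphologies only.
- The SPWVD kernel interpretation of (0.03, 0.15, 0.25) is one reasonable
  reading; energy-based acceptance bounds, not kernel equality, are the
  contract.
- Bootstrap CIs over CV iterations understate variance because iterations
  share training rows; the permutation-null check therefore aggregates over
  independent within-map label shuffles.
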