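# Methods

This note documents the models, default parameters, numerical policies
and design choices behind `hbnet`, and what the synthetic validation
does and does not demonstrate about real recordings.

## Pipeline model

The package assumes concurrent, trial-structured EEG and fNIRS from an
emotion-evoked paradigm: minute-scale audiovisual stimuli whose
intensity fluctuates continuously, so the haemodynamic response cannot
be modelled by boxcar regressors. The chain is

1. **Preprocessing.** EEG: optional common-average re-reference,
   zero-phase 4th-order Butterworth band-pass 0.5–45 Hz, polyphase
   resampling to the common 200 Hz grid. fNIRS: baseline correction,
   band-pass 0.01–0.2 Hz at the native rate (11 Hz by default),
   modified Beer–Lambert conversion of optical density to ΔHbO when
   needed (defaults: 760/850 nm, DPF 6.0, 3 cm separation, tabulated
   extinction coefficients; all overridable), then upsampling to
   200 Hz. Filters are zero-phase because phase distortion would bias
   the lagged regressions of the causal stage; upsampling is
   band-limited (polyphase), not sample-and-hold, to avoid spurious
   high-frequency content in the GLM target. ICA artifact removal is
   deliberately out of scope — the pipeline expects cleaned EEG.
2. **Source localisation.** Minimum norm estimate with identity source
   prior, solved through a Cholesky factorisation of the u×u
   regularised Gram matrix (never an explicit inverse). The
   regularisation weight α defaults to a data-scale value,
   α⁻¹ = trace(LLᵀ)/(u·SNR²) with an assumed amplitude SNR of 3, and is
   config-overridable. Lead fields and dipole→region memberships are
   inputs; the package does not do head modelling. Any atlas size is
   accepted; region order in the lead-field file fixes all downstream
   row/column orders.
3. **Causal networks.** Windows of 3 s sliding by 1.5 s, linearly
   detrended (short-window trends are the dominant stationarity
   violation). One lag order per window, selected by BIC over pooled
   bivariate VAR fits on the common sample (candidates 1..p_max,
   default p_max 10, ties to the smaller order; `granger.fixed_p`
   skips selection). The causality of i onto j is the log ratio of
   restricted to full residual sums of squares on the same r−p target
   points — nonnegative by nesting, with tiny negative rounding
   clipped to zero. The diagonal is zero by convention: self-causality
   is undefined under the nested contrast. Edges are *not*
   significance-thresholded; raw F values are the features. The
   all-pairs matrix is computed from one per-window lag Gram matrix
   with batched small solves, numerically identical (≤1e-10) to the
   explicit per-pair OLS path, which stays in the code as the readable
   reference and test oracle.
4. **Coupling networks.** Per source: squared-magnitude STFT (1 s Hann
   window, 0.1 s hop — resolves the 0.5–45 Hz band while tracking
   second-scale power fluctuations), band sum over 0.5–45 Hz, min–max
   normalisation to [0,1] *per trial* (normalisation precedes
   segmentation; a numerically constant envelope maps to zeros, never
   0/0), linear interpolation of frame-centred values onto the 200 Hz
   grid, and convolution with the canonical double-gamma HRF (32 s
   support, dt-scaled so predictions are sampling-rate invariant,
   truncated to the first n samples). The c predicted series form the
   design matrix of one least-squares GLM per 3 s window against the
   measured HbO channels; the coupling matrix is |β|. No intercept or
   drift columns are added: the measured stream is already band-passed
   and baseline-corrected upstream.
5. **Fusion and evaluation.** Hybrid networks concatenate the causal
   and coupling matrices column-wise (c×(c+d)); row-major
   vectorisation gives the feature vector. Evaluation is stratified
   k-fold CV (k = 5) repeated with reseeded fold assignments (default
   5 repetitions), linear SVM with C = 1 and KNN with k = 10, features
   z-scored with training-fold statistics only, accuracies summarised
   as mean ± sd over all folds, confusion matrices row-normalised.
   Fold assignment defaults to the window-sample level to replicate
   the reference protocol; a trial-level option exists because 1.5 s
   window overlap leaks information between sample-level folds, and
   sample-level accuracies should be read as optimistic in that sense.

## Numerical policy of the window GLM

Windowed HRF-convolved regressors are structurally ill-conditioned:
every design column is band-limited below ≈0.3 Hz, so over a 3 s window
the columns span an effective subspace of dimension 2–4 regardless of
c, with singular-value ratios around {1, 3e-2, 6e-3, 1e-3, …}. The
plain least-squares solution therefore amplifies noise or any
design/measurement mismatch by up to the condition number (~1e6).
`glm_fit` offers two stabilisations, both exact no-ops when the model
fits the data perfectly and the design is well conditioned:

* a **residual-significance cutoff** (`kappa`, default 3 in
  `trial_coupling`): SVD coordinates whose data projection is below
  κ·s, with s the full fit's residual standard deviation, are zeroed;
* a **relative singular-value floor** (`sv_rel`): coordinates with
  σ_k < sv_rel·σ₁ are treated as null space.

The library-level default (`sv_rel = 0`) recovers the exact
least-squares/minimum-norm solution, which is what the forward-model
recovery experiments use. The *feature-extraction pipeline* sets
`coupling.glm_sv_rel = 0.1`, keeping only the stable subspace
(typically one coordinate per window): coefficients along weaker
directions cannot be estimated from band-limited physiological data at
any realistic noise level, and carrying them into the feature matrix
buries the class signal under amplified noise. The two settings serve
different goals — unbiased coefficient recovery versus reproducible
features — and both are config-exposed.

A corollary, measured in the recovery experiment the acceptance script
reruns: per-window coupling coefficients are *not* identifiable under
broadband measurement noise. With fNIRS simulated from known weights W,
the correlation between window-averaged |β| and |W| is essentially 1.0
in the noiseless case but collapses for 10 dB (indeed any realistic)
broadband SNR, because the information about W along the weak singular
directions of a 3 s window is negligible. Fitting the same GLM over the
whole trial instead recovers W with correlation ≈0.6 at 10 dB and ≈0.9
at 20 dB. Per-window |β| should be treated as features of the
stimulus–response geometry, not as estimates of physiological coupling
gains.

## The synthetic generator

The simulator emulates the structure every stage assumes, with
deterministic output given the seed:

* **Sources:** a stable VAR(2) over c = 8 regions (companion spectral
  radius checked < 1 before any trial is emitted; 500-sample burn-in
  discarded), innovation sd 1, self-gain 0.4, six directed cross-edges
  of gain ≈0.35. A single adjacency is spread over lags with
  geometrically decaying weights summing to one; explicit per-lag
  matrices are also accepted.
* **Stimulus-intensity modulation:** each source is amplitude-modulated
  by a slow (0.04–0.25 Hz) unit-peak profile at depth 0.6 — the
  coupling model is only meaningful if band power varies in time.
  80% of the profile is shared by all trials of a class
  (same-emotion stimuli share temporal structure) and 20% is
  trial-specific; this class-shared fraction is what makes the
  coupling features discriminative at levels comparable, relative to
  the causal features, with published multimodal studies.
* **EEG:** each of v = 16 dipoles carries its region's series (2 per
  region), projected through a random unit-column 16×16 lead field,
  plus white sensor noise of sd 0.5.
* **fNIRS:** d = 4 channels mix the HRF-convolved normalised source
  envelopes through nonnegative weights (uniform 0.3–1.0, ~60%
  density), evaluated on the 200 Hz source grid — exactly the
  analysis-side forward model — then sampled at 11 Hz (the mixed
  signal is band-limited far below that rate) with white noise at
  10 dB broadband SNR.
* **Classes:** four, 15 trials each, 30 s per trial; class templates
  perturb both the VAR cross-gains and the coupling weights
  multiplicatively by (1 + 0.5·z), rectified to stay nonnegative and
  re-stabilised; effect size 0 yields an exact null dataset.

What passing the end-to-end tests shows: the implementation chain is
consistent (forward model ↔ inverse analysis), the causal statistic is
calibrated and recovers planted edges, and hybrid features beat either
unimodal network when both carry class signal. What it does not show:
robustness to head-model mismatch, physiological artifacts (cardiac,
Mayer waves, motion), nonlinear or subject-specific haemodynamics, or
cross-subject generalisation — none of which the generator emulates.

## Problem sizes and runtimes

The default study (60 trials × 19 windows × 8 regions) runs the full
pipeline in under a minute on one CPU; the all-pairs causal stage uses
the batched Gram path (one 590×80 Gram product per window instead of
112 independent OLS fits). The hybrid-ordering validation repeats the
full pipeline over five seeds with two CV repetitions per run; the
remaining validations (null calibration with 500 replicates, 30-window
edge recovery, forward-model recovery) each run in seconds.

## Known limitations

* Bivariate (not conditional) Granger causality: common-driver and
  chain confounds can produce indirect edges; this mirrors the
  construction the feature set is defined by.
* Sample-level CV folds leak overlapping-window information; use
  `evaluate.fold_unit: trial` for leakage-free estimates.
* The EDF writer quantises to 16 bits over integer physical ranges;
  it is meant for interchange, not archival fidelity. SNIRF support
  covers the minimal structure (time series, time vector, measurement
  lists, wavelengths), not probe geometry.
* MAT trial files require a variable-name mapping when the defaults
  (`data`, `fs`, `channel_names`) do not match.
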