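# Methods

## Signal model

The pipeline assumes that facial skin reflectance carries a pulse-frequency
Red-channel modulation that is far below visual threshold (≤ one 8-bit
intensity step) and that its *temporal statistics* — not its amplitude
alone — differ between people with diabetic neuropathy (DM) and healthy
controls (C). Controls are modelled as operating near self-organized
criticality: microvascular color fluctuations arrive in avalanche-like
bursts with scale-free amplitudes, so the largest eigenvalues of windowed
covariance matrices of the magnified signal have a polynomial right tail.
In the DM group the modulation is larger in amplitude (chronic erythema)
but temporally unstructured, so the windowed largest eigenvalues
concentrate and their tail is finite, approaching the Tracy–Widom edge
statistics of a noise covariance matrix.

## Eulerian magnification

* Full Laplacian pyramid per frame; depth "auto" = ⌊log₂(min(H, W))⌋ − 2,
  the deepest pyramid whose residual is still a few pixels wide.
  The decomposition is exactly invertible (band = level − expand(reduce(level))),
  so reconstruction error is float rounding only; the expand step uses
  bilinear interpolation, chosen after cubic splines proved ~3× slower with
  no effect on any measured quantity.
* Temporal filter: difference of two Butterworth low-pass filters at 4.0
  and 0.4 Hz, each applied forward–backward (zero phase). Order 4 per
  filter: the band-center gain is then within 0.1% of unity while 10 Hz is
  attenuated ~30 dB, so α = 50 amplifies out-of-band content by less than
  10%. (An order-1 pair leaks: gain 0.80 at 1 Hz and a 6× amplification of
  10–12 Hz at α = 50.)
* Amplification is uniform across pyramid levels and pixels; channels are
  processed independently in float [0, 1]; clipping happens only at export.
  A gray-world color-constancy gain can be applied before magnification.
* Frame stacks persist as 16-bit TIFF directories: 8-bit storage would
  quantize away the sub-visible modulation.

## Tensor profile and spectra

* The highest- and lowest-intensity patches are chosen once per segment by
  time-averaged mean, avoiding frame-to-frame identity switching; the
  pixelwise difference matrix (961×T) is z-scored per row. Zero-variance
  rows are flagged degenerate and imputed to zeros. The patch-mean
  difference scalar series is also exposed.
* One segment yields one λ_max sample by sliding a window over the profile
  and recording the top covariance eigenvalue per window (power iteration
  on the implicit covariance operator, tolerance 1e−10, ≤ 10⁴ iterations,
  fixed-seed start vector; verified against a dense eigensolver to 1e−8
  relative). Defaults: window 250 frames (5 s at 50 fps), stride 50 (1 s),
  sized for full-length ~2-minute segments.
* **Window length is the key sensitivity knob.** The control group's heavy
  tail lives at the pulse-beat scale: a window spanning many beats averages
  the burst envelope and hides the tail. At the 1.32 Hz default pulse
  (≈ 38 frames/beat) the 5-s default window covers ~6.6 beats; for the
  desk-scale test segments (2,500 frames) the tests use window 70
  (~2 beats), stride 8, and a 0.5 exceedance threshold, which recovers the
  rendering group's tail type in ≥ 90% of segments.
* The ESD is a Freedman–Diaconis-normalized histogram; Tracy–Widom
  normalization ξ = √2·N^{1/6}(λ_max − √(2N)) is applied on request.

## Tail fitting

* GP(k, σ) is fitted by maximum likelihood to exceedances over an empirical
  quantile threshold (default 0.9 in `tails`, the conventional
  peaks-over-threshold choice). The pipeline-level default is 0.7: with the
  window counts a 2-minute segment yields, the larger exceedance set makes
  sgn(k) substantially more stable (measured sign-accuracy 0.97/0.99 for
  C/DM feature samples at n = 1500 vs 0.93/0.98 at the 0.9 threshold).
* The verdict is sgn(k): k ≥ 0 → polynomial tail (SOC, control-like);
  k < 0 → finite tail (Tracy–Widom-like, DM-like). k = 0 is assigned to
  the polynomial class by convention.
* Γ(β, θ) uses the rate parametrization and is fitted only when k < 0; the
  exact Tracy–Widom CDF (Airy/Painlevé) is intentionally not implemented —
  the Gamma surrogate is the operational model throughout.
* The power-law exponent uses the Hill MLE on the magnitude,
  1 + N[Σ ln(x_i/x_min)]^{−1}, reported with a negative sign. (The
  reciprocal form is the standard estimator; the sum-only variant is
  dimensionally inconsistent with a decay exponent > 1.) With
  `x_min="auto"` the cutoff minimizes the KS distance between fitted and
  empirical tail over the observed values, scanning at most 100 candidates.

## Classification

* Features per segment: (k, σ) of the GP tail fit; the class labels are
  C = 0, DM = 1. A 12-feature subject-level mode is not provided; fusion
  happens at the vote level.
* COWE: out-of-fold class-1 probabilities of each base learner are
  collected by stratified 5-fold cross-validation; simplex weights minimize
  the cross-validated MSE via projected gradient with multistart (uniform,
  vertices, random Dirichlet starts; ties resolve toward uniform, so two
  identical learners share weight equally). An exhaustive 0.01-resolution
  grid solver is available for ≤ 3 learners. The optimal weighted MSE never
  exceeds the best single learner's (vertex feasibility).
* Reference base learners: gradient-boosted shallow trees (10 learners,
  learning rate 0.469, ≤ 38 splits per tree), a random-undersampling
  SAMME boosting variant (≤ 39 splits) for the 2:1 class imbalance, LDA,
  and 5-NN. A 52-learner / 0.107-learning-rate boosted-trees alternative is
  exposed as the "alt52" configuration. Hyperparameters are pinned rather
  than re-optimized so runs are reproducible.
* Decision rule: weighted score ≥ 0.5 → DM (the boundary is assigned to DM
  explicitly). Subject fusion: with six segments the winner needs ≥ 4
  votes; with fewer, a strict majority; exact ties are "undecided".
  Undecided subjects count against sensitivity and specificity and are
  reported separately.
* Evaluation is leave-one-subject-out: all six segments of the held-out
  subject are excluded from training (a leakage assertion enforces this),
  and pooled out-of-fold segment scores provide the ROC.

## Synthetic data

The generator defines the study conditions; its defaults are fixed.

* **Feature level.** 18 DM and 9 C subjects, 6 segments each, 1,500 λ_max
  values per segment (the pooling of windows/repetitions behind the
  published per-segment samples is not documented; 1,500 gives tail fits
  with a few hundred exceedances, enough for a stable sign of k). Typical
  DM segments draw from the published Gamma(β, θ) family, typical C
  segments from the published positive-k GP family; a mixture fraction
  (default 1/6) of subjects per group draws from the opposite family,
  reproducing the reported 15/18 and 7/9 within-group consistency.
  `dm_tail_family="gp"` instead draws DM segments from the published
  negative-k GP pairs, for cohorts that should live on the published
  feature scale directly. Note the two published DM parametrizations are
  mutually inconsistent in scale: the GP σ of ~0.1–0.9 cannot arise from
  samples whose Gamma fit has mean β/θ ≈ 250, so the two families are
  alternatives, not a joint model.
* **Video level.** A flat skin-toned scene with eight disjoint 31×31
  patches (2 cheek, 3 forehead, 2 nose, 1 philtrum). Cheeks carry the
  shared pulse modulation at 1.32 Hz; one background patch is offset
  −10⁻³ in Red and the cheeks +10⁻³ so the extreme-intensity patches are
  stable. Group C's per-beat envelope is Pareto-distributed (exponent
  magnitude 2.2, unit-mean normalized, capped at 50× to keep intensities
  in range) — the avalanche mechanism that provably induces a polynomial
  λ_max tail; group DM's envelope is 1 + 0.3·white noise. Calibrated
  amplitudes (C 1.8×10⁻⁴, DM 3.3×10⁻³, both sub-visible; sensor noise sd
  8×10⁻⁵) reproduce the reported ~22× DM/C ratio of mean
  post-magnification patch-difference intensity (measured ≈ 24× at desk
  scale). Scene sizes: 180×320 default, 70×136 compact (tests), 720×1280
  full scale.
* What the generator does **not** emulate: real facial texture and
  landmarks (patch positions come from a static JSON manifest), head
  motion, illumination drift beyond a global gain, melanin/haemoglobin
  decomposition, and any physiological coupling between the two
  hypotheses' signals. Passing tests therefore demonstrate that the
  *pipeline* recovers the statistical structure the model posits — not
  that real faces exhibit that structure.

## Problem sizes

Tests run at desk scale: 2,500-frame (50 s) compact-layout segments for
video-level checks (20 segments), 10⁴-draw samples for parameter-recovery
checks, and the full 27-subject cohort at feature level. The acceptance
script uses the same sizes. Full-scale runs (1280×720, 5,901-frame
segments) use identical code paths via `SceneLayout.full_scale()` and the
default `SegmentSchedule`.

## Known limitations

* The mapping from one video segment to an ESD of largest eigenvalues is a
  reconstruction (sliding windows); other poolings (across pixels or
  repetitions) would change the effective sample size per segment.
* Whether N in the Tracy–Widom normalization should be the pixel dimension
  or the window length is ambiguous; the pixel dimension is used.
* sgn(k) near k = 0 is noise-sensitive; the per-segment sign accuracy
  bounds above translate into occasional subject-level flips at small
  sample sizes.
* The COWE weight optimization assumes base-learner hyperparameters are
  tuned beforehand; no nested tuning is performed.
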