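# Methods

## The analysis this package implements

`erpic` implements a case-control classification pipeline for averaged
event-related potentials (ERPs) recorded in a visual two-stimulus go/no-go
task. Each subject contributes four channels × time ERP matrices — go,
nogo (continue preparatory set) and ignore, novel (discontinue set) — on a
19-channel 10-20 montage, 250 samples at 250 Hz covering [0, 996] ms after
the second stimulus (sample *k* ↔ *k*·4 ms).

The stages are:

1. **Average reference.** Every ERP is re-referenced to the common average
   (a rank-18 projection, idempotent).
2. **Group ICA per preparatory set.** ERPs of all subjects are concatenated
   along time (subject-major, set conditions within subject) and decomposed
   into independent components under the standard forward model: scalp
   potentials are instantaneous linear mixtures of sources with spatially
   fixed topographies and independent activation time courses,
   `X = A S`. The unmixing is estimated by FastICA after PCA whitening to
   `n_ics` dimensions (extended Infomax is available as
   `algorithm="infomax"`). Topography columns are normalized to unit L2
   norm with the sign fixed positive at the maximum-|value| channel; all
   amplitude information lives in the back-projected activation curves
   `a_i[site] · (w_i @ erp)` in µV at the IC's site (the max-|topography|
   channel).
3. **Component stability by dual correlation matching.** Decompositions
   computed separately on the case and control sub-cohorts are matched
   one-to-one: a pair of ICs corresponds when its topography correlation
   and the activation-curve correlation in *every* condition of the set
   all exceed 0.5. Among admissible pairings the summed |topography r| is
   maximized by an exact assignment on a zero-padded weight matrix, so
   partial matchings are handled correctly. Ocular-artifact ICs are
   excluded by |r| ≥ 0.8 against a fronto-polar template. ICs found in
   both preparatory sets (topography r > 0.5 across sets) are treated as
   set-independent: the discontinue-set copy is kept and forced to the
   ignore condition, the continue twin is dropped to avoid duplicate
   features.
4. **Window-grid features.** For each retained IC, curves at the IC's site
   in its dominant condition(s) (peak-to-peak ratio ≥ 0.8 keeps the second
   condition) are swept with closed windows: starts every 8 ms from 0 ms,
   widths 114 ms × {0.5, 0.75, 1, 1.25, 1.5} floored to the sample grid
   (56, 84, 112, 140, 168 ms), window end ≤ 700 ms — 371 windows, five
   feature kinds each (min/max peak amplitude in µV, their latencies in ms
   with earliest-sample tie-break, mean amplitude). "Peak" is the window
   extremum, not a local-extremum detector.
5. **Classification.** RBF-kernel SVM on standardized features; stratified
   10-fold cross-validation with confusion counts pooled over held-out
   folds (case = positive class). Greedy sequential forward selection adds
   at each step the feature maximizing pooled CV accuracy (ties → lower
   column index), up to `k_max` = 10; the retained count is the smallest k
   that no later step improves by more than 0.01 accuracy. An optional
   univariate pre-screen (|Welch t|, computed on training data only) keeps
   the top-m candidates; with ~3·10⁴ window-grid features this is what
   makes greedy selection tractable, and because it runs inside each
   training fold it introduces no leakage. `nested_cv` repeats screening,
   selection and tuning inside every outer training fold for an unbiased
   accuracy estimate; the plain CV accuracy of the finally selected subset
   is also reported.
6. **Frozen-filter external validation.** A held-out (here: all-case)
   sample is decomposed with the main-sample spatial filters unchanged,
   its features extracted with the trained model's feature identities, and
   accuracy reported. For a single-class sample only accuracy and the
   corresponding class rate are defined; the report flags this.

## Synthetic cohort generator

Because the pipeline's correctness claims are all relative to known ground
truth, the generator realizes exactly the assumptions the ICA stage makes:
linear summation at the electrodes, spatially fixed topographies,
condition-specific source activation curves. Per subject and condition,

`ERP = A S(subject, condition) + ε`, `ε ~ N(0, noise_sd²)` i.i.d.

* **Topographies** are unit-norm spatially smooth fields on the electrode
  positions: a Gaussian-process draw (squared-exponential covariance,
  chord-distance length scale `smoothness` = 0.6) plus a deterministic bump
  at each source's center channel. Draws with pairwise column correlation
  ≥ 0.95 are rejected. Dipolar forward models are deliberately avoided —
  smooth fields suffice for identifiability testing without a head-model
  dependency.
* **Activation curves** are sums of Gaussian deflections
  (polarity, latency, width = Gaussian σ, amplitude), which give analytic
  peak locations for oracle tests.
* **Group effect**: designated informative sources shift all deflection
  latencies by +40 ms and scale amplitudes ×1.5 in the case group
  (defaults; both configurable).
* **Subject variability**: per subject and source one latency offset
  ~ N(0, 8 ms) and one amplitude factor ~ N(1, 0.2), shared across
  conditions as a stable individual trait.
* **Default catalogue**: eight sources emulating a go/no-go component set —
  an early visual stream source active in all conditions
  (set-independent), an inhibition-related N2/P3 sequence (nogo), a
  parietal P3b (go), a biphasic premotor go/nogo source, a triphasic
  medial-frontal nogo source, a novelty P3a, an auditory-N1-like novelty
  source, and an occipito-temporal ignore/novel source. Sources 1, 2 and 5
  (N2-nogo, P3b-go, P3a-novelty) are informative. Deflection latencies and
  widths were chosen so that no two co-active sources have activation-curve
  correlation above ≈0.5 and the average-referenced mixing has condition
  number ≈10: with substantially stronger temporal collinearity the ICA
  model itself is unidentifiable and no implementation could recover or
  stably match the planted components.

Magnitudes the generator does **not** take from any published source (none
are printed): sensor noise sd 1.0 µV — plausible for ~100-trial averages of
raw EEG with 10–20 µV background — deflection amplitudes 3–7 µV, subject
amplitude sd 0.2. What the generator does *not* emulate: trial-level
epochs and their averaging, non-Gaussian or spatially correlated residual
noise, volume-conduction head geometry, eye-blink waveforms, inter-subject
topography variability. Passing tests therefore show the pipeline recovers
what it assumes; they do not show robustness to violations of the forward
model (e.g. moving sources or strongly correlated generators), which is a
known limitation of ICA-based ERP decomposition generally.

## Numerical choices

* FastICA: PCA whitening to `n_ics`, tol 1e-6, max 1000 iterations, fixed
  seed; on heavily overlapping sources it may stop at the iteration cap —
  the resulting rotation is still deterministic given the seed. Input rank
  below `n_ics` raises a degenerate-input error naming the achieved rank.
* Window widths are floored to the 4 ms grid (57 → 56, 142.5 → 140 …),
  matching the printed spans of known selected windows; windows are closed
  intervals including both endpoint samples; latency ties take the
  earliest sample.
* Standardization uses population (ddof 0) moments; zero-variance columns
  are centered, scale left at 1, and flagged.
* Default SVM hyperparameters during selection are C = 1, γ = "scale" (a
  single-point grid, so no inner search); the final model is tuned by
  inner 5-fold search over C ∈ {1, 10} × γ ∈ {"scale", 0.1}.
* Matching uses signed correlations for admissibility (polarity is already
  canonical) and |r| for the assignment objective.
* Trained models serialize to JSON (support vectors, dual coefficients,
  intercept, standardization); prediction is computed from the stored
  arrays, so deserialized models reproduce decision values exactly.

## Problem sizes in the validation suite

The test suite validates the pipeline at sizes a laptop CPU handles in
minutes, chosen as the package's own verification scale: ICA oracles on
noiseless cohorts of up to 8 sources; matching stability on two 40-per-group
cohorts drawn from one ground truth at default noise; the classification
null on 100 subjects per class over 20 seeds; end-to-end recovery on 20
seeded 50-per-group cohorts with nested 10-fold CV, selection capped at 6
features over the top-25 screened candidates; frozen-filter validation on a
17-subject all-case sample. The acceptance script runs the full default
configuration (k_max 10, screen 40) once.

## Known limitations

* With the default effect sizes (40 ms shift, ×1.5 amplitude, 8 ms jitter)
  the groups are strongly separable: forward selection typically reaches
  ≥ 0.96 CV accuracy with the *first* feature, so the tolerance elbow
  retains one feature. The five-feature outcome the window-grid/selection
  machinery is designed around emerges only for weaker, complementary
  effects (see the planted-feature selection tests).
* ICs are matched to planted sources by topography correlation; when two
  planted sources overlap both spatially and temporally, ICA returns a
  rotation of them and attribution to a single source is ill-defined.
* The ICA stacking treats subjects as time-concatenated observations; the
  alternative subject × (channel, time) array formulation is not
  implemented.
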