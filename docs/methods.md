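# Methods

This note documents the models, estimators and design choices behind
`emgshift`: what is computed, under which assumptions, and what the
synthetic experiments do and do not demonstrate.

## Grid geometry and the simulated-shift protocol

The electrode grid is a regular `n_rows × n_cols` array with a common
inter-electrode distance (IED), channels numbered row-major; `x` runs along
columns (transversal to the muscle fibers), `y` along rows (longitudinal).
The default montage is 8 × 24 at 10 mm (192 monopolar channels). The grid
is treated as planar: although a real forearm montage wraps around the
limb, no wrap-around distances are used anywhere (variogram lags and
blob-to-electrode distances are computed in the flat layout).

Electrode shift is simulated by interleaved half-grid partitions. ST1
trains on even-index columns and tests on odd-index columns; ST2 reverses
the roles; SL1/SL2 do the same with rows. Within a partition the spacing
along the shift axis doubles to 2·IED while the orthogonal spacing stays at
IED, and the i-th test channel is the i-th train channel displaced by
exactly one pitch — so train and test montages are congruent 96-electrode
grids offset by 10 mm. ST and SL are matched controls (train = test on the
even-index half). Mapping "even" to training in ST1/SL1 is a labeling
convention; any consistent assignment is equivalent under relabeling, which
is why ST1 and ST2 are each other's role swap.

The generator additionally supports a *continuous* physical shift
(`apply_physical_shift`), implemented by translating source activation maps
relative to the grid; the half-grid protocol and the continuous shift can
be composed or compared.

## Synthetic HD-EMG model

Real recordings matching this protocol are not publicly available, so the
package generates sessions with the statistical structure the features
consume:

* **Shared anatomy, motion-specific recruitment.** A pool of `n_sources`
  (default 8) muscle-like sources is placed uniformly under the grid once.
  Each motion recruits a sparse subset (default 3) with its own gains
  (uniform 0.5–1.5); the last motion is "no movement" (sensor noise only).
  Sharing sources across motions is what makes the problem realistically
  hard: motions overlap in space and differ in recruitment, so class
  separation depends on covariance structure rather than disjoint support.
* **Spatial mixing.** Each source projects onto the channels through a 2-D
  Gaussian blob. Blob spreads are drawn per source from 10–20 mm (muscles
  at different depths have surface representations of different widths),
  which also gives motions distinguishable variogram signatures.
* **Fine-scale texture.** Each source's smooth blob is multiplied by a
  fixed positive random field (random-Fourier construction of a
  squared-exponential Gaussian process, length scale 5 mm, relative
  amplitude 0.4) standing in for motor-unit-territory granularity. The
  texture is anchored to the source, so any montage displacement re-samples
  it. This is the mechanism that makes per-channel amplitude features
  genuinely shift-sensitive while leaving spatially aggregating filters
  comparatively robust; without it, a 10 mm shift of smooth blobs barely
  moves per-channel features and every method looks artificially immune.
* **Dynamics.** Sources are independent Gaussian processes band-passed to
  10–500 Hz (4th-order Butterworth, forward-backward) at 2048 Hz, matching
  the amplifier band of the targeted acquisition setup, and amplitude-
  modulated by a slow positive envelope (low-passed noise at 2 Hz, relative
  depth 0.2) capturing the ~1 s nonstationarity of sustained contractions.
  Each source is standardized to unit sample variance per trial, so the
  expected channel covariance is exactly `A Aᵀ + σ² I` for mixing `A` and
  sensor-noise SD `σ` (default 0.3).
* **Protocol.** Default sessions mirror the experimental design — 11
  motions, trials cycled in blocks, one global seed with per-trial seeds
  derived by a counter rule (`seed + trial_counter`) — at a reduced scale
  of 3 trials × 2 s per motion, which keeps a full five-feature ×
  six-configuration evaluation within minutes on one CPU while leaving
  ≥ 111 analysis windows per class.

The envelope depth and texture amplitude were calibrated so that the
synthetic study reproduces the regime reported for this protocol on real
recordings: all five feature sets above 90 % accuracy on the no-shift
half-grid controls, and per-channel time-domain features degrading severely
(roughly 45–90 %) under a 10 mm shift. They were then frozen; the package
does not adapt them per experiment.

**What the generator does not model:** motor-unit action potentials and
their waveforms, volume conduction, heavy-tailed EMG amplitude statistics,
force levels, fatigue, electrode-skin impedance changes, or inter-subject
variability. Consequences: (i) all channels share one spectral shape, so
zero-crossing/slope-sign counts carry little information here — TD
performance rests on its amplitude components, which is also where real
shift damage concentrates; (ii) passing the package's end-to-end tests
shows the *pipeline* reproduces the comparative phenomenon under a
plausible second-order model, not that the effect sizes transfer to any
particular subject.

## Windowing and features

Analysis windows are 408 samples (~200 ms at 2048 Hz, the value used with
this recording setup) advanced in 102-sample (~50 ms) increments — short
enough for a sub-300 ms controller response; both are configurable.
Windows tile each trial from its start; a trailing partial window is
dropped; no window crosses a trial boundary.

* **TD** (per channel): mean absolute value, waveform length, zero
  crossings, slope-sign changes. The ZC/SSC amplitude threshold defaults to
  0 (synthetic signals are noise-floor-free by construction); it is a
  config knob for real data.
* **TDAR**: TD plus order-6 autoregressive coefficients per channel,
  estimated by Yule–Walker equations solved with the Levinson–Durbin
  recursion on biased autocovariances of the demeaned window (sign
  convention `x_t = Σ a_k x_{t−k} + e_t`; equals statsmodels'
  `yule_walker(method="mle")`, which serves as the cross-check in tests).
  A zero-variance channel yields all-zero coefficients rather than an
  error.
* **Variogram**: isotropic empirical semivariance
  `γ(h) = 1/(2|P(h)|) Σ_{(i,j)∈P(h)} mean_t (x_i − x_j)²` over channel
  pairs grouped by distance (rounded to 0.1 mm for deterministic grouping),
  one feature per lag up to 80 mm. Raw differences are used — no
  per-channel mean removal — because the semivariance of a monopolar field
  is a statement about amplitude differences, and demeaning would erase
  constant spatial gradients. The 80 mm cap covers the grid's short axis
  and typical inter-source distances; at 40 mm a half-grid partition has
  only 7 isotropic lags, too few to separate 11 motions. The lag set is a
  documented default, not a claimed optimum.
* **Log-variance** (CSP components): natural log of the unbiased sample
  variance of each selected component, mean-centered per window; zero
  variance is floored at 1e−12 with a warning instead of producing −∞.

## CSP estimation

Class covariances are averages of per-window covariances (each window
demeaned per channel, normalized by 1/(l−1)), optionally ridge-regularized
by `ridge · trace/c · I` (default 1e−6 — the 96-channel covariances here
are kept positive definite by the sensor-noise floor, and shift accuracies
were measured to be insensitive to ridge values up to 0.2). Averaging
per-window covariances over the training windows is a pinned estimator
choice; estimating one covariance from concatenated class data is
numerically almost identical at these window counts.

The two-class solve whitens the composite `Σⱼ + Σₖ` (eigendecomposition,
inverse square root), diagonalizes the whitened `Σⱼ`, and maps the rotation
back, giving `W` with `W (Σⱼ+Σₖ) Wᵀ = I` — so `Dⱼ + Dₖ = I` holds by
construction rather than by post-hoc normalization. Filters are sorted by
descending class-j eigenvalue; the retained pair is the first and last
filter (one per extreme, the `m`-per-side generalization is available but
defaults to 1). Eigenvector signs are pinned (first nonzero element
positive). The implementation agrees with an independent generalized-
eigenproblem solve of `(Σⱼ, Σₖ)` to 1e−8 on random SPD pairs up to c = 96;
with this scaling a pure class-j toy signal with variance ratio 4:1 yields
component variances 0.8/0.2 (the ratio is preserved, the absolute scale is
fixed by the whitening constraint).

OvO fits one bank per unordered class pair (lexicographic order); OvR fits
one bank per class against the unweighted mean of the other classes'
covariances. Spatial patterns are columns of `W⁻¹ = (Σⱼ+Σₖ) Wᵀ`,
normalized to unit maximum absolute value for display.

## Classification and evaluation

LDA uses class means, a pooled within-class covariance with 1/(n−N)
normalization plus `ridge · trace/d · I` (default 1e−6), and empirical
priors; ties in the discriminant argmax break to the lowest class index.
The variogram features are classified by an RBF-kernel SVM (C = 1, kernel
width 1/(d·feature variance)) on standardized features; a small grid-search
helper exists but is off by default, since SVM hyperparameters are known to
matter for this feature family and no claim of optimality is made.

Control configurations are scored by stratified 5-fold cross-validation
over windows (the conventional protocol; note that overlapping windows make
window-level folds optimistic — trial-level grouping is available and
removes that leakage at the cost of coarser folds). For control schemes the
feature pipeline (including CSP filters) is fitted once on the half-grid
data and the folds split the feature matrix; the filters therefore see each
fold's test windows, a small optimism shared by common practice.

Shifted configurations use a strict hold-out: CSP filters, the classifier,
and the FLD projection are fitted on training-partition windows only; test
windows come from the displaced partition over the same time segments and
are only ever transformed and scored. Tests assert that corrupting
test-partition channels leaves every fitted artifact bit-identical.

## RCS

Feature sets of different dimensionality are compared after Fisher-
discriminant reduction to N−1 = 10 dimensions (generalized eigenvectors of
between- vs. within-class scatter, ridge 1e−6·trace/d on the within
scatter). The projection is fitted on pre-shift training features only —
fitting it on post-shift data would leak the very displacement being
measured. RCS is then

    RCS = (N−1) Σᵢ √((μᵢ−μ_si)ᵀ ((Sᵢ+S_si)/2)⁻¹ (μᵢ−μ_si))
          ───────────────────────────────────────────────────
          Σᵢ Σ_{j≠i} √((μ_sj−μ_si)ᵀ ((S_sj+S_si)/2)⁻¹ (μ_sj−μ_si))

with centroids μ and covariances S computed per motion in the reduced
space (where they are invertible at realistic window counts; a 1e−9·trace/d
ridge guards the inverses). RCS is zero iff no centroid moves, is invariant
to affine maps applied to both feature sets, and increases monotonically
with centroid displacement at fixed covariances. It is not computed for
the variogram/SVM pairing, which has no LDA-compatible discriminant
geometry to project with.

## Numerical conventions

Deterministic tie-breaks and sign pins everywhere: eigenvector signs by
first nonzero element, argmax ties to the lowest index, lag rounding to
0.1 mm. All randomness flows from integer seeds through
`numpy.random.default_rng`; rerunning any experiment with the same config
and seed reproduces output files byte-for-byte.

## Known limitations

* The generator validates the pipeline, not clinical effect sizes; its
  parameters are frozen, documented choices.
* The variogram baseline transfers poorly across shifted partitions in the
  synthetic world (the texture field decorrelates pairwise differences);
  on real data its robustness depends on lag-set and SVM tuning that this
  package deliberately does not optimize.
* Window-level cross-validation inflates control accuracies (overlapping
  windows); use trial-level grouping for leakage-free estimates.
* EDF input is read via `mne` when installed and is untested here (no EDF
  writer exists in the dependency set); HDF5 and delimited-matrix I/O are
  the supported round-trip formats.
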