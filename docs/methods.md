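# Methods

## The analysis model

`erpfield` contrasts paired experimental conditions of a high-density ERP
study at three levels.

**Amplitude (mass-univariate).**  For each electrode and time sample the
per-participant condition averages are compared with a paired t-test,
`t = mean(d) / (sd(d)/√n)`, df = n − 1, two-tailed p.  Points with p below
the significance level (default α = 0.01) are then pruned by two persistence
criteria: a *temporal* criterion clearing runs shorter than `min_samples`
(default 10 samples, i.e. 20 ms at the 500 Hz default rate) per electrode,
and a *spatial* criterion that, per time sample, keeps only connected groups
of at least `min_channels` (default 5) significant electrodes, where
connectivity uses the montage adjacency graph restricted to edges inside one
scalp cluster.  Multiple comparisons are additionally controlled with a
paired sign-flip randomization test on the participant difference waves: the
statistic is the point-wise t; when 2ⁿ ≤ `n_perm` all sign assignments are
enumerated and p is the exact null proportion, otherwise `n_perm` seeded
draws are used with `p = (count + 1)/(draws + 1)`.  The default order of
criteria is temporal → spatial, with the parametric and randomization masks
combined by flagging each summarized effect with whether it intersects the
randomization-surviving mask.  Zero-variance points yield flagged ±∞ t
values rather than exceptions (0/0 points are defined as t = 0, p = 1).

**Global field.**  GFP is the spatial standard deviation over channels
(population convention; equal to the RMS under the average reference) and
indexes field strength.  DISS between two average-referenced maps, each
scaled to unit GFP, is `sqrt(mean of squared differences)` and satisfies
`DISS² = 2(1 − r)`; it indexes field topography and ignores strength.  The
GFP test statistic per time point is |mean over participants of the GFP
difference| with a sign-flip null; the TANOVA statistic is the DISS between
the two conditions' group-mean maps with a per-participant label-swap null
(label swapping, not sign flipping, because DISS is unsigned).  Participant
maps are GFP-normalized *before* averaging by default
(`normalize_first=False` normalizes the group averages instead; the two
conventions differ only when participants' map shapes differ, and the
per-participant normalization weighs participants equally).  Windows
shorter than `min_duration_ms` (default 20 ms) are discarded.

**Sources.**  The forward model is a three-shell concentric-sphere conductor
(default radii 0.87 / 0.92 / 1.0 of the head radius, conductivities 0.33 /
0.0042 / 0.33 S/m for brain / skull / scalp).  Per spherical-harmonic order
the radial solution in each shell is `A rⁿ + B r⁻⁽ⁿ⁺¹⁾`; matching potential
and radial current at both interfaces with an insulating scalp surface gives
the outer-surface transfer factor, and dipole potentials follow from the
Legendre expansion of the source term (default truncation 60 terms;
adequate for sources with eccentricity ≤ 0.85, where the series decays like
0.85ⁿ).  With equal conductivities the transfer factor reduces analytically
to the single-sphere value (2n+1)/n, which the tests verify against an
independent homogeneous-sphere series.  Gains are computed for unit dipoles
along x, y, z at every grid point and average-referenced per column.

The inverse is LAURA (Local Auto-Regressive Average): on the cubic solution
grid (spacing default 0.15 head radii, clipped strictly inside radius 0.85)
the local operator has `A_ii = (26/|N(i)|) Σ_k d_ik^−e` and
`A_ij = −d_ij^−e` over the 26-neighborhood (weight exponent e = 2 by
default, 3 selectable for the vector-field convention), applied blockwise
per Cartesian component.  The source metric is `M = (AᵀA)⁻¹` and the
estimator `G = M Lᵀ (L M Lᵀ + λ²I)⁻¹` with
`λ² = lambda_frac × mean diag(L M Lᵀ)` (default `lambda_frac` 0.01; the
paper-style workflow fixes regularization once and logs it).  `M` is never
formed explicitly — `AᵀA` is factorized sparsely and applied to `Lᵀ`.
Group analysis averages each participant's evoked scalp map over the test
window, applies `G`, takes per-point magnitude, normalizes magnitudes to
unit RMS over the grid, and runs voxel-wise paired t-tests: points beyond
the two-tailed critical value (2.88 for 19 participants at α = 0.01) are
grouped by 26-neighborhood contiguity per sign; clusters below the
`min_cluster` cut-off (default 10) are excluded from the main report but
listed sub-threshold, without any extra multiplicity adjustment.

**Behavior.**  Valence (−4..+4) and arousal (1..9) scores are rescaled per
participant and measure by subtracting the trial-weighted grand mean over
the three conditions (the unweighted mean of condition means is available
by flag; the two coincide for balanced designs).  Summaries report the mean
and SE of participant-level condition means.  Mixed-effects modeling of the
ratings is intentionally left to standard statistical packages — the module
emits a tidy long-format table ready for such a fit.

## The synthetic generator

The generator emulates a three-condition film-editing ("neutral face →
emotional context → same neutral face") EEG study so that every stage has
ground truth:

* **Design** — 6 blocks × 48 trials; 48 contexts (16 per condition), each
  shown once per block; 24 face identities (half female), each repeated 12
  times, paired with any given context at most once; gender and gaze
  orientation balanced 48/48 within each condition.  Identity assignment is
  a seeded randomized backtracking search with per-block identity capacity
  (2), per-block condition × gender quota (8), and pair-uniqueness
  constraints; trial order within block is a seeded permutation.  The
  (block, condition, context) content is identical across seeds — only the
  pairing and ordering vary.
* **Epochs** — each trial is a sum of Gaussian-envelope component templates
  (P1 110 ms / N170 185 ms / N2 250 ms / LPP 550 ms, plus an anterior LPP
  subcomponent at 560 ms) times smooth von Mises–Fisher scalp topographies,
  scaled by a per-participant gain (SD 0.15), plus structured noise:
  spatial covariance `exp(−angle/0.6 rad)` across channels and an AR(1)
  process (coefficient 0.95) in time, marginal SD 10 µV, average-referenced
  per sample.  Condition effects follow the emulated study's qualitative
  pattern: the P1 peaks 12 ms earlier for Fear; the N170 is strongest (most
  negative) for Neutral (multipliers 1.2 / 0.8 / 0.875); the LPP is larger
  for emotional contexts (1.0 / 1.65 / 1.4 for Neutral / Fear / Happiness)
  *and* gains an anterior/medial subcomponent there (0.2 / 1.3 / 0.9) — the
  latter makes the late modulation topographic as well as quantitative,
  which is what the TANOVA and the source contrast are designed to detect.
  Effect magnitudes are calibrated so the largest posterior condition-mean
  difference falls in the LPP window, per the emulated study's pattern.
  A full-sequence mode generates −100..6000 ms epochs locked to the first
  face with condition-independent components at the first face onset and the
  condition-modulated set at +4500 ms (1500 ms face + 3000 ms context shot),
  used for segmentation tests and the first-face negative control.
* **Ratings** — score = baseline + participant intercept (SD 0.5) +
  condition shift + integer-rounded noise (SD 1.5), clipped to the scale.
  Default shifts relative to Neutral: Fear valence −0.93, arousal +0.79;
  Happiness valence +0.46, arousal 0.  The noise is discretized so the
  zero-noise limit reproduces the configured shifts exactly.
* **Artifacts** — a configurable fraction of trials receives a 500 µV
  Gaussian transient (SD 10 ms) on one random channel, with ground truth
  returned, exercising peak-to-peak rejection (default threshold 200 µV).

What the generator does **not** emulate: ocular/cardiac artifact
morphologies (threshold rejection replaces ICA-based cleaning), line-noise
spectra, inter-individual head geometry, volume-conduction-consistent
noise (noise topographies are distance-correlated, not lead-field
generated), or realistic single-trial non-stationarity.  Passing tests
therefore demonstrate statistical correctness and sensitivity under a
plausible signal-plus-structured-noise model, not performance on any real
recording.

## Sensor model

The built-in layout is the 129-channel geodesic net geometry bundled with
MNE, re-centered on its best-fit sphere and normalized to unit radius; any
`.sfp`-style position file is accepted as an alternative.  The conventional
19-channel outermost belt is excluded by default, retaining 110 channels.
"Adjacent" is operationalized as a central angle ≤ 26°, chosen so the
retained montage has mean degree ≈ 6.  The nine scalp clusters are a 3 × 3
partition by the anterior–posterior and left–right coordinates with a
configurable midline/central band half-width (default 0.25).  Bad channels
are repaired by spherical-spline interpolation (order m = 4, series
truncated at 7 Legendre terms, ridge 1e−5 on the spline system) — spline
order and truncation follow common practice for scalp potentials.

## Numerical choices and degenerate inputs

* Randomization p-values: exact proportions in exhaustive mode (identity
  permutation included), `(count+1)/(draws+1)` in sampled mode; statistics
  compared with a 1e−12 tie tolerance.  The significance mask uses strict
  `p < α`.
* The sign-flip t statistics reuse the flip-invariant sum of squares, so a
  permutation pass is a single matrix product (chunked to bound memory).
* Filters: 4th-order Butterworth band-pass applied forward–backward
  (zero-phase) plus an IIR notch (Q = 30); band edges validated against the
  Nyquist frequency.  Epoch windows are inclusive of both endpoints
  ((−100, 6000) ms at 500 Hz → 3051 samples).
* Zero-GFP samples in TANOVA are skipped with p = 1; degenerate permuted
  group maps count as extreme (conservative).
* The repeated-measures ANOVA on accepted-trial counts returns F = 0 when
  the between-condition sum of squares vanishes (the fitted model is
  singular there).
* Rejection refuses to discard all trials; rejection above 22 % logs a
  warning.

## Problem sizes used by the test suite and acceptance script

Chosen as desk-scale versions of the study conditions: type-I calibration
uses 300 (tests) / 150 (script) null simulations at 8 participants × 8
trials × 10 channels × 60 samples with exhaustive 256-permutation tests,
pooling point-wise rejection rates; parameter recovery runs the full
110-channel analysis at the study size (19 participants × 80 accepted
trials) over 3 seeded replicates in the tests and one replicate in the
script; dipole localization averages 50 random interior sources on a
spacing-0.15 grid (~750 points); behavioral recovery uses 18 participants.

## Known limitations

* The concentric-sphere head model replaces realistic (BEM/FEM or locally
  fitted) geometry; solution points carry no anatomical labels, so source
  clusters are reported by head-frame coordinates only.
* The grid point count is a free parameter of the head model, not a
  constant of the method.
* The spatial criterion is applied per time sample; requiring the electrode
  group to persist jointly across a whole window would be stricter (the
  per-sample choice matches the separable reading of the two criteria).
* TANOVA here is the two-condition paired variant; omnibus multi-condition
  topographic tests and microstate segmentation are out of scope.
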