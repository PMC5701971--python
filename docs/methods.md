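# Methods

## Permutation entropy

The package measures temporal complexity as the Shannon entropy of ordinal
patterns. A window of `m` samples taken every `l` steps is reduced to the
permutation that sorts it ascending; sliding the window with step 1 over a
series of length `N` yields `N − (m−1)·l` patterns, whose empirical
distribution has entropy `PE = −Σ P_g ln P_g` (nats), normalized by
`ln(m!)` to `[0, 1]`. Conventions fixed here:

* **Pattern identity** is the ascending-order index sequence `(j₁…j_m)` —
  the stable argsort of the window — not its inverse permutation. Both
  conventions give identical entropies; the tests and oracle pin this one.
* **Ties** are broken by original position (stable sort). Equality is
  bitwise floating-point equality, with no epsilon: BOLD values virtually
  never tie, and an epsilon would make the pattern map discontinuous.
* `0·ln 0 = 0`; a single-pattern series has entropy exactly 0.
* **Validity**: both `m! ≤ N − (m−1)·l` (every pattern reachable) and
  `N ≥ (m+1)!` (no undersampling) must hold. `validate_params` returns a
  verdict instead of raising so exploratory settings can be logged and run
  anyway in library code; the CLI refuses invalid settings unless `--force`
  is given. With the default 130 retained volumes, `m = 4, l = 1` is the
  only recommended choice (`m = 5` already fails `N ≥ 720`).

Because only ranks enter, the measure is invariant under strictly
increasing transforms of the signal — so whether voxel series are variance-
normalized before entropy computation is immaterial, and the package does
not normalize them.

## Temporal preprocessing

Stage order is fixed and recorded in every output's sidecar: drop the first
`k = 10` volumes (adaptation/equilibration), voxelwise OLS linear detrend,
then optional nuisance regression (global mean, 6 motion parameters, CSF
and WM means, plus an intercept). Spatial preprocessing is assumed done
upstream; the package consumes registered volumes and says so loudly in the
logs. No temporal filtering is applied. Detrending is idempotent and is
*not* monotone, so the stage ordering is observable: entropy after
detrending differs from entropy before, which the tests exercise.

## Maps

* **PE map**: normalized PE of every in-mask voxel's preprocessed series,
  vectorized over voxels (integer-encoded patterns + bincount).
* **ReHo map**: Kendall's W of each voxel with its neighborhood (27 by
  default; 7/19 available). Within-series ranks use midranks for ties and
  no tie-correction term — ties are negligible for continuous BOLD data. At
  mask edges the neighborhood shrinks to the in-mask members; voxels with
  fewer than 2 members are dropped from the output mask. This matches
  common ReHo tooling; the neighborhood size is configurable because
  published choices vary.
* **Smoothing** is applied to the finished maps, never to the 4-D series:
  pre-smoothing the series mechanically inflates regional concordance (a
  property test demonstrates the inflation). The kernel is an
  axis-separable discrete Gaussian with `σ = FWHM/(2√(2 ln 2))` per axis in
  voxel units, truncated at 4σ, with weights renormalized over the in-mask
  support: constants are preserved exactly and no out-of-mask sentinel
  leaks in. Out-of-mask voxels are NaN on disk, never 0. Renormalized
  masked smoothing preserves constants but is not exactly mean-preserving
  for non-constant maps near mask edges; bit-level equivalence with SPM's
  smoother is a non-goal.

## Group statistics

* **Voxelwise ANOVA**: per voxel, a single linear model with treatment-coded
  group indicators plus covariates (age, sex by default); the group effect
  is the partial F from full-vs-reduced residual sums of squares with
  df = (G−1, n−G−c). A single adjusted model was preferred over
  residualize-then-ANOVA: the two differ slightly and the model-based route
  is the standard one. Without covariates this reduces exactly to textbook
  one-way ANOVA (checked against hand-computed sums of squares and the t²
  identity for two groups).
* **Cluster correction**: voxels with parametric p below the forming
  threshold (default 0.005) are grouped by face adjacency (6-connectivity,
  configurable to 18/26 since published tools differ across versions).
  Extent significance comes from a permutation null: group labels are
  shuffled (covariates held fixed), the maximal suprathreshold cluster size
  recorded, and observed clusters compared against the (1−α) null quantile,
  with `p_cluster = (1 + #{null ≥ size})/(n_perm + 1)`. This replaces
  parametric Gaussian-random-field correction, which needs smoothness
  estimation machinery and is fragile at small scale; the permutation route
  is assumption-light and its familywise error is itself verified by a
  calibration test (200 pure-noise replicates at reduced resolution).
  Permutations that produce a singular design (possible at tiny n) are
  redrawn. Fewer than 100 permutations are refused without a force flag.
* **ROIs** are spheres in world (MNI) coordinates, default radius 8 mm,
  membership by voxel-center-in-sphere without partial-volume weighting;
  the voxel containing the center is always a member (covers radius 0). ROI
  centers default to detected cluster peaks, or can be supplied as a CSV to
  decouple extraction from detection.
* **Post-hocs**: all pairwise pooled-variance t tests with Bonferroni
  adjustment (×number of pairs); a Welch variant is available. Pairs with a
  group of fewer than 2 subjects are skipped with a note.
* **Correlations**: Pearson r with two-sided t-based p, computed by default
  over the pooled patient groups (EMCI+LMCI+AD), optionally all four
  groups. CDR is treated as numeric here even though it is ordinal with
  three levels — a deliberate mirroring of common practice, and a
  statistical caveat.

## Synthetic cohort

The generator manipulates complexity through AR(1) regularity — one
parameter, monotone in entropy, trivial to calibrate — rather than spectral
shaping. Defaults define the study conditions:

* Grid 20×24×20 at 3 mm (reduced preset 12³), 140 timepoints at TR = 3 s
  (130 analyzed), groups NC/EMCI/LMCI/AD of 30/33/32/29.
* Each voxel: `x_t = φ·x_{t−1} + ε_t`, unit innovations, exact stationary
  start. Effect-region φ by group: 0.30 / 0.40 / 0.50 / 0.65 against a 0.30
  background, per-subject jitter SD 0.03. A Monte-Carlo test (500 series
  per level, N = 130) confirms expected entropy strictly decreases over
  φ ∈ {0, 0.3, 0.6, 0.9} with non-overlapping confidence intervals.
* Each effect region carries one shared AR(1) series mixed in with weight
  `√ρ`; ρ rises with severity (0.10 / 0.20 / 0.30 / 0.45), so regional
  homogeneity rises while entropy falls — producing the negative
  entropy–ReHo association in the patient pool.
* Clinical scores are linear in the realized regularity θ:
  `MMSE = 35.7 − 22.6·θ + N(0, 2)` clipped to [0, 30] and
  `FAQ = −12.6 + 42.5·θ + N(0, 3)` clipped to [0, 50], calibrated so group
  means land in the instruments' typical cohort ranges (NC ≈ 28.9 / 0.1,
  AD ≈ 21 / 15). CDR is group-assigned (0, 0.5, 0.5, and for AD 0.5 or 1
  with P(1) = 0.68, mean ≈ 0.84). Ages ~ N(73, 6²) truncated; sex
  alternates within group. Clipping events are recorded in the truth file.
* Signal units: baseline 1000, scale 20, plus a per-voxel linear drift
  (slope SD 0.05/volume) so detrending has real work to do. A mock
  six-column motion random walk per subject exercises the nuisance path.
* Tissue masks are fixed geometric partitions (ellipsoid brain; core
  "CSF", mid shell "WM", outer shell "GM") — purely synthetic geometry to
  exercise tissue summaries, with no anatomical realism intended.
* Determinism: every random stream is derived from the master seed plus a
  fixed stream index (cohort-level draws, per-subject volumes, motion), so
  identical spec + seed reproduce byte-identical outputs regardless of
  iteration order.

What the generator does **not** emulate: hemodynamic response shape, 1/f
and physiological noise spectra, spatial autocorrelation of real BOLD
outside the shared-signal regions, motion artifacts, registration error,
and anatomical structure. Passing recovery tests therefore show that the
pipeline detects and orders regularity differences of plausible magnitude
under realistic n and N — not that real ADNI effect sizes are reproduced.

## Problem sizes used in the automated checks

Chosen as the package's own validation budget: ANOVA calibration uses a
study-sized cohort (124 subjects) on 2,000 independent null voxels with a
Kolmogorov–Smirnov uniformity check; cluster-extent familywise error uses
200 pure-noise replicates of 24 subjects on a 12³ grid with 100
permutations each at α = 0.1; finding recovery uses 20 seeded runs of the
default cohort on the reduced 12³ grid, unsmoothed maps, with the effect
region itself as the ROI. The full-size grid and peak-derived ROIs run
through the same code paths in the example workflow and CLI tests.

## Known limitations

* No spatial preprocessing: garbage in, garbage out for unregistered data.
* GRF correction is intentionally not implemented; permutation extent
  correction answers a slightly different question (max-extent FWE).
* Kendall's W omits the tie-correction term (midranks only).
* The entropy of short series (N = 130, m = 4) is estimated from 127
  windows over 24 patterns and is biased downward for near-random signals;
  group *comparisons* are unaffected since the bias is shared.
* CDR-as-numeric Pearson correlation is a convention, not a recommendation.
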