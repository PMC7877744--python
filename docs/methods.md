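# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions of the `kinclust` pipeline, and what its synthetic validation can
and cannot show about real motion-capture data.

## The analysis model

The pipeline treats "does a bypass-prosthesis group move differently from
non-disabled controls for task T at degree of freedom D?" as an unsupervised
separability question. For each cell (condition, task, DOF) it clusters the
pooled six-feature observations of 6 bypass participants and 6 normative
controls (2 trials each, last manipulation segment only → 24 rows × 6
features) into two groups with binary k-means, and scores the agreement
between cluster membership and true group membership with the Deviation from
Chance,

    DfC = |labeling accuracy% − 100/#categories|,

which is invariant to the arbitrary assignment of cluster indices: an
accuracy of a% and of (100 − a)% give the same DfC, so only the *separation*
matters. For the binary case DfC ∈ [0, 50]. Each cell is evaluated over 10
iterations, each drawing a fresh random 6/6 split of the 12 normative
participants into a BP-control and a DK-control group, so the spread of the
10 DfC values reflects natural variation in normal movement. A cell is
flagged when a one-sided Wilcoxon rank-sum test supports that its DfC values
exceed 25, half the maximum, at α = 0.05. No multiple-comparison adjustment
is applied (the goal is identification of candidate cells, not confirmatory
inference); a Benjamini–Hochberg option exists but is off by default.

### Statistical conventions

* **Rank-sum against a scalar threshold.** Comparing a 10-value sample
  against the constant 25 through a two-sample rank test is ambiguous; the
  default resolves it literally, testing the sample against ten copies of the
  threshold. The exact permutation path (pooled n ≤ 20) uses midranks, so
  this heavily tied comparison is handled without approximation — ten values
  of 50 against ten of 25 give p = 1/C(20,10) ≈ 5.4·10⁻⁶. A conventional
  one-sample alternative (`method="signed_rank"`, Wilcoxon signed rank of the
  differences, zeros dropped) is available.
* **Rank-sum implementation.** Exact enumeration of all C(n, n_a) group
  assignments for pooled n ≤ 20 (cached membership matrices make this a few
  milliseconds); otherwise the midrank normal approximation with tie
  correction and 0.5 continuity correction. The two paths agree within 0.02
  on tie-free 10 vs 10 samples; the exact path matches scipy's exact
  Mann-Whitney on tie-free data to machine precision.
* **Sample SD** of iteration DfC values uses ddof = 1.

### Clustering conventions

The k-means core is implemented in-repo so its policy is fully specified:
k-means++ seeding (first center uniform over points, each next center drawn
with probability proportional to squared distance to the nearest chosen
center), Lloyd iterations until assignments stabilize (cap 100), empty
clusters repaired by re-seeding with the point farthest from its assigned
center, five seeded replicates with minimal within-cluster sum of squares
(WCSS) winning and ties broken toward the lowest replicate index. WCSS
non-increase is asserted at every Lloyd step. On two-cloud instances
separated by ≥ 5 cluster-SDs with n ≤ 12 the best-of-five procedure attains
the exhaustively enumerated global optimum in ≥ 99% of seeded instances;
on unstructured noise the rate drops to ~92–95%, identical to other
best-of-five Lloyd implementations — a property of the local optimizer, not
of this implementation.

## Preprocessing

* **"4th-order zero-lag Butterworth at 6 Hz"** is realized the way the
  biomechanics literature conventionally means it: a 2nd-order filter applied
  forward and backward, which squares the magnitude response (effective 4th
  order) and cancels phase. `filter.mode = "literal_dual_pass"` selects the
  literal reading (4th order per pass, effective 8th-order magnitude). Both
  modes are validated against the closed-form squared magnitude response of
  the designed filter. Edge handling: odd reflection, pad length
  3 × (per-pass order + 1).
* **Segmentation**: "approximately 10 frames" before contact and after
  release is implemented as exactly 10 (configurable), closed intervals,
  0-based frames, clamped to trial bounds. Whole trials are filtered before
  windowing. Only the last segment per trial enters the analysis.
* **Resampling**: the common length n for the path-distance feature is not
  fixed by the study description; the default is n = 101 (a 0–100% normalized
  time axis), linear interpolation with exact endpoints.

## Features

Velocity is computed by central differences (one-sided at the ends) on the
filtered, segmented trace at native sampling — only PDist uses the resampled
trace, since resampling exists to make path length comparable across
durations. Peak angular velocity is the signed maximum of the derivative per
the literal definition (`features` config offers |·|). Zero crossings count
strict sign changes of the velocity, ignoring exact zeros (a +,0,− run counts
once). Max normalization (divide each column by its maximum absolute value;
all-zero columns pass through with a warning) is applied per analysis matrix
— i.e. per condition × task × DOF × iteration — because each clustering in
the original design saw exactly one such matrix; whether normalization was
instead global is not recoverable, and the per-matrix choice keeps every
iteration self-contained.

The unit of clustering is the (participant, trial) last segment, giving 24
rows per analysis; `analysis.average_trials` collapses to one row per
participant (12 rows) for sensitivity checks.

## The synthetic cohort generator

The generator exists because the study's recordings are not deposited; it
emulates the *statistical structure* the analysis assumes, not biomechanics.

* **Trajectory model**: per object manipulation, each DOF performs an
  out-and-back excursion `baseline + amplitude · s(τ)` where `s` is the
  minimum-jerk position profile 10τ³ − 15τ⁴ + 6τ⁵ (bell-shaped velocity, the
  standard kinematic model of reaching), mirrored about the segment midpoint.
  Event pairs bracket each excursion with ≥ 20 frames of clearance, so the
  ±10-frame margins never clamp.
* **Defaults**: 100 Hz; segment length 120 frames (1.2 s) with 40-frame gaps
  and 30-frame lead-in/out; 5 manipulations for JHFT tasks (page turning's
  five card turns; the other JHFT items are unstated in the study design and
  default to the same, configurable) and 16 for the Box-and-Blocks variants;
  12 Norm / 6 BP / 6 DK participants, 2 trials, 9 tasks → 432 recordings.
* **Variability model**: per-participant baseline posture jitter
  (SD 2° per DOF) and amplitude factor (SD 10%), per-segment amplitude jitter
  (SD 5%), i.i.d. Gaussian sensor noise (SD 0.5°) added *before* filtering so
  the 6 Hz low-pass is exercised. Participant styles are drawn from the same
  population regardless of condition, making conditions exchangeable when no
  effects are injected — the basis of the null calibration tests.
* **Compensatory effects** per (condition, task, DOF): postural offset
  (degrees), amplitude scale, windowed sinusoidal oscillation (amp, Hz < 50),
  and a movement-speed scale that rescales excursion duration. The study
  reports no effect sizes, so magnitudes are free parameters; the built-in
  preset uses offsets of 6–10°, amplitude inflation of 20–40% and ~2° 1.5–2 Hz
  oscillations, loading torso/shoulder cells for the body-powered condition
  and additionally neck cells for the DEKA condition — qualitatively the
  pattern such devices elicit. These were chosen once as plausible values and
  are not calibrated to the study.
* **Seeding**: one master integer seed; every trial, participant draw,
  iteration plan and k-means replicate derives an independent substream via
  `SeedSequence(master, *keys)` with string keys mapped through CRC-32, so
  any single unit is regenerable in isolation and runs are bit-reproducible.

**What passing tests show**: that the pipeline's machinery is correct (filter
response, feature identities, clustering optimality on separable data, exact
test p-values), that its null behavior is calibrated (< 10% of cells flagged
on effect-free cohorts; observed rate ≈ 0), and that injected single-cell
effects of ~5× the between-participant feature SD are recovered as the
top-ranked significant cell. **What they cannot show**: anything about real
compensatory movement — real joint angles are cross-correlated across DOFs,
non-stationary, and contain soft-tissue/marker artifacts the generator does
not model, and the study's empirical DfC values and frequency tables depend
on its unavailable recordings.

## Problem sizes used in validation

The test suite runs full-design analyses (432 recordings, 2,520 k-means) for
the enumeration checks, and reduced designs (1–2 tasks, 3 manipulations,
shorter segments) for the repeated-cohort calibration checks: 20 perturbed
cohorts for effect recovery and 5 null cohorts for specificity at the full
9 × 14 grid, 200 mini-cohorts for the exchangeability calibration, and 500
instances for the k-means/enumeration equivalence. These sizes were chosen to
keep the whole suite in a few minutes while leaving the statistical
assertions well-powered.

## Known limitations

* Independent DOFs in the generator: no kinematic chain coupling, so
  multi-DOF compensation patterns cannot be emulated.
* The rank-sum-vs-constant construction is one defensible reading of a
  genuinely ambiguous design; the signed-rank alternative can disagree near
  the threshold.
* k-means is a local optimizer; with five replicates a small fraction of
  unstructured instances converge to non-global optima (logged, and bounded
  by the oracle-equivalence test on separable instances).
* Labeling accuracy is reported under both cluster-to-group mappings; DfC is
  invariant to the choice, but any consumer of raw accuracies must pick a
  convention (the log stores the identity mapping).
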