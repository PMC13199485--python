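# Methods

`cet` quantifies when convergence & extension (C&E) morphogenesis begins —
in gene expression, in explant shape, and in cell movement — from
stage-resolved TPM panels, explant segmentation masks, and nuclear-tracking
tables.  This note documents the models, the parameters that matter, the
synthetic-data generators the tests run against, and the numerical choices
made where the design was genuinely open.

## The trigger-gene screen

A *trigger* gene is one whose transcript level is flat before gastrulation
onset and rises sharply at it, in every condition screened.  The screen
operationalizes this on replicate-mean TPM with hard fold-change rules:

1. **Pre-window unchanged** — |log FC| across the pre-gastrula window
   (sphere → 50% epiboly by default) at most log(1.25);
2. **Trigger-stage increase** — fold change at the trigger stage (shield,
   ~6 hpf) versus the pre-window end at least 1.5;
3. **Sustained** — the mean at every later stage at least 0.8 of the
   trigger-stage level.

A pseudocount of 0.1 TPM is added before every log or ratio (zeros are
common at early stages).  `significance_mode="replicate_test"` adds a Welch
t test on log2(TPM + 0.1) between the pre-window end and the trigger stage;
an optional Benjamini–Hochberg switch adjusts those p-values across genes
(off by default — the screen is a hard-threshold filter, not a
differential-expression analysis).  Tiering: tier 1 intersects the call
across all explant conditions; tier 2 requires an increase over the same
transition in an intact-embryo series; tier 3 keeps genes with fractional
increase Δ > 0.5 and > 5 TPM at the trigger stage in embryos.  Tiers are
nested by construction.  Gene universes are reconciled by inner join, with
dropped identifiers reported.

Paired-gene ratio trajectories report each gene's fold change relative to
the first stage and the per-stage numerator/denominator ratio of replicate
means, with the peak stage (ties broken to the earliest stage) and the
first up-crossing of ratio 1, linearly interpolated in hpf.

**Operating characteristics.**  On noiseless planted panels the screen's
tier-1 set equals the planted set exactly (verified against a per-gene
brute-force oracle).  Under replicate noise the hard thresholds are
deliberately strict: at CV 0.2 with 3 replicates, the replicate-mean log
fold-change SD (~0.16) makes criterion 1 alone reject ~17% of true triggers
per condition, so sensitivity of the three-condition intersection is
limited (~0.3 in simulation) while specificity stays near 1.  This is the
documented behaviour of threshold screens on noisy fold changes — strict on
false positives, lossy on true positives — and is reported, not hidden, by
`scripts/acceptance.py`.

## Explant shape dynamics

**Roundness** is the moments-based descriptor 4·Area/(π·Major²), where
Major is the major-axis length of the ellipse with the same second central
moments as the segmented region (regionprops); it is 1 for a circle and
equals the minor/major axis ratio for an ellipse.  It is invariant to
rotation and uniform scaling (tested to 0.02 on rasterized ellipses —
discretization, not the descriptor, sets that tolerance).  Polygon input is
supported through exact polygon moments.

**Inclusion rule.**  Only explants whose roundness falls below 0.5 by
12 hpf enter timing analyses, separating changed timing from failed
morphogenesis; series ending before 12 hpf without reaching the cutoff are
flagged indeterminate and excluded.

**Boltzmann fit.**  Roundness curves are fitted with the decreasing sigmoid

    r(t) = Bottom + (Top − Bottom) / (1 + exp((t − V50)/slope)),

slope > 0 meaning decreasing roundness; V50 is the time of half the total
roundness change.  The increasing form is obtained by negating the slope
and swapping asymptotes, and the fitter normalizes any slope-negative
solution back to this convention.  Initialization: Top = max r, Bottom =
min r, V50 = time of the midrange value, slope = range/10; five
multiplicatively jittered restarts; Levenberg–Marquardt with tolerances at
1e-15 (noiseless series round-trip to ≤1e-6 relative error).  Gaps of ≤2
frames are linearly interpolated; longer gaps are dropped from the fit.
Groups pool residuals across their explants with equal frame weights (the
alternative — fitting per-group mean curves — is available by averaging
upstream; pooled points are the default because they keep the residual
degrees of freedom honest).

**Curve comparison** uses the extra sum-of-squares F test between a fit
sharing a chosen parameter subset across groups (null) and fully separate
fits (alternative): F = ((SSE₀−SSE₁)/(df₀−df₁))/(SSE₁/df₁) with p from
F(df₀−df₁, df₁).  The nested SSE is clipped at the free SSE to absorb
solver jitter.  Simulated type-I error at α = 0.05 is within 0.05 ± 0.02
(2000 null replicates at noise SD 0.03, 37 frames per group).

**Extension onset** is automated as a sustained plateau drop: the first
time roundness falls below (1 − 0.05) × the mean of the first 6 frames and
stays below for 3 consecutive frames.  The drop fraction and sustain length
are configuration with these defaults; the automated call stands in for
visual tip-emergence scoring and agrees with the analytic 5%-drop time of a
noiseless sigmoid to within 2 frames.

**Morphometry**: length/width ratio = midline polyline arc length (so
curvature counts) divided by the maximal perpendicular width segment.

## Convergence kinetics

Tracks are 2D (x, y) positions per frame (default 5-min frames), with x the
mediolateral axis and a configured midline position.  Filtering follows the
imaging analysis: observations within 100 μm of the midline are removed
(convergence is reduced there), by observation (default) or by track, and
only maximal runs of ≥3 consecutive frames survive; a track split by the
exclusion band contributes its long-enough fragments separately.

**Signed ML displacement** per step is |x_t − m| − |x_{t+1} − m|, positive
toward the midline on either side — so mirror-image embryos give identical
curves, and translating coordinates together with the midline changes
nothing (both properties are tested).  The per-frame mean over cells (with
SE and n) is smoothed by a trailing sliding window of 4 frames with
shrinking edge windows; centered alignment is available.

**Onset** is a hinge changepoint: a continuous two-segment piecewise-linear
model over a breakpoint grid at frame resolution, against a single line by
an F test with 2 extra parameters (second slope, breakpoint), accepted at
α = 0.05 only when the post-break slope exceeds the pre-break slope.  In
the pipeline summary the hinge is applied to the *cumulative* mean ML
displacement: convergence with roughly constant speed turns that curve from
flat to linearly rising — exactly the hinge alternative — whereas the
per-frame curve steps to a plateau whose post-break slope is ~0 and cannot
pass the slope gate.  `convergence_onset` itself is generic and can be
applied to any curve.  The estimator recovers planted onsets within one
5-min frame in ≥95% of simulations at signal/noise 0.5 (200 cells), and
reports an onset on flat-noise nulls in ≤5% of replicates (both bounds
re-measured by the tests and the acceptance script); a perfectly linear
curve yields no onset by an explicit numerical-degeneracy guard.

**Per-track statistics**: persistence = net displacement / path length
(defined 0 for a zero-length path); straight-line speed = net displacement
/ total tracking time; instantaneous velocity = step length / frame
interval, all in μm and minutes.  Mean instantaneous velocity ≥
straight-line speed for every track (triangle inequality; property-tested).

## Quantification formulas

- **2^−ΔΔCt**: technical-replicate Cts are averaged on the Ct scale
  (arithmetic mean, not of linearized quantities), then ΔCt = Ct_target −
  Ct_reference per sample, ΔΔCt versus the calibrator, fold = 2^−ΔΔCt; the
  calibrator's own fold is 1 by construction.
- **Disaccharides**: amount = (light area / heavy area) × 20 pmol of
  heavy-isotope-tagged standard per species; percent composition over the
  quantifiable species sums to 100; optional normalization per μg protein.
  Codes with zero heavy-channel area are flagged unquantifiable rather than
  dropped silently.  The computation is homogeneous in the light areas:
  scaling them scales the amounts and leaves percents unchanged.
- **Identity/similarity**: global pairwise alignment (Needleman–Wunsch with
  affine gaps via Biopython's PairwiseAligner) under BLOSUM62 with X scored
  0 against everything; gap open 10, extend 0.5, the opening penalty
  including the first gapped position (the alignment score is verified
  against an exhaustive enumeration of all alignments on short sequences).
  Identity = identical columns, similarity = identical-or-positive-scoring
  columns, both over columns where both sequences have residues (default;
  an all-columns denominator is available).  The original comparison used a
  progressive multiple aligner whose effective gap costs differ, so
  percentages are mildly sensitive to the gap parameters — they are exposed
  as options for that reason.

## Synthetic data

The generators produce inputs with the statistical structure each stage
assumes, with known ground truth:

- **Expression**: seven stages (sphere 4.0, dome 4.3, 50% epiboly 5.3,
  shield 6.0, 75% 8.0, 90% 9.0, bud 10.0 hpf — a standard staging grid;
  the first three and shield anchor the screen's criteria) × four
  conditions (three explant series and one embryo series) × 3 replicates.
  Planted triggers are flat then elevated 3-fold from shield on;
  non-triggers mix flat (0.7), monotone-decreasing (0.15, factor 0.7 per
  stage) and late-rising (0.15, elevation starting one stage after shield)
  shapes, chosen to exercise the pre-window and trigger-stage criteria
  respectively.  Baselines are lognormal (log-mean 3.5, log-SD 1.0 →
  median ~33 TPM); replicate noise is mean-preserving multiplicative
  lognormal at CV 0.2.
- **Tracks**: 200 cells on a ±400 μm field, uniform initial positions
  outside a 120 μm midline dead zone, isotropic Gaussian steps (SD 1 μm
  per 5-min frame), a constant 1 μm/frame bias toward the midline from the
  planted onset (8.0 hpf) on, and reflecting field edges (reflection is
  applied only to out-of-bounds moves so zero-noise trajectories are
  exact).
- **Shapes**: Boltzmann roundness decay (Bottom 0.3, Top 0.95, V50 9.0 hpf,
  slope 0.5 hpf, 10-min frames over 6–12 hpf) with additive Gaussian noise
  (SD 0.02) clipped into (0, 1]; optional elliptical masks whose analytic
  roundness b/a equals the series value frame by frame, so a roundness of
  0.5 yields a major axis exactly twice the minor.

One master seed; every entity draws from
`default_rng(SeedSequence(seed, spawn_key=(k,)))` with a documented counter
k, so outputs are bit-identical per seed regardless of generation order.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: segmentation error and mask topology defects;
tracking errors (mislinking, gap closing) and z-projection artifacts;
gradual speed ramps at convergence onset (the simulated bias is a step);
stage-correlated library effects and count-level overdispersion in TPM;
explant-to-explant parameter heterogeneity beyond additive noise.  Results
on real data additionally depend on upstream segmentation and tracking
quality, which this package consumes rather than produces.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 100–500 genes (5–25
planted) for noiseless screen checks and 200 genes × 20 planted × 20 seeds
for noisy operating characteristics; 50 noisy series for V50 recovery and
2000 null replicates for F-test calibration; 100 track simulations (200
cells each) for onset recovery and 1000 flat-curve nulls for the onset
false-positive rate.  These sizes give stable estimates of every reported
rate while keeping a full run to a few minutes.

## Known limitations

- The screen's "unchanged"/"increased" rules are fold-threshold surrogates
  for an unspecified original criterion; reproducing deposited-data
  candidate counts exactly may require iterating criteria against the
  accession metadata.
- The hinge model assumes one onset; biphasic convergence (slow-down late
  in gastrulation) is not modeled.
- Boltzmann fits assume exchangeable residuals when pooling explants within
  a group; strong per-explant asynchrony inflates the apparent slope.
- The aligner is strictly pairwise; multi-sequence comparisons should use a
  dedicated MSA tool and feed the prealigned pair back in.
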