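# Methods

## The problem

A bacterial culture in a controlled bioreactor is perturbed (here, a gas
switch such as CO addition under aerobic or anoxic growth) and sampled for
transcriptomics immediately before the switch and at 2.5, 5, 10, 20, 40 and
80 minutes after it.  Expression values are log2 ratios to the minute-0
sample.  Hundreds of genes respond, driven by a much smaller number of
transcription factors (TFs) whose *activity* — their effectiveness at their
target promoters — is not directly measurable: for redox regulators like
ArcA or FNR, activity changes through phosphorylation or cofactor state, not
through the TF's own transcript.  The pipeline infers those latent activity
profiles from the expression of each TF's regulon, and then compares one
TF's response across two conditions with a coherence statistic.

## Differential-expression bookkeeping

A gene is called responsive at a sampling point when its linear ratio
`2^y` is at least 2.0 or at most 0.5 (both boundaries inclusive).  The
fraction-of-genome-changed summary divides by the genes *measured* at that
timepoint; missing cells propagate as `missing` calls, never as
"unchanged", and never enter a denominator.  Fold changes are taken per
timepoint against the single minute-0 baseline, with no smoothing across
time.  Category summaries report percent up and percent down separately
relative to the category's genes present in the matrix (they need not sum
to 100).

## The activity model

Observed expression is modelled as a linear mixing of TF activities through
regulon connectivity:

    y_gt = mu_g + sum_m X_gm * b_gm * c_mt + eps_gt,   eps_gt ~ N(0, sigma^2)

* `X` — binary genes x TFs connectivity from a RegulonDB/EcoCyc-style edge
  table, restricted to genes present in the expression matrix.  TFs whose
  every target is absent are dropped and reported; TFs with no observed
  target data are flagged `uninformed` and returned at their prior.
* `b_gm` — regulatory strength of TF m on gene g; prior N(0, tau_b^2) with
  tau_b = 1 on the log2 scale, truncated to the half-line matching the
  regulon sign when the edge sign is declared (+ means b >= 0).
* `c_mt` — latent activity; prior a Gaussian random walk over the irregular
  minute grid, innovation sd tau_c * sqrt(dt) with tau_c = 0.5 per
  sqrt-minute, and N(0, 1) on the first point.  The sqrt(dt) scaling
  handles the 2.5-to-40-minute gap spacing without resampling to a regular
  grid.  The pre-treatment point is included and not anchored at zero.
* `mu_g` — per-gene offset, N(0, 10^2); absorbs array-level baseline shifts.
* `sigma^2` — inverse-gamma(2, s^2) with scale s = 0.5, i.e. prior mean
  s^2 on the noise variance, weak in n.

Missing cells are dropped from the likelihood, not imputed.

### Sampling

All full conditionals are Gaussian (activities jointly across TFs per
condition, via the block random-walk + likelihood precision; weights per TF
column with vectorised truncated-normal draws; offsets; conjugate noise
variance), so inference is blocked Gibbs sampling: by default 2 chains,
1,000 burn-in sweeps each, 2,000 retained draws total, seed mandatory.
Split-chain potential scale reduction is reported per TF; values above 1.1
produce a warning, not an error.

Plain Gibbs is not sufficient here, because the likelihood only constrains
the product `b * c` and the model has three indeterminacies that become
slow or multimodal directions:

1. **Scale** — `(b, c) -> (s b, c / s)` per TF.  A Metropolis move proposes
   `s` lognormally around 1 and accepts with the exact prior ratio times
   the Jacobian `s^(k - K T)` (k targets, K conditions, T timepoints); the
   likelihood cancels.
2. **Sign** — with sign-truncated weights the posterior has a spurious
   local mode in which a TF's activity is mirrored and its sign-constrained
   weights collapse onto the zero boundary.  An involutive Metropolis move
   proposes flipping the activity together with the *unsigned* weights
   only; from the spurious mode the likelihood change is tiny and the move
   escapes, from the correct mode it is strongly negative and is rejected.
3. **Level** — a constant shift of one TF's activity absorbed into its
   targets' offsets (`c + delta`, `mu_g - b_g delta`) leaves the likelihood
   unchanged and is priced only by the first-point activity prior and the
   diffuse offset prior.  A joint Metropolis shift move mixes this ridge;
   without it, chains equilibrate at visibly different activity magnitudes
   (split-Rhat 3-4 on profile norms in 40-gene instances).

All three moves leave the posterior invariant; the sampler with weights and
noise clamped reproduces the closed-form Gaussian posterior for the
activities to within Monte-Carlo error (see the conjugate-case check in the
test suite and acceptance script).

### Gauge fixing

`(b, c)` products are invariant under per-TF rescaling, so reported
activities need a convention.  Each draw is normalised by scaling the TF's
weight vector to unit root-mean-square over its targets and pushing the
magnitude into the activity.  Two details matter:

* The RMS is taken over *conditional-mean* (ridge) weights given the drawn
  activities, not over the drawn weights themselves: for targets whose data
  are uninformative the drawn weight sits at the prior scale regardless of
  the data, which lets the raw-weight RMS drift along a nearly flat
  posterior direction; the likelihood-shrunk weights suppress that noise
  and pin the reported magnitude to the fitted signal.
* Normalising the weights (rather than the activities, the other natural
  choice) keeps activity *amplitudes* meaningful: profiles normalised to
  unit RMS would all have identical norms, and the coherence magnitude
  difference would be identically zero by construction.

The sign convention orients each TF so the known-sign weight majority is
positive; if no target sign is declared, so that the data cannot tell the
two orientations apart, the profile is oriented to rise over the course.

### Joint two-condition fitting

The coherence analysis compares activity *magnitudes* between conditions,
which is only meaningful if the two fits share a scale.  When two
conditions use the same regulon, `infer_tf_activities_multi` fits them
jointly: weights are shared across conditions (one regulon, one organism),
activities are condition-specific, and the noise variance is pooled.  The
per-TF scale indeterminacy is then common to both conditions and cancels
exactly from any between-condition comparison.  Fitting each condition
independently leaves the scale split between weights and activities only
prior-identified; in experiments the between-run magnitude spread was a
factor of ~2 — enough to randomise quadrant calls.  The returned posteriors
are draw-aligned: draw i of each condition shares the same weight sample.

## The coherence statistic

For each TF shared by two conditions, on the posterior-mean profiles:

* profile difference `d = 1 - |rho|`, `rho` the Pearson correlation between
  the two profiles (constant profiles yield an explicit `undefined` record
  with reason code, never a silent number);
* magnitude difference `m = | ||a||_2 - ||b||_2 |` (Euclidean norm — the
  default reading of profile magnitude).

95% intervals come from per-pair `d` and `m` over paired posterior draws:
index-aligned pairs for jointly fitted posteriors, randomly paired
otherwise (independent experiments).  A TF whose |rho| interval half-width
exceeds 0.15 is marked omitted but kept in the table; omission affects
plotting and reporting, not storage.  Quadrants: the d-axis splits at 0.5
(midpoint of [0, 1]); the m-axis splits at the median magnitude difference
across non-omitted TFs; both are config-overridable, and boundary values go
to the high side.  TFs near the origin responded alike in both conditions;
the top-right corner differs in both kinetics and amplitude.

## The synthetic-data generator

The generator emulates the study design at desk scale: 200 genes, 10 TFs,
Poisson(20) regulon sizes drawn without replacement, half the edges with a
declared sign, weights ~ N(0, 1) consistent with declared signs and shared
between conditions, noise sd 0.3 on the log2 scale, the 0-80 minute grid.
Activity templates mirror the kinetics of the redox regulators: a transient
pulse (linear rise to the peak, then exponential decay with half-life equal
to the peak time — ArcA-like), a saturating monotone rise (FNR-like) and a
monotone decline (PdhR-like), amplitudes 1.5-3.  Default peak times are
staggered (2.5-40 min) so that no two TFs within a condition have
near-collinear true activities (max pairwise |Pearson| about 0.92): exactly
collinear activity curves make the corresponding TF contributions
unidentifiable for *any* method, which is a property of the scenario, not
of the sampler.  Random streams are split per component (topology, weights,
noise) so changing one leaves the others untouched at a fixed seed.

The designed 3-TF benchmark scenario (60 genes, regulons of ~15) places one
TF with an identical response in both conditions (true d = 0, m = 0), one
with the same kinetics at 3x amplitude (true d = 0, m = 2.7), and one with
weakly correlated kinetics — an early pulse vs. a late, larger pulse (true
d = 0.84, m = 1.3).  With the median rule for the m-threshold, the designed
quadrants are lower-left, upper-left and the right half respectively.

What the generator does *not* emulate: microarray technical structure (dye
bias, probe effects, spatial artifacts), mRNA decay kinetics, TF-TF
interactions or combinatorial promoter logic, and regulon tables with
errors (missing or false edges).  Passing recovery tests on this generator
therefore shows the inference is correct *under its own model family* at
realistic noise, not that real-data regulon annotations are accurate enough
for the same fidelity.

## Problem sizes and numerical choices

The validation experiments run at the scenario sizes above: 10 recovery
replicates of the 200-gene scenario and 20 runs of the 3-TF scenario, each
with 2 chains x (1,000 burn-in + 1,000 retained) sweeps — chosen so the
whole battery completes in minutes on one core while leaving wide margins
on its thresholds.  Other numerical details:

* Truncated-normal draws use inverse-CDF sampling with the uniform clipped
  to [1e-15, 1 - 1e-15] to avoid infinities deep in a tail.
* `d` is clipped to [0, 1] against sub-1e-15 rounding excursions.
* Credible and confidence intervals are central percentile intervals
  (numpy linear interpolation).
* Ties at quadrant thresholds go to the high side, so a TF exactly at the
  d-threshold lands in the right half.
* `write_table` renders floats with 17 significant digits: reruns are
  byte-identical and read-back recovers float64 exactly (pandas is told to
  use its round-trip float parser).

## Known limitations

* Activity level (a constant offset per TF) is only weakly identified by
  design — the data see it through the diffuse per-gene offsets.  The
  posterior honestly reflects this as wider intervals at late timepoints.
* Per-condition independent fits give comparable *shapes* but not
  comparable magnitudes; use the joint fit for coherence work.
* The model is linear in activities; saturating or switch-like promoter
  responses are outside the family and will be approximated by their best
  linear fit.
* Convergence warnings (split-Rhat > 1.1) should be taken seriously for
  magnitude-sensitive downstream use; shapes are typically robust well
  before magnitudes.
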