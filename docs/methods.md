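# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of `dialmet`.

## Study template

A cohort is described by a `StudyDesign`: three arms (sleep-first S6-EW3
with 7 mice; wake-then-sleep EW6-S3 and spontaneous-wake SW6-EW3 with 6
each), two brain regions, 41 fifteen-minute bins per mouse of which the
first five (end of treadmill hour 1 plus hour 2) are the reference window,
and 9 experimental hours of 4 bins each. Hour *h* of a bin is
`(bin − 5) // 4 + 1`; reference bins map to hour 0.

## Preprocessing ladder

Steps run in a fixed order; each consumes the previous step's output.

* **Detection filter.** An analyte is retained in a region iff it has at
  least one non-missing intensity in ≥ `min_mice` (default 3) mice of
  *every* condition. Applied per region, before any transformation.
* **Baseline z-scores.** Per (mouse, region, analyte):
  `z_t = (x_t − mean(ref)) / sd(ref)` with the sample sd (ddof = 1) of the
  non-missing reference bins. Series with < 2 reference values or zero
  reference sd cannot be standardized; they are carried forward as
  all-missing hourly series and recovered by tier-1 imputation (this is how
  wholly missing series are book-kept, rather than silently dropping them).
* **Outlier rule.** Index *i* is flagged iff
  `|z_i| > factor · max_{j≠i} |z_j|` (factor 5). The absolute value makes
  the rule symmetric for analytes that move downward; at most one point per
  series can satisfy it. Flagging runs on the 15-min series *before*
  coarse-graining.
* **Wrong-state exclusion.** A non-reference bin is removed when the
  mouse's observed wake fraction contradicts the scheduled state strictly
  beyond the threshold (default 0.5): sleep scheduled and > 50% awake, or
  wake scheduled and > 50% asleep. The boundary itself (exactly 50%) is
  retained. Reference (treadmill) bins are exempt.
* **Coarse-graining.** Blocks of 4 consecutive post-reference bins average
  into hours; a partial block averages its present members and an hour is
  missing only when all four members are. 36 post-reference bins yield
  exactly 9 hourly points.
* **Imputation.** Tier 1: a series with no observed hours takes, per hour,
  the mean observed z of the other mice in the same (condition, region,
  analyte). Tier 2: remaining gaps take the mean of the `k = 2` nearest
  *originally observed* hours of the same series (ties broken toward the
  earlier hour; one-sided at the edges; a single observed hour is copied).
  Restricting tier-2 neighbours to observed hours prevents imputation
  chains, and makes the operation idempotent. Provenance
  (observed / imputed_tier1 / imputed_tier2) is kept per cell, and an audit
  (counts of dropped series, flagged outliers, discarded bins, imputed
  cells by tier, imputed fraction) accompanies the matrix.

**Who consumes what.** Mixed models and EEG correlations use only
originally *observed* hourly cells: mixed models tolerate missingness by
construction, and tier-1 cells are copies of a condition mean — including
them would count the same evidence several times and demonstrably inflates
the null rejection rate (measured roughly twofold in simulation). The
imputed complete matrix feeds the classifiers (which need a dense epoch ×
feature matrix) and the heatmaps.

## Mixed-effects analysis

Three models per analyte, all fitted by maximum likelihood (statsmodels
MixedLM): ML rather than REML throughout because both the AIC comparison
and the likelihood-ratio test compare models with different fixed effects,
for which REML likelihoods are not comparable.

* *Between-groups*: hours 1–6, condition = arm, both regions pooled with
  region and condition × region fixed-effect candidates.
* *Within-group* (two): hours 1–9 of one arm, condition = scheduled phase
  of the hour (the 6-h segment vs the 3-h segment), time continuous.

**Random effects.** Candidates are a per-series intercept and a per-series
time slope. The grouping unit is the mouse-by-region *series*, not the
mouse: baseline standardization is per series, so each series carries its
own (5-sample) baseline-estimation offset and scale, and treating the mouse
as the unit leaves a per-(mouse, region) offset unmodeled — in simulation
this mis-specification drove the spurious selection of condition × region
effects with extreme p-values. With series grouping the fixed-specification
LRT is approximately calibrated. The slope is dropped when its fitted
variance falls below `v_tol = 1e-6`, its correlation with the intercept
exceeds `c_tol = 0.99` in magnitude, or the extended fit fails to converge;
the intercept is never dropped.

**Response transform.** Identity, log or sqrt — whichever minimizes the
absolute skewness of residuals from a pilot OLS fit on the maximal fixed
design. Because hourly values are z-scores, log and sqrt operate on
min-shifted values (`y − min + 1`); the shift is monotone, so directions
are unaffected.

**Fixed effects.** Minimum AIC (`2k − 2 logLik`, k counting fixed plus
variance parameters) over the hierarchy-respecting subsets of {condition,
time, condition × time, region, condition × region} (interactions require
their main effects). Condition is then forced into the tested "full" model
even if the AIC search dropped it, so the condition test is always defined.

**Inference.** Likelihood-ratio χ² of the full model against the same model
with *every* condition term removed (main effect and interactions), df =
the difference in fixed-parameter count. The result is reported as a
condition × time interaction test when the interaction was selected,
otherwise as a main-effect test. Negative LR statistics beyond 1e-6 trigger
a refit from a different optimizer start; small negatives clamp to zero.
The wake-vs-sleep **direction** is the sign of the model-implied fixed-
effect contrast at the final hour (hour 6 for the between model, hour 9
within), averaged over regions.

**State-specificity verdict.** An analyte is state-specific iff at least
one of the three models rejects at α and the direction agrees across all
three. If any model cannot be fitted the verdict is "undetermined" and the
analyte is excluded from the report.

**Sleep-phase model.** Early sleep (S6 hours 1–3), late sleep (hours 4–6)
and recovery sleep (EW6-S3 hours 7–9), time recoded 1–3 within each window;
fixed effects sleep-phase × time, random intercept per series; the
interaction is tested by a 2-df LRT. Post-hoc, the early-vs-recovery slope
contrast uses an uncorrected Wald z on the fitted interaction coefficient.
Significant interactions are typed: both compared slopes must be negative
(else "other"); Type 1 when the contrast is non-significant, Type 2 when
recovery declines faster, Type 3 when early sleep declines faster. The
sleep-phase response is left untransformed. Reports are per region (the
per-analyte state verdict pools regions; the sleep-phase table does not).

**Calibration.** Under the null generator the fixed-specification LRT
rejects at roughly the nominal rate; the full selection-then-test pathway
is mildly anti-conservative per model (roughly 8–16% at α = 0.05 in
simulation, an intrinsic property of testing an AIC-selected specification
on the same data), and the three-model direction-consistency requirement
brings the end-to-end false-positive rate of the *verdict* down to about
5%.

## Unknown-feature clustering

Two feature observations measure the same unknown analyte when
`|Δmass| < 0.0014` Da and `|Δrt| < 0.3` min (strict inequalities, per
"differed by less than"). The pairwise relation is not transitive; clusters
are its transitive closure — single-linkage connected components —
enumerated exactly with a KD-tree on tolerance-scaled coordinates under the
Chebyshev metric plus a strict re-check of every candidate edge. Cluster
centroids are median mass and retention time (robust to stray tail
features); per-sample intensities of co-clustered features are summed.
Survivors run through the identical preprocessing and three-model pipeline
as known analytes, keyed by centroid in the report.

## Classification

Observation units are mouse-hour epochs (hours 1–6); features are
region-tagged analytes from both regions, from the imputed matrix.

* **PLSDA**: NIPALS PLS2 of centered one-hot labels on centered X, X-score
  deflation, unit-norm weight vectors, mutually orthogonal score vectors.
  Explained-Y sums of squares per component are the deflation decrements.
  VIP_j = sqrt(p · Σ_a SSY_a w_ja² / Σ_a SSY_a); the mean of VIP² equals 1
  identically. Training-set accuracy (argmax of predicted Y) is reported
  alongside cross-validated accuracy, since in-sample PLSDA separation is
  optimistic by construction.
* **Penalized logistic**: multinomial softmax minimizing
  `Σ −log p(y|x) + (1/2C)‖W‖²` (intercepts unpenalized), L-BFGS from a zero
  start, default C = 0.001. Pairwise problems reduce to binomial
  automatically.
* **Cross-validation**: repeated (default 100×) stratified 3-fold over
  *mice* — every epoch of a mouse shares its fold, and standardization
  statistics come from training folds only, so no information leaks from
  held-out mice. The 95% CI is the 2.5/97.5 percentile of the repetition
  accuracies.
* **Permutation test**: condition labels permuted across mice; per
  permutation the CV accuracy is recomputed as the mean of `perm_reps`
  (default 10, vs 100 for the observed statistic — the permutation
  distribution's spread is dominated by label reassignment, not fold
  resampling, and the reduction keeps 1000 permutations tractable);
  p = (1 + #{perm ≥ obs}) / (1 + n). With the uneven 7/6/6 design,
  stratification makes the permuted-label accuracy concentrate at 1/k —
  folds whose training set over-represents a class are exactly the folds
  whose test set under-represents it.

## EEG correlations

Per analyte × region, pooled mouse-hour pairs inside a state window —
2–6 Hz wake activity over the six enforced-wakefulness hours, SWA over the
three recovery-sleep hours, both in the wake-then-sleep arm — correlate the
log-transformed (min-shifted) hourly level with raw band power (Pearson,
two-sided; Pearson is invariant to the band's affine calibration). Records
with fewer than 3 pairs or zero variance are excluded from the family.
Benjamini–Hochberg runs per band across analytes and regions at q = 0.05.
The gamma band (40–100 Hz), which the generator leaves uncoupled, is the
negative control: its pass fraction should track q.

## Synthetic cohort generator

The generator emulates the study design, not any particular dataset.

* **Intensities.** `x = exp(baseline + mouse intercept + drift + ε)`,
  baseline log-level uniform in [4, 8], mouse intercept N(0, 0.3²),
  ε N(0, 0.25²) per 15-min bin. Lognormal intensities make z-scoring
  non-trivial and give the transform-selection step something to do.
* **State drift.** For the (default 11 of 36) state-dependent analytes the
  log-level is an integral of state occupancy: +0.12 per hour awake, −0.12
  per hour asleep (≈ 6 baseline-sd divergence between arms after six hours
  in opposite states — strong, clearly recoverable effects, matching a
  design whose published hits are unambiguous hour-scale trends).
  Depletion analytes (default 3) decline at −0.08 log/h in every state —
  planted to verify the specificity rule excludes monotone-in-time
  analytes. Remaining analytes are flat.
* **Hypnograms.** Reference and treadmill bins are fully awake;
  sleep-opportunity bins draw wake fractions from Beta(2, 9); novel-object
  and spontaneous-wake bins from Beta(12, 2). The beta tails occasionally
  cross 50%, which exercises the wrong-state filter.
* **EEG.** 2–6 Hz log-power = 1 + 0.15 · cumulative-hours-awake + trait
  offset N(0, 0.2²) + N(0, 0.15²): it rises across enforced wakefulness.
  SWA follows a sleep-pressure state (accumulating during wake, decaying
  exponentially during sleep), so it starts high at sleep onset and falls
  across recovery sleep. Gamma is uncoupled noise. Wake-upregulated
  analytes co-vary positively with 2–6 Hz power through the shared
  time-awake integral; one designated analyte loads *negatively* on the
  per-mouse trait offset (strength 3) — mice with higher overall 2–6 Hz
  power carry lower levels. A mouse-level shift is absorbed by the random
  intercept, so this plants a correlation without planting a condition
  effect.
* **Artifacts.** Whole-series missingness is concentrated: three "bad"
  mice in the sleep-first arm lose each series with probability 0.65,
  everyone else 0.04 — at full cohort size this yields about 185 missing
  series with roughly three-quarters contributed by the bad mice,
  emulating a cohort where a few animals' probes underperform. Point
  missingness is 0.5% per cell; 13 outliers are planted at
  1.3 × 5 × max|z| of their series (guaranteeing the flag rule fires),
  only at schedule-consistent bins of intact series.
* **Unknown features.** Cluster centroids are spaced ≥ 0.05 Da apart with
  mass jitter sd 0.00014 (a tenth of the tolerance) and RT jitter sd 0.03;
  per sample each cluster is detected with probability 0.9.

**What the generator does not emulate:** circadian modulation beyond the
arm schedules, probe drift and calibration decay, correlated analyte
modules and pathway structure, heteroscedastic measurement error, REM/NREM
substructure, or realistic effect-size spectra (all planted effects share
one slope). Passing recovery tests therefore demonstrates that the
machinery detects what it is pointed at under the design's noise and
missingness — not that it would enumerate the metabolome of a real
dialysate series.

## Numerical choices

* MixedLM fits try L-BFGS, then Powell, then CG, keeping the best finite
  log-likelihood; non-finite likelihoods (degenerate rays) are rejected;
  an analyte whose models cannot be fitted at all is skipped with a logged
  reason.
* LRT statistics below −1e-6 trigger a Powell refit of the full model;
  residual small negatives clamp to 0. LRT df is the fixed-parameter
  difference.
* Tier-2 imputation ties (equidistant observed hours) resolve toward the
  earlier hour; exact-boundary wake fractions (0.5) are retained by the
  strict wrong-state rule; z-scoring uses ddof = 1.
* NIPALS converges on the score vector to 1e-10; zero-variance feature
  columns are a hard error naming the column.
* Problem sizes in the test suite are scaled (cohorts of 4–10 analytes,
  permutation counts of 60–200, 20-seed recovery runs, 200-replicate
  calibration) so the full suite runs in minutes; the acceptance script
  uses the full 36-analyte cohort with 200 permutations.

## Known limitations

* Post-selection inference: testing an AIC-selected specification on the
  data that selected it inflates per-model type-I error (see Calibration);
  the pipeline reports the verdict-level behavior honestly rather than
  attempting selective-inference corrections.
* No Satterthwaite/Kenward-Roger small-sample df corrections; χ²
  asymptotics at 6–19 mice are approximate.
* The between-groups model pools regions with region fixed effects for the
  per-analyte verdict; the sleep-phase table is per region. Both choices
  are reasonable; results for region-idiosyncratic analytes differ between
  them.
* Tier-1 imputation assumes missing-completely-at-random within condition;
  informative missingness (e.g., concentrations below detection) would
  bias imputed values toward the detected mice.
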