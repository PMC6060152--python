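# dialmet

Analysis pipeline for **brain-microdialysis metabolomics time series across
sleep/wake states**.

In the experimental design this package targets, mice carrying microdialysis
probes in two cortical regions (medial prefrontal cortex, mPFC, and primary
motor cortex, M1) are sampled every 15 minutes for about ten hours (41 bins).
After a two-hour treadmill period — five bins of which form the per-mouse
reference window — three arms follow different schedules: six hours of
spontaneous sleep then three hours of enforced wakefulness (S6-EW3, n = 7),
six hours of enforced wakefulness then three hours of recovery sleep
(EW6-S3, n = 6), and six hours of spontaneous dark-phase wakefulness then
three hours on the treadmill (SW6-EW3, n = 6). The question is which
extracellular metabolites track behavioral state rather than time of day or
the method of keeping mice awake.

`dialmet` implements the full analysis chain:

1. **Preprocessing** — detection filter (analyte kept only if observed in
   ≥ 3 mice per condition, per region), baseline z-scoring
   `z_t = (x_t − μ_ref)/σ_ref` per (mouse, region, analyte), a 5× outlier
   rule (`|z_i| > 5·max_{j≠i}|z_j|`), removal of 15-min bins whose observed
   state contradicts the schedule by more than 50%, coarse-graining of 4
   bins into hourly values, and two-tier imputation (condition-mean for
   wholly missing series, k = 2 nearest-hour averaging for point gaps).
2. **Unknown-feature clustering** — untargeted LC-MS spectral features are
   merged into putative analytes when masses differ by < 0.0014 Da and
   retention times by < 0.3 min (single-linkage closure), then run through
   the same pipeline as known metabolites.
3. **Mixed-effects state testing** — per analyte, three linear mixed models
   `Y_it = β₀ + b_i0 + Σ β_p X_itp + Σ b_iq Z_itq + ε_it`
   (between-groups over hours 1–6; two within-group models over hours 1–9),
   with log/sqrt response transforms where residual symmetry requires,
   random-effect reduction (intercept + time slope, slope dropped when its
   variance collapses or correlates perfectly), AIC selection over
   hierarchy-respecting fixed-effect sets, and a likelihood-ratio test of
   condition. An analyte is called **state-specific** when at least one
   model rejects at α = 0.05 and the wake-vs-sleep direction agrees across
   all three.
4. **Sleep-decline typing** — an additional model contrasts decline slopes
   in early sleep, late sleep and recovery sleep and classifies significant
   interactions as Type 1 (equal declines), Type 2 (recovery faster) or
   Type 3 (early faster), with "other" for non-declining patterns.
5. **Classification** — PLS discriminant analysis (NIPALS) with VIP scores,
   and an ℓ2-penalized multinomial logistic classifier (C = 0.001) assessed
   by 100× repeated stratified 3-fold cross-validation over *mice* (no
   epoch leakage) with percentile confidence intervals and mouse-level
   label-permutation tests.
6. **EEG correlation** — Pearson correlation of log-transformed metabolite
   levels with 2–6 Hz wake activity (enforced-wakefulness window) and slow
   wave activity (recovery-sleep window), Benjamini–Hochberg corrected,
   with a gamma-band negative control.

Because no public dataset accompanies this design, the package ships a
first-class **synthetic cohort generator** (`dialmet.simulate`) producing
study-shaped tables with known ground truth: lognormal intensities whose
log-levels drift up per hour awake and down per hour asleep for planted
state-dependent analytes, depletion analytes declining in every state,
concentrated whole-series missingness, guaranteed-flaggable outliers,
jittered unknown-feature clusters, and homeostatically coupled EEG band
trajectories.

## Worked example

```bash
dialmet simulate --seed 1 --out cohort/
dialmet lme --samples cohort/samples.tsv --wake cohort/wake.tsv --out run/
```

The second command prints

```
13 state-specific of 36 analytes
```

and writes `run/state_specificity.tsv`, with rows such as

```
analyte  p_between  p_within_sew  p_within_ews  direction     state_specific
A01      2.48e-07   9.60e-08      4.12e-07      wake_higher   True
A12      0.266      0.062         0.194         inconsistent  False
```

The seed-1 cohort plants 11 wake-upregulated analytes (A01–A11), 3
depletion analytes (A12–A14) and 22 with no state effect. `A01` is a
planted wake-upregulated analyte: all three models agree its levels are
higher after wakefulness, so it is called state-specific. `A12` is a
planted depletion analyte — its levels fall over time in every arm, so it
shows no consistent condition effect and is correctly rejected; the 13
calls comprise all 11 planted analytes plus two borderline false
positives, consistent with the verdict's measured ~5% null rate. The same
library calls are available in Python:

```python
import dialmet as dm

table, wake, band, truth = dm.simulate_cohort(dm.GeneratorParams(seed=1))
zm = dm.preprocess(table, wake, dm.default_design())
report = dm.state_specificity_report(zm, dm.default_design())
```

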