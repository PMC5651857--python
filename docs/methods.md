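# Methods

## The procedure

`seromir` implements a four-stage serum-miRNA biomarker workflow for
acute type A aortic dissection (AAAD), stratified by hypertension (HPT).

1. **Array screen** (`seromir.screening`). Pooled serum from each of the
   four groups (HPT−/AAAD−, HPT+/AAAD−, HPT−/AAAD+, HPT+/AAAD+) yields
   one expression value per assay per group. A candidate must show a
   fold change ≥ 2 (or ≤ 1/2) in three comparisons — HPT+/AAAD+ vs the
   AAAD− reference, HPT−/AAAD+ vs the AAAD− reference, and HPT+/AAAD+
   vs HPT+/AAAD− — with all three on the same side of 1. The AAAD−
   reference is the equal-weight mean of the two AAAD− pools; assays
   undetected in any group are excluded, since a ratio against a
   detection-ceiling value is meaningless. Group-profile similarity is
   summarized by the squared Pearson correlation over assays detected
   in both groups, computed on the log2 scale.

2. **Quantification** (`seromir.qpcr`). Triplicate Ct values are
   averaged arithmetically per (sample, assay); relative expression is
   2^−(Ct − Ct_spike-in) against an external spike-in (default id
   `MIR2911`), which absorbs per-sample technical variation. Undetected
   cells keep their ceiling-derived value with a `detected = False`
   flag: they count in the denominator of the detection rate but are
   excluded from group statistics (imputing at the ceiling would bias
   fold changes). No replicate-outlier rejection is applied.

3. **Confirmation** (`seromir.diffexp`). A candidate survives when, in
   every training/validation phase available: its detection rate is
   ≥ 0.75; the overall AAAD+ vs AAAD− two-sided t-test has raw
   p < 0.05; and the parallel-trend requirement holds — the same three
   group contrasts as the screen, now computed from per-sample group
   means, all move in the screen's direction. The HPT+ stratum t-test
   (HPT+/AAAD+ vs HPT+/AAAD−) is reported alongside. Because relative
   expression is log-normal by construction, t-tests run on log2
   expression; reported fold changes are geometric means. Student's
   pooled-variance test is the default (it reproduces published
   demographics-table p values more closely than Welch, which remains
   available behind a flag). Benjamini–Hochberg-adjusted p values are
   reported per phase and contrast, but filtering uses raw p.

4. **Risk score** (`seromir.risk`, `seromir.roc`). Surviving markers
   are binarized against reference-interval limits estimated on
   training controls: the empirical 5% quantile for down-regulated
   markers (indicator fires below it), the 95% quantile for
   up-regulated markers (indicator fires above it). Weights are the
   univariate logistic slopes of status on each indicator — computed in
   closed form as the log odds-ratio of the 2×2 table, with a
   Haldane–Anscombe 0.5-cell correction (and a flag) under separation.
   The raw score rsf = Σ W·S is mapped to a percentage by a logistic
   calibration fitted on the training phase, and the decision cutoff is
   the percentage maximizing sensitivity + specificity on the training
   ROC sweep. Classification is strict: positive iff percentage >
   cutoff. Two frozen model instances are first-class: the all-comers
   model (trained on the training phase) and an HPT+-stratum model
   refit on the hypertensive subset of the pooled training + validation
   samples, used for the blind and retrospective phases.

## The synthetic cohort generator

`seromir.synthetic` emulates the statistical structure the analysis
assumes, so every stage is testable without patient data.

* **Noise model.** Gaussian on the Ct scale: per-(sample, assay)
  biological noise (SD 1.5 cycles) around a common baseline (mean Ct
  30), with replicate noise (SD 0.25 cycles) nested inside. On the
  expression scale this is log-normal with nested technical error, the
  standard qPCR error structure.
* **Planted markers.** miR-25, miR-29a, miR-155 up-regulated and
  miR-26b down-regulated in AAAD+ samples, default |log2 fold change|
  3.75 cycles. With the 1.5-cycle between-sample SD this separates the
  groups by d = 2.5, so an indicator at the 95% control limit flags
  about 80% of cases — calibrated so the *panel-level* training
  operating point reaches ≈96% sensitivity at ≈100% specificity, the
  behavior of the strong published panels this workflow targets. The
  implied single-marker AUC is ≈0.96, somewhat above the 0.86–0.92
  typically printed for individual markers: under a single-component
  Gaussian noise model the panel operating point and the per-marker
  AUCs cannot both be matched, and the panel behavior was chosen as the
  binding constraint. Eighteen null miRNAs accompany the markers, so a
  fully screened candidate set has 22 members.
* **Detection.** Assays fail per (sample, assay) with probability 0.02
  (dropout) and are recorded at the detection ceiling (Ct 40) with
  `detected = False`, never as missing rows — this keeps the table
  rectangular and the 75% detection filter well defined. The spike-in
  (mean Ct 22, SD 0.5) varies per sample but is independent of group
  and never drops out.
* **Array pools.** One synthetic value per group per assay (not an
  average of per-sample draws): a per-assay base level (log2 SD 1.5)
  plus pool-level technical noise (log2 SD 0.1) plus the planted effect
  in AAAD+ pools. 313 of 760 assays are detectable, the detected
  fraction typical of serum profiling runs. The pool noise is small
  enough that planted effects of |log2FC| ≥ 1.5 survive all screen
  criteria in ≥95% of seeds.
* **Cohort sizes.** Defaults mirror the per-phase counts of the study
  design emulated: training 25 AAAD+ / 30 AAAD− (15/15 hypertensive),
  validation 64/58 (44 HPT+/AAAD+, 29 HPT+/AAAD−), blind 15/15 (all
  hypertensive), retrospective 4/10 (all hypertensive). The published
  cohort tallies are internally inconsistent between sections (e.g. 89
  vs 64 validation cases); the counts reported alongside each result
  were used.
* **Determinism.** All output is a pure function of (design, seed); the
  per-phase stream is derived from the seed and the phase label, so
  phases are independent but reproducible.

What the generator does **not** emulate: demographic covariates related
to outcome, hemolysis and other pre-analytic artifacts, batch effects
between phases, correlated marker co-regulation, amplification-
efficiency differences between assays, and heavy-tailed or skewed Ct
noise. Passing tests therefore demonstrate correctness of the analysis
machinery under its stated assumptions, not clinical performance on
real serum.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `alpha` | 0.05 | — | confirmation significance on raw p (the stricter 0.01 sometimes quoted for such studies is configurable) |
| `alpha_ref` | 0.05 | — | reference-interval tail mass (5%/95% limits) |
| `fc_threshold` | 2.0 | ratio | array-screen fold-change criterion |
| `min_detection` | 0.75 | fraction | detection-rate floor |
| `min_controls` | 10 | samples | floor for estimating a reference limit |
| `n_boot` | 2000 (function) / 500 (pipeline) | replicates | stratified bootstrap for the AUC CI; the pipeline default keeps a full study under a few seconds |
| `indicator_rule` | `direction_aware` | — | `lower_tail` reproduces the literal lower-limit-only rule for audit; it cannot flag up-regulated markers and yields chance-level panels |
| `baseline_ct_sd` | 1.5 | cycles | between-sample biological noise |
| `replicate_sd` | 0.25 | cycles | within-triplicate technical noise |
| `detection_ceiling` | 40 | cycles | Ct at/above which an assay is undetected |

## Numerical choices

* Quantiles interpolate linearly between order statistics
  (`numpy.quantile`, `method="linear"`); the method is recorded in the
  serialized model.
* Indicators and classification use strict inequalities; a value
  exactly at a limit or cutoff is negative.
* ROC thresholds sweep the unique score values plus a −∞ sentinel;
  prediction is strict (score > threshold), matching classification.
  AUC is the trapezoidal area, identical to the Mann–Whitney
  probability with ties half-credited. Cutoff ties are broken toward
  higher specificity, then higher threshold.
* The AUC confidence interval is a class-stratified percentile
  bootstrap (2.5/97.5), seeded; no analytic (DeLong) interval is
  provided.
* Separation in a weight fit uses the Haldane–Anscombe correction
  rather than an iterative penalized fit: deterministic and exactly
  reproducible.
* The percentage calibration is a mildly ridge-penalized logistic
  regression (intercept unpenalized), so the map stays finite when the
  training scores separate the classes perfectly — common with strong
  markers. A negative fitted slope (anti-predictive scores) warns and
  falls back to the identity map.
* Undetected expression cells (ceiling-derived, very small values) do
  enter indicator evaluation; for a down-regulated marker an undetected
  cell fires the indicator, which is the biologically intended reading
  of "not amplifiable".

## Open design choices

* The score-to-percentage map is not uniquely determined by the
  published cutoffs (46.50%, 36.89% are percentages, but the transform
  behind them is never defined); any monotone map preserves ROC and
  ranking behavior, which is the only contract asserted. The logistic
  calibration was chosen as the simplest monotone probability map.
* Whether the hypertensive-stratum analysis refits weights and limits
  is not documented in this study family; refitting on the HPT+
  training + validation pool is the default and can be disabled
  (`refit_hpt_stratum=False`).
* Panel membership is a two-phase decision (a candidate must confirm in
  training *and* validation when both are supplied), which is what
  drives the null false-discovery protection; all numeric model
  parameters — limits, weights, calibration, cutoff — are functions of
  training-phase samples only.

## Problem sizes

The test suite and acceptance script use the default cohort sizes
throughout; seeded replication counts are 100 seeds for the end-to-end
recovery and null-design properties (25 in the acceptance script),
1000 replicates for type-I calibration of the t-test, and 60 replicates
for bootstrap-CI coverage. The full suite runs in well under a minute
on one CPU.

## Known limitations

* Fold changes at the array phase come from single pooled values; no
  variance estimate exists there, so no test statistic is computed at
  screening.
* The per-marker ROC cutoffs in reports are on the oriented
  relative-expression scale (down-regulated markers negated); the scale
  is recorded in the output.
* The generator's marker strength is calibrated to panel-level
  behavior, making single-marker AUCs optimistic relative to typical
  published values (see above).
* Real serum studies contend with normalizer instability; here the
  spike-in is group-neutral by construction, so normalization can only
  remove noise, never introduce bias.
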