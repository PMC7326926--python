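# Methods

## Scope and model

`aquascore` quantifies tumor-specific marker expression from multiplex IF
and links it to survival. The pipeline has four stages — synthetic data
generation, segmentation/quantification, scoring, cohort statistics — and
every stochastic step takes an explicit seed; there is no global random
state, and identical configurations produce bit-identical outputs.

## Synthetic image generator

Cells are concentric disks: a nucleus of radius *r* ~ Normal(6, 1) px
(clipped to mean ± 2 sd), a cytoplasm annulus of width 3 px and a membrane
annulus of width 2 px. Centers are placed by rejection sampling with a
minimum separation that covers two maximal outer radii plus a 1-px guard
band, so cells never overlap and segmentation ground truth is unambiguous;
exceeding the feasible density raises a placement error that reports the
requested density. Default core: 512×512 px, 50 tumor cells, 20 T cells.

Marker intensities are lognormal per phenotype, constant across a cell's
compartment (the drawn value is exactly the cell's true mean, which makes
the truth table an exact oracle):

| marker | compartment | tumor (μ, σ) | T cell (μ, σ) |
|---|---|---|---|
| DAPI | nucleus | (ln 100, 0.3) | (ln 100, 0.3) |
| CD20 | membrane | (ln 60, 0.4) | — |
| CD3 | cytoplasm | — | (ln 60, 0.4) |
| BCL2 | cytoplasm | (2.4428, 1.2691) | (ln 6, 0.9) |
| MYC | nucleus | (ln 9, 1.0) | — |

The tumor BCL2 parameters are solved from a target median of 11.5 and
mean of 25.7 on the raw intensity scale (median = e^μ,
mean = e^{μ+σ²/2}), reproducing the strong right skew of per-cell BCL2 in
DLBCL tumors. T cells express BCL2 at a lower level — the fraction of T
cells per core and their BCL2 level are not empirically constrained, so
both are configurable defaults, not claims about any real cohort.
Additive Gaussian noise (sd 0.5 raw units) is applied last and clipped at
zero.

What the generator does **not** emulate: spectral unmixing artifacts,
autofluorescence, tissue texture, non-circular or overlapping cells, and
staining gradients. Passing tests therefore demonstrate correctness of the
quantification and statistics on resolvable, geometrically clean input —
not robustness to the segmentation failure modes of real tissue.

## Synthetic cohort generator

Survival follows an exponential proportional-hazards model: patient *i*
has event rate `baseline_hazard · exp(lp_i)` with
`lp = log(2)·highBCL2 + log(1.5)·highMYC + log(2)·highIPI` by default.
High-BCL2 prevalence defaults to 0.389 and high-MYC to 0.249, matching a
typical R-CHOP-treated training cohort; covariate marginals likewise.
Censoring is independent exponential (0.006/month) capped at 120 months of
accrual; with the 0.004/month baseline hazard this gives whole-cohort
5-year OS in the low 60s % — the range typical of R-CHOP-treated DLBCL. Event-free survival adds an independent
progression process with the same linear predictor, so EFS time never
exceeds OS time.

Observed scores are the true group-specific scores (low ~ N(30, 7),
high ~ N(55, 8) for BCL2 on a 0–100-like scale) distorted by per-batch
affine effects (site shift and scale) — exactly the structure the
two-stage adjustment removes. The conventional percentage is driven by the
proportion of expressing cells alone, drawn independently of the intensity
group, which recreates the clinically important discordance: a patient can
be conventional-high yet truly low-risk.

## Segmentation and quantification

* **Normalization**: each channel is divided by its maximum over all
  cores analysed together (batch max), not per core — per-core scaling
  would erase between-core intensity differences that the AQUA score must
  preserve. All-zero channels pass through.
* **Detection**: Otsu threshold on DAPI (overridable), Euclidean distance
  transform, peaks at least `min_radius_px` apart as watershed seeds,
  equivalent-radius filter 3–12 px, labels dense from 1.
* **Compartments**: cytoplasm and membrane rings of configured width,
  truncated by a nearest-nucleus partition. Contested equidistant pixels
  go to the lower cell label, implemented by running the distance
  transform twice (once with label order reversed) and taking the minimum
  label where the assignments disagree. Nucleus, cytoplasm and membrane
  pixels of a cell are disjoint; non-background pixels belong to exactly
  one cell.
* **Quantification**: per (cell, marker, compartment) intensity sums and
  pixel areas via composite-bin `bincount`; means are sums over areas.

## Scoring conventions

* Gating: tumor iff membrane CD20 mean ≥ 0.05 **and** cytoplasm CD3
  mean < 0.05; CD3 at/above threshold always wins (a double-positive cell
  is called a T cell — conservative for tumor specificity).
* AQUA pooling is pixel-area-weighted across all of a patient's tumor
  cells (cores pooled), equivalent to the area-weighted mean of per-cell
  means — not a mean of per-core scores.
* Quantiles (positivity threshold, quantile groups) use linear
  interpolation between order statistics.
* All positivity/grouping comparisons use ≥: a value exactly at a
  threshold or cutoff is positive/high; the conventional call is positive
  at exactly 50%.
* H-score percentages are taken over all cells, bin-0 included in the
  denominator; normalization to 0–100 uses the theoretical maximum 300 for
  H-scores and cohort min–max for AQUA scores (a constant vector maps to
  zeros with a warning).
* QC: patients with fewer than 20 gated tumor cells are flagged and
  excluded from cutoff derivation and survival analysis (configurable).
  No published floor exists; 20 cells keeps the per-patient score sd below
  ~1/4 of the between-group separation under the default intensity model.

## Cohort statistics

* **Batch adjustment**: stage 1 removes per-batch means (grand mean
  restored); stage 2 scales each batch's centered residuals to the pooled
  sd. Affine per batch with positive slope, so within-batch ranks are
  preserved. Batches of size 1 (or zero variance) are errors.
* **ROC cutoff**: every observed score is a candidate threshold
  (rule: score ≥ t is positive); Youden's J is maximized with ties broken
  toward the lower cutoff, computed on the integer numerator
  `TP·N_neg + TN·N_pos` so floating-point rounding cannot flip a tie.
  AUROC is the trapezoid under the empirical staircase. The binary
  endpoint is a design choice recorded in the result: death within 5 years
  among patients evaluable at 5 years (OS), or any event within 2 years
  (EFS).
* **Survival**: Kaplan–Meier, k-group log-rank and Cox models are fitted
  with lifelines; Cox uses Efron tie handling. Univariate fits run each
  covariate in its own model; the default multivariate model uses BCL2
  group, MYC group, IPI group and cell-of-origin (patients with unknown
  COO are dropped from that model only).
* **PH diagnostic**: per-group log(−log S) vs log t curves; the
  parallelism summary is the sd of between-group vertical gaps on a common
  log-time grid restricted to where every curve has survival in
  [0.05, 0.95] — outside that band KM tails are too noisy to judge
  parallelism. Groups without events are omitted with a note.
* No multiple-testing correction is applied anywhere; subgroup p-values
  are descriptive.

## Problem sizes

The test suite and the acceptance script scale the study down to what the
properties need: oracle equivalence uses 50 small cores (128² px);
segmentation fidelity 10 default cores; tumor-specificity 100 cores at
256² px with T-cell BCL2 raised to make contamination material; Cox
recovery 200 cohorts of n = 300 at ~30% censoring; log-rank calibration
1000 null cohorts of n = 200; the end-to-end study 50 runs of n = 300
(cohort stages only; the image stages are exercised separately). The
acceptance script uses 5 cores, one n = 300 study and 50 Cox-recovery
replicates.

## Known limitations

Disk-shaped, non-overlapping cells make segmentation far easier than real
tissue; the batch model is affine only; the exponential survival model has
no time-varying effects, so the PH diagnostic is validated only against
constructed violations; the positivity threshold's [0, 1] domain assumes
normalized intensities and rejects raw-scale inputs by design.
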