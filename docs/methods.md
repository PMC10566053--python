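# Methods

## The problem and the model

Men with elevated PSA are routinely referred to prostate biopsy, yet a
large fraction of those biopsies find benign tissue or clinically
insignificant disease. The pipeline implemented here builds urine
metabolite panels that predict, before biopsy, which NCCN risk category
a man's eventual diagnosis will fall into, and quantifies the clinical
value of acting on those predictions.

Every predictive model is a binary logistic regression
logit P(y = 1 | x) = β₀ + βᵀx, fitted by maximum likelihood. Four
endpoints dichotomise the ordered NCCN strata (benign, VLR, LR, FIR,
UIR, HR, VHR, mPC):

| model | negative class | positive class |
|---|---|---|
| I | benign | any cancer |
| II | benign, VLR/LR | FIR … mPC |
| III | benign, VLR/LR, FIR | UIR … mPC |
| GS | benign, Gleason sum < 7 | Gleason sum ≥ 7 |

Models II and III correspond to "significant cancer" for men with long
and shorter life expectancy respectively; Model GS exists for
comparability with grade-based studies.

## Preprocessing

Raw GC–MS peak tables are sparse and scale-inconsistent across runs.
The pipeline applies, in this fixed order:

1. **Presence filter** — keep a feature iff it is observed in *strictly
   more than* `presence_threshold` (default 0.60) of the samples of at
   least one risk stratum. The filter runs on the pooled cohort before
   the training/validation split, since it models acquisition-time QC,
   not outcome-dependent screening. Strata are the six merged analysis
   groups (benign, VLR/LR, FIR, UIR, HR/VHR, mPC).
2. **Normalization** — default `sequential`: divide by the sample's
   total observed peak area, then by urinary creatinine. Both correct
   urine dilution/batch scale; the single modes are selectable because
   the combination of "both" corrections admits more than one reading.
3. **Imputation** — remaining missing cells become half the feature's
   minimum observed normalized value, the standard detection-limit
   surrogate in metabolomics. Selectable off.
4. **log** — natural log, so planted/biological effects are additive
   and multiplicative MS noise becomes roughly Gaussian.

Whether the original analysis log-transformed before regression is not
documented; the log default is the field convention and is
config-switchable.

## Marker selection

The selection engine controls selection instability by resampling:
`rounds` × `k_folds` stratified fold assignments (defaults 20 × 5 = 100
fold-models; folds are stratified by outcome and reshuffled every
round). Per fold-training set:

1. univariate logistic screen at Wald p ≤ 0.1 (a ridge-rescued,
   i.e. separated, fit is kept outright — separation is maximal signal);
2. greedy backward elimination on the AIC: repeatedly remove the single
   feature whose removal lowers the AIC most, stop at a local minimum
   (the intercept-only model is a legal endpoint);
3. multivariable pruning: iteratively drop the worst feature with joint
   Wald p > 0.1.

If the screened set exceeds n/10 features it is pre-truncated to the
best n/10 by univariate p before elimination, keeping the IRLS
well-posed; the event is logged.

Each fold-model is scored by AUC on its held-out fold. The best
⌈75 %⌉ of fold-models by held-out AUC vote with their retained sets;
features are ordered by recurrence count, ties broken by mean
univariate p (ascending) then feature id, so output is deterministic.
The ranking statistic for "best models" is not documented in the
original description; held-out AUC is the default here and training AIC
is available via config.

Finally the top `top_n_recurring` (default 30) features enter nested
logistic fits (top-1, top-2, …) on the full training cohort; the panel
size is the argmin of this cumulative AIC sequence (ties → smaller
panel). Running the nadir search on the full training cohort (rather
than within folds) is a design choice; the alternative is not exposed.

## The logistic engine

IRLS (Newton) with step-halving, gradient tolerance 1e-8, 100
iterations. On non-convergence or quasi-complete separation (detected
as |β| ≥ 30, where probabilities saturate) the model is refit with a
ridge penalty of 1e-4 on slopes only — never the intercept — and
flagged `converged=False`. This keeps screening loops total: every
candidate model gets a finite AIC. Firth's correction would be the
more principled rescue; ridge was chosen for simplicity and is recorded
in the fit provenance. Wald standard errors come from the final
(penalised, when applicable) information matrix. AIC = 2k − 2 ln L with
k counting all estimated coefficients including the intercept.

Combined models (panel + age, PSA, family history, previous negative
biopsy, abnormal DRE) refit all coefficients jointly rather than
appending clinical factors to a frozen panel score; the original
procedure is not documented, and joint refitting is the reading
consistent with reporting a single combined AUC. PSA enters
untransformed by default.

## Evaluation

* **ROC/AUC** — tie-corrected concordance (ties ½); curve thresholds
  are the observed scores; positive ⇔ score ≥ threshold.
* **DeLong** — placement-value decomposition for the AUC variance,
  paired covariance for model comparisons, two-sided normal p. A zero
  variance of the difference returns p = 1 when ΔAUC = 0, else p = 0
  (flagged degenerate by the ±∞ z).
* **Operating points** — Youden's J maximiser (ties → higher
  specificity) and the highest threshold reaching each target
  sensitivity (0.90, 0.95), with sensitivity, specificity, NPV, PPV and
  accuracy from the 2×2 table at that threshold.
* **Biopsies avoided** — the observed cohorts over-represent cancer, so
  raw specificity overstates population-level benefit. The avoided
  share is reweighted to the enrollment composition w =
  (0.520, 0.087, 0.074, 0.110, 0.183, 0.026):
  avoided = Σ_g w_g · #{endpoint-negative & test-negative in g} / n_g.
  For strata that are entirely endpoint-negative this is w_g ×
  specificity (0.520 × 0.92 ≈ 48 % for a benign-only negative class);
  for mixed strata (Model GS) each stratum's weight contributes through
  its observed negative fraction.
* **Cohort comparisons** — uncorrected Pearson chi-square (the
  continuity-corrected variant does not reproduce the published
  cohort-comparison p-values; the uncorrected one does, to 4 decimals)
  and the Mann–Whitney U normal approximation with tie and continuity
  corrections.
* **Decision curves** — net benefit NB = TP/n − (FP/n)·p_t/(1−p_t)
  over p_t ∈ {0.01, …, 0.50}; references are biopsy-for-all
  (π − (1−π)p_t/(1−p_t), crossing zero at p_t = π) and biopsy-for-none
  (0); biopsies avoided per 1,000 = 1000·(NB_model − NB_all)·(1−p_t)/p_t.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes; its
defaults are the study conditions.

* **Cohorts** — training 603 (110/74/74/105/202/38 across
  benign/VLR-LR/FIR/UIR/HR-VHR/mPC) and validation 325
  (158/26/25/34/66/16): the validation cohort restores the
  benign-heavy enrollment composition. VLR/LR and HR/VHR are generated
  as merged strata and split into individual labels at random,
  mirroring the demographic-table row structure.
* **PSA** — log-normal per stratum with severity-increasing location
  (medians ≈ 7 → 45 ng/mL from benign to mPC), so clinical models carry
  real signal and combined models beat panel-only models.
* **Clinical factors** — per-stratum Bernoulli rates; abnormal DRE
  rises from 0.20 (benign) to 0.60 (mPC), previous negative biopsy
  falls with severity, family history is nearly flat.
* **Peak areas** — log-normal per feature (log-mean ~N(10, 1.5), log-SD
  ~U(0.4, 1.0)) times a per-sample dilution/loading factor shared with
  creatinine. Planted effects are additive on the log scale in units of
  the feature's log-SD.
* **Planted markers** — default 20 markers at 1.25 log-SD, alternating
  a flat suppression in all cancer strata (the "down in cancer"
  profile) and a severity ramp (0 / 0.35 / 0.6 / 0.8 / 1.0 / 1.0, the
  "up in significant cancer" profile). These defaults were fixed once
  so that on validation the panel AUC (≈0.87–0.94) exceeds the
  clinical-factor AUC and the combined model tops both — the
  qualitative ordering the real study reports.
* **Missingness** — a fixed-size "reliably detected" feature subset
  (8.8 % of features, always containing planted markers) has missing
  rates U(0.02, 0.25); the rest sit near `missing_rate_base` (0.75).
  Within a feature, the missing probability falls with the sample's
  latent standardized intensity (detection limit acts on the actual
  abundance, planted shifts included). With 1,941 raw features this
  yields ≈170 features surviving the 60 % presence filter, matching
  the study's scale.
* **Creatinine** — the loading factor times log-normal noise (scale
  0.25 around 1.0); no published distribution exists to calibrate
  against, so these values are plausible rather than calibrated.

What the generator does **not** emulate: chromatographic retention or
spectral structure, batch effects beyond total-area scale, correlated
metabolite blocks, and non-random missingness tied to clinical
variables. Passing tests therefore demonstrate that the machinery is
correct and calibrated under the assumed data model, not that the
published AUCs would reproduce on real patients — the patient-level
data are not public, and the published headline AUCs are not
desk-reproducible.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the pipeline at full default size (928
subjects, 1,941 features, 4 endpoints × 100 fold-models; ≈2–3 minutes
on one CPU). Calibration suites run a reduced design chosen to keep the
statistics honest at manageable cost: 150 raw features (≈65 after
filtering), the full 603/325 cohort split, 15 fold-models per run, and
40 generator seeds for each of the null and planted conditions. The
planted condition uses exactly 10 markers at 0.9 log-SD flat across
cancer strata. At very small feature counts (≲50) total-peak-area
normalization itself injects sample-level noise (the total is dominated
by a few log-normal features), so reduced designs keep ≥150 features.

## Known limitations

* Ridge rescue instead of Firth for separation; Wald inference near
  separation is unreliable (mitigated by treating rescued univariate
  fits as "keep" decisions rather than trusting their p-values).
* AIC backward elimination retains a pure-noise predictor with
  probability ≈ P(χ²₁ > 2) ≈ 0.16 by construction; the ensemble's
  recurrence ranking, not any single fold-model, is what suppresses
  noise.
* Half-minimum imputation distorts feature variances when missingness
  is heavy; this is faithful to field practice, not optimal statistics.
* The biopsy-avoidance reweighting assumes the enrollment composition
  is the deployment population.
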