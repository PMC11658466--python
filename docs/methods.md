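# Methods

`panelforge` implements a discovery pipeline for serum-protein biomarker
panels of the kind produced by ~1.3K-plex aptamer assays (SOMAScan-style
RFU matrices): three complementary rankers nominate proteins, their
intersection defines a core panel, and a repeated-split logistic
evaluation decides which remaining candidates add predictive value.
This note records the model, the defaults and why they were chosen, what
the synthetic cohort generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Pipeline

1. **QC filter** — analytes flagged as failing assay quality control are
   dropped, as are blinded technical duplicate samples (re-measurements
   linked by `duplicate_of`), so all discovery statistics see unique
   subjects only.
2. **Normalization** — `z = clip(zscore(log10(RFU)), −3, 3)` per analyte,
   with the z-score computed across all retained samples (both groups
   pooled). Clipping bounds outlier leverage; it is idempotent and
   rank-preserving except among clipped ties, and the transform is
   invariant to positive rescaling of an analyte.
3. **Ranking** — three top-*k* lists (*k* = 10 by default):
   - *Random forest*: a classifier of group on all analytes is fit
     `n_repeats` times (default 100) with seeds `seed + r`; each analyte's
     mean decrease in Gini impurity is averaged over repeats and the top
     *k* by averaged importance are kept.
   - *t-test*: per-analyte Welch test of case vs control on the
     normalized values, Benjamini–Hochberg FDR across all analytes; top
     *k* by ascending p.
   - *Severity correlation*: per-analyte Pearson correlation with the
     ADOS total score (SA + RRB), computed **over case samples only** —
     the severity instrument is administered only to diagnosed children,
     so controls are structurally excluded (they carry no score at all,
     never a placeholder value); top *k* by |r|.
4. **Core panel** — the set intersection of the RF and t-test lists.
   The correlation list contributes candidates only: its proteins are
   selected within the case group and cannot define a case-vs-control
   core.
5. **Additive search** — every non-core protein from the three lists is
   added to the core one at a time and scored by repeated-split logistic
   regression; candidates whose mean AUC strictly exceeds the core
   baseline join the final panel, which is then re-evaluated once.
6. **Confounder battery** — Welch t-tests of each panel protein across
   ethnicity (white vs non-white) and allergy strata, Spearman rank
   correlation with age, a medication sensitivity analysis (re-evaluate
   the *fixed* panel with medicated subjects removed; no re-selection),
   and per-protein %CV between blinded duplicate assay pairs.

### Panel evaluation

Each of `n_splits` iterations (default 1000) draws a simple random
80/20 subject split (redrawn if either side lacks both classes;
class-stratified splitting is available by flag), fits an unpenalized
logistic regression of group on the panel's normalized columns on the
training side, and records on the test side:

- **AUC** as the rank-based Mann–Whitney area over predicted
  probabilities — the probability that a random case outranks a random
  control, with half credit for ties;
- **sensitivity/specificity** at predicted probability 0.5 with case as
  the positive class. The 0.5 threshold is a convention choice; no
  threshold optimization is performed.

Summaries are means ± SDs over splits. Two panels evaluated with the
same seed see *identical* split sequences, so AUC differences in the
additive search reflect the added protein rather than split luck.
If a training split is perfectly separated (the unpenalized fit fails to
converge), the fit falls back to an effectively-unpenalized ridge
(penalty 1e-6) and the event is logged; predicted probabilities saturate
and the recorded metrics are unaffected in practice.

## Synthetic cohorts

The generator produces the study design the pipeline assumes, with
planted, recoverable truth:

- 76 case + 78 control subjects; 1,317 analytes of which 192 fail QC
  (1,125 analyzed); 7 + 7 blinded duplicate pairs (defaults of
  `study_cohort_spec`, all overridable through `CohortSpec`).
- Baseline log10 abundance per analyte: mean uniform in [2.0, 4.5]
  (RFU ~ 10²–10⁴·⁵, the dynamic range of serum aptamer panels), shared
  across-subject SD `baseline_log10_sd = 0.05`. The SD was set so that a
  mid-range planted fold change (|log2 FC| ≈ 0.15 at n = 154) lands at
  p ~ 1e-8 — the fold-change-to-significance relationship such panels
  report. RFU data are positive and right-skewed; log-normality is an
  assumption, not an observed property.
- Group effects: a planted `(analyte, d)` shifts case log10 values by
  `d·log10(2)`, so the case/control ratio of expected RFU means is
  exactly `2^d`. Default magnitudes mirror the reported serum-panel
  scale (log2 FC from −0.88 to +0.10).
- Severity effects: cases carry a latent N(0,1) trait mapped linearly to
  integer ADOS-like totals in [6, 26] (≈3 SD to each bound, rounded and
  clipped; the linear map keeps the Pearson attenuation from
  discretization ≈1%). A planted `(analyte, r)` gives that analyte's
  case noise a Gaussian-copula correlation `r` with the trait. Realized
  case-only correlations scatter around the target with SE ≈ 0.1 at
  n = 76 — single-cohort deviations up to ±0.15 are expected sampling
  noise, not generator error.
- Duplicates: the re-measurement multiplies the original RFU by
  `exp(σZ)` with `σ = √π · duplicate_cv`, chosen analytically so the
  *expected two-point %CV* of an (original, duplicate) pair — sample-SD
  convention, `sd = |a−b|/√2` — equals `duplicate_cv`. At 10% the
  per-analyte mean over 14 pairs lands in the 6–13% band for ≈91% of
  analytes; the per-pair CV is half-normal-like with substantial spread,
  so a tighter band would not be met by any honest noise model.
- Demographics (age 2–10 y, ethnicity ≈ 73:77 white:non-white, allergy
  ≈ 44:105, medication ≈ 8:146, each with a few unreported) are drawn
  independently of all protein values, making them true nulls for the
  covariate battery.

**What passing tests do and do not show.** Analytes are generated
independently given group and severity. Real serum proteins are
correlated, which is precisely why a 12-protein panel in real data
plateaus near AUC 0.88 while the synthetic core — six independent
effects, the largest at Cohen's d ≈ 5 on the log scale — saturates at
AUC ≈ 1.0. Recovery and calibration results on these cohorts therefore
validate the machinery (ranking, intersection, split bookkeeping, FDR),
not the achievable discrimination on correlated biological data. Plate
and batch effects, assay calibrator scaling, and hybridization chemistry
are out of scope.

## Numerical and design choices

- **z-score denominator**: population SD (`ddof=0`) by default — this is
  the convention under which the canonical worked example
  `(10, 100, 1000) → (−1.2247, 0, 1.2247)` holds; `ddof=1` is one flag
  away. Zero-variance analytes become all-zero columns (with a logged
  warning) rather than being dropped, keeping column indices stable;
  they are inert downstream.
- **Welch, not Student**: unequal-variance t-tests throughout; with
  ~77 per group and heteroskedastic analytes Welch is the safer default.
- **Pearson by default** for severity correlation ("correlation
  coefficient" unqualified conventionally means Pearson); Spearman by
  config. The covariate battery's age check is Spearman (rank-based, as
  is standard for age trends).
- **BH step-up** for FDR; no other multiplicity correction.
- **RF hyperparameters**: 500 trees, `mtry = floor(sqrt(#analytes))`,
  unlimited depth, no class weights — the documented defaults of the
  classic R implementation of random forests. Importances are exported
  on the MeanDecreaseGini scale (per-tree total impurity decrease
  averaged over trees, rescaled by sample count, not normalized to sum
  to one). Per-repeat seed = `seed + repeat`, so the averaged-importance
  table is reproducible; top-k set equality across analyte permutations
  holds up to ties given the same per-repeat randomness.
- **Fold changes on the raw scale**: t-statistics are computed on
  normalized values, but log2 fold changes come from raw RFU group
  means. This reconciles small printed fold changes with z-scale
  testing; both scales are exportable.
- **Additive rule**: strictly-greater mean AUC vs the core baseline over
  a shared split sequence, margin 0 (configurable). Additions are judged
  one-at-a-time against the core, not cumulatively; the final panel is
  core plus all individually-improving candidates, re-evaluated once.
- **Tie-breaks**: RF ties by analyte id; t-test ties by larger |t| then
  id; correlation ties by id. Core/candidate ordering by best rank
  across lists, then id. All orderings are deterministic.
- **Seed fan-out**: one master seed; RF uses `seed + 101`, split
  evaluation `seed + 211`. Identical config + seed gives byte-identical
  pipeline outputs.
- **Degenerate inputs**: both-groups-zero-variance analytes are decided
  by exact mean comparison (p = 1 when equal); an empty RF∩t-test
  intersection warns and proceeds with a candidates-only search against
  a chance baseline of 0.5; covariate strata smaller than 2 mark rows
  untestable instead of failing the battery.

## Problem sizes in the test suite

The statistical conditions in the acceptance-style tests are the
study's (76 + 78 subjects, 1,317 analytes with 192 QC failures);
simulation *effort* knobs are scaled for speed: 20 forest repeats
instead of 100 in the recovery test (the averaged ranking stabilizes
well before 20 repeats at these effect sizes), 150–400 evaluation splits
instead of 1,000, and 10–20 seed replicates per property. The
acceptance script uses 50 forest repeats and 400 splits. None of these
change the quantities being estimated, only their Monte-Carlo error.

## Limitations

- No inter-analyte correlation structure; see above for what that means
  for AUC levels.
- The severity trait is unidimensional and linear in the copula; real
  ADOS totals are sums of discrete item scores with floor effects.
- The confounder battery is univariable; no multivariable adjustment or
  interaction modelling.
- XLSX ingestion reads the first worksheet (plus an `analytes` QC sheet
  when present); SomaLogic ADAT files are not parsed.
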