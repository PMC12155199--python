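# Methods

`mecfstrial` re-implements, as a reusable and testable pipeline, the
analysis of a decentralized single-arm trial of weekly low-dose rapamycin
in ME/CFS: patient-reported-outcome (PRO) scoring, responder
stratification by minimal clinically important differences (MCIDs),
longitudinal inference over four timepoints, autophagy-biomarker
correlation, and a random-forest responder classifier.  Because the
underlying trial deposited no participant-level data, every stage is
exercised against a synthetic cohort generator that reproduces the study's
structure and plants known ground truth.

## Instruments and scoring

Four instruments are scored from raw item responses:

- **BAS** (Bell Activity Scale): a single functional rating, validated to
  be a multiple of 10 on [0, 100]; higher is better.
- **SSS** (Specific Symptom Severity): integer severities 0–10 for
  fatigue, disturbed sleep, post-exertional malaise and orthostatic
  intolerance; identity scoring with validation; higher is worse.
- **MFI-20**: 20 items on 1–5, four per domain over five fatigue domains
  (general fatigue, physical fatigue, reduced activity, reduced
  motivation, mental fatigue).  Reverse-keyed items are mapped r → 6 − r
  before summation; each domain is the sum of its four keyed items
  (range 4–20) and the aggregate the sum of the five domains (20–100);
  higher is worse.  The keying map is configuration; the shipped default
  is the standard MFI-20 keying (items 2, 5, 9, 10, 13, 14, 16, 17, 18,
  19 reversed).
- **SF-36** (RAND v1): items recoded to 0–100 by the published v1 recode
  tables; each of the eight subscales is the mean of its non-missing
  recoded items.  A subscale is scored when at least half of its items
  are present (half-scale rule with person-mean imputation); otherwise it
  is missing.  PCS/MCS are norm-based summaries,
  `50 + 10 · Σ_s w_s · z_s`, with z-scores computed against a
  configurable norm table; the shipped default uses the 1990 US
  general-population subscale norms with the published orthogonal
  factor-score coefficients, but any table can be supplied — the weights
  are data, not constants baked into the algorithm.  PCS/MCS require all
  eight subscales.

Change scores ("deltas") are *last completed timepoint minus baseline*,
resolved **per instrument**: a participant who skipped the MFI at day 90
but completed it at day 60 contributes an MFI delta from day 60.
Biomarker concentrations are log2-transformed before differencing;
non-positive concentrations are rejected rather than silently dropped.

## Responder stratification

Per-instrument MCID rules, combined into an overall call:

| Instrument | Responder | Partial responder |
|---|---|---|
| SF-36 | ≥ 2 of: ΔVT ≥ +3, ΔSF ≥ +3, ΔRP ≥ +3, ΔPCS ≥ +2 | exactly 1 criterion |
| MFI | ≥ 3 domains ≤ −2, or 2 domains ≤ −2 and aggregate ≤ −10 | ≥ 2 domains ≤ −2, or 1 domain ≤ −2 with aggregate in (−10, 0) |
| BAS | Δ ≥ +10 | — (no partial stratum) |

The MFI aggregate threshold of −10 is the per-domain MCID of −2
extrapolated over the five domains.  The responder rule is evaluated
before the partial rule, so a pattern satisfying both is a responder.
BAS deltas strictly inside (0, 10) cannot arise from valid scores but can
from free-text data entry; they are flagged *indeterminate* and treated
as non-responder.  Overall: ≥ 2 instrument-level responders → responder;
otherwise any partial-or-better instrument call → partial responder;
else non-responder.  One quirk of the published MFI rule is worth
knowing: the partial window for a *single* qualifying domain is the open
interval (−10, 0) on the aggregate, while the ≤ −10 branch requires two
qualifying domains — so a single-domain partial whose aggregate improves
past −10 is, literally, reclassified as non-responder.  The package
implements the rule as published rather than smoothing the boundary, and
its property tests pin down exactly this exception.  We read the overall
partial rule as "at least one
instrument at partial or better, short of the responder rule", which is
the only reading under which the three overall strata partition the
cohort.  The SSS deliberately plays no role in stratification.  Because a
published "showed recovery" headline may pool strata differently than the
stratum-count figure, `pooled_percent` reports any user-chosen pooled
grouping alongside the raw counts without asserting one reading.

## Longitudinal inference

Complete participants × timepoints matrices use a one-way
repeated-measures ANOVA; its degrees of freedom are multiplied by the
Greenhouse-Geisser epsilon (computed from the double-centered timepoint
covariance, floored at 1/(k−1)) to protect against sphericity violations.
Incomplete data use a linear mixed model — categorical timepoint fixed
effect, random intercept per participant — fitted by REML, the minimal
structure that behaves like an RM ANOVA while tolerating missingness.
The omnibus time test is the Wald F with containment (between-within)
denominator degrees of freedom, `N_obs − n_participants − (k − 1)`; on
complete balanced data this F coincides with the RM ANOVA F (the package
asserts agreement to 1e-6 relative).  When requested (the default) the
mixed-model degrees of freedom are likewise deflated by an epsilon
estimated from complete-case participants (set to 1 when fewer complete
cases than timepoints exist).  Under a null simulation with monotone
dropout this makes the omnibus test mildly conservative (empirical
type-I error ≈ 0.03–0.04 at nominal 0.05), never anticonservative —
the property the test suite locks in.

Timepoint-vs-baseline comparisons are paired t contrasts adjusted by
Dunnett's many-to-one method: the adjusted p is
`1 − P(max_j |T_j| ≤ |t|)` under the equicoordinate multivariate t with
the balanced many-to-one correlation of 0.5 between contrasts and
degrees of freedom from the smallest contrast.  The rectangle
probability is evaluated by seeded quasi-Monte Carlo integration
(absolute tolerance about 1e-4, bit-reproducible given the seed).  With
a single contrast the adjustment degenerates exactly to the paired t
test.  Group × time interactions (onset or responder subsets) reuse the
mixed-model machinery with a `group * timepoint` fixed-effect structure;
groups below two participants are dropped with a warning.

Numerical note: statsmodels' REML optimizer convergence flag is
unreliable near the random-intercept variance boundary, so the fitter
runs a tight conjugate-gradient pass (plus a BFGS polish) and ranks
candidate fits by restricted log-likelihood, falling back to L-BFGS and
Powell only when the gradient path fails outright.  The paired-t/mixed-F
identity holds only when the variance estimate is interior; on boundary
data (no between-subject variance) the REML estimate pools differently
and small discrepancies are expected.

## Biomarker analysis

BECLIN-1 (pan-autophagy marker; rising levels read as improved autophagy
flux) and pSer258-ATG13 (mTOR-phosphorylated ATG13; a marker of impaired
autophagy initiation) are analysed on the log2 scale.  Endpoint changes
are summarised as linear fold ratios `2^(Δlog2)`, verbalised as x-fold
increase (ratio > 1) or x-fold reduction (x = inverse ratio); all folds
are computed as ratios, with the verbal descriptor purely presentational.
Marker deltas are related to questionnaire deltas by Spearman rank
correlation (mid-rank ties, two-sided p, pairwise deletion with the n
used reported per cell) and simple linear regression.  The correlation
panel emits one row per marker × measure × subgroup; subgroups with
fewer than five usable pairs are reported as skipped rows rather than
dropped, mirroring how underpowered subsets are handled in small trials.
No multiplicity adjustment is applied by default (matching common
practice for exploratory panels); a Benjamini-Hochberg flag is provided.

## Responder prediction

Features are the change scores the stratification itself uses: BAS, the
five MFI domains plus aggregate, SF-36 RP/VT/SF and PCS (11 columns,
fixed order).  Missing cells are filled by k-nearest-neighbour
imputation with k = 2, using scikit-learn's `nan_euclidean` distance
(Euclidean over mutually observed coordinates, rescaled by coordinate
count).  The cohort is split 80/20, stratified by label when every class
has at least two members (unstratified with a warning otherwise).
Hyperparameters are tuned by exhaustive grid search over
`max_depth ∈ {2, 3}` with `max_features='sqrt'`, `min_samples_leaf=1`,
`min_samples_split=2`, `n_estimators=200`, scored by mean 5-fold CV
accuracy (folds capped at the smallest class count); ties break in grid
order.  The chosen forest is refit on all training rows with out-of-bag
scoring.  Evaluation reports the confusion matrix (rows = true class in
responder/partial/non order), per-class one-vs-rest AUC from predicted
probabilities (undefined AUCs reported as such), feature importances
(non-negative, summing to 1) and train/OOB/test accuracy.  The whole
impute→split→tune→train→evaluate chain is deterministic under a fixed
seed.  Accuracies reported by the original cohort are descriptive
context only; they are not reproducible without the raw data and are not
targets of this package.

## Synthetic cohort generator

The generator emits raw *item-level* responses — not scores — so the
scoring code is exercised end to end.  Defaults emulate the study
conditions: 109 enrolled, 23 declining, 86 initiating, 70/55/46
completing days 36/60/90, 40 analyzed completers split 17/18/5 into
responder/partial/non-responder strata and 36/4 into viral/non-viral
onset.  The funnel is reproduced in expectation by per-interval retention
draws, or exactly under `exact_funnel`.

Each stratum plants endpoint change patterns that satisfy its MCID rules
by construction (responders: BAS +10/+20, MFI domain deltas
(−3, −3, −2, −1, −1), SF-36 item steps delivering ΔVT = +5, ΔSF = +12.5,
ΔRP = +25; partials: one MFI domain at −2 with aggregate −5; non:
flat), realised as item patterns that score to the target values under
the default keying.  Intermediate timepoints realise a rising fraction
(0.4/0.7/1.0) of the endpoint effect.  Baseline heterogeneity comes from
per-participant draws (BAS from {20..50}, MFI domains from 12–16, SSS
from 5–8, SF-36 items jittered one step around a moderately impaired
template, with the three criterion-carrying items held fixed so planted
improvements never clip).  With all noise knobs at zero the planted
strata are recovered *exactly*; the default noise (score-level jitter of
SD ≈ 1 point, 15% BAS step jitter, 4% SF-36 item flips, 3% per-visit
instrument missingness) blurs them realistically.

Biomarkers are log-normal: baseline log2 levels ~ N(6.0, 0.8) for
BECLIN-1 and N(7.0, 0.8) for pSer258-ATG13 (pg/mL scale), with
stratum-specific endpoint shifts (+1.5/+0.4/0.0 and −1.8/−1.0/−0.1 log2
units) along marker-specific time profiles (BECLIN-1 rising late,
pSer258-ATG13 dropping early), measurement noise of 0.4 log2 units, and
a per-participant latent response multiplier (SD 0.3) supplying
within-stratum heterogeneity.  These choices make the simulated cohort
reproduce the *qualitative* reported pattern — a BAS improvement near
15%, roughly 1.5–2-fold BECLIN-1 increase and ≥ 2-fold pSer258-ATG13
reduction by day 90, and moderate negative BECLIN-1/MFI correlations —
without being fit to any quantitative result.
`plant_biomarker_coupling` additionally rewrites a marker's trajectory
as a deterministic (optionally noisy) function of a chosen questionnaire
delta, giving exact control over correlation-recovery tests.

What the generator does **not** emulate: item-level response styles and
floor/ceiling clustering of real PROs, informative (outcome-dependent)
dropout, site effects, medication co-interventions, assay batch effects,
and within-participant biomarker autocorrelation beyond the shared
latent.  Passing recovery tests therefore demonstrates correctness of
the pipeline's logic under the planted data-generating process, not
clinical validity on real cohorts.

## Problem sizes and tolerances used by the test suite

Calibration checks run at the cohort's own scale (n = 40, 4 timepoints):
the Dunnett family-wise error uses 2000 null replicates (bound: nominal
0.05 plus two Monte-Carlo SEs), the mixed-model type-I check 400
replicates with ~20% monotone dropout (one-sided anticonservativity
bound), the permuted-label predictor null 50 replicates, and the
MFI-rule oracle enumerates all 16 807 domain-delta patterns in
{−4..+2}⁵.  The RM-ANOVA/mixed-model equivalence is asserted at 1e-6
relative; the Dunnett quasi-Monte Carlo tolerance is ~1e-4; exact-score
assertions are exact.

## Known limitations

- Denominator degrees of freedom use the containment method; Satterthwaite
  or Kenward-Roger approximations are not implemented, so p-values on
  heavily unbalanced data are approximate (empirically conservative with
  the GG deflation applied).
- The Dunnett adjustment assumes the balanced many-to-one correlation of
  0.5 rather than estimating the contrast correlation from the data.
- PCS/MCS values depend entirely on the supplied norm table; comparisons
  across studies require the same table.
- The generator's dropout is non-informative by design; analyses of
  missing-data mechanisms are out of scope.
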