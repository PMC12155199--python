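# mecfstrial

Analysis pipeline for a decentralized, single-arm trial of weekly
low-dose rapamycin in ME/CFS (myalgic encephalomyelitis / chronic
fatigue syndrome).  The package is for biostatisticians and trialists
who need the full chain — patient-reported-outcome scoring, responder
stratification, longitudinal inference, biomarker correlation, responder
prediction — as reusable, tested code rather than a one-off analysis,
plus a synthetic cohort generator so every stage can be exercised and
validated without access to participant-level data.

## What it computes

**Scoring.**  Four instruments per participant per timepoint (baseline
and days 36/60/90): the Bell Activity Scale (BAS, 0–100 in steps of 10,
higher = better), the Specific Symptom Severity inventory (four hallmark
symptoms on 0–10), the MFI-20 (five fatigue domains, each the sum of
four keyed 1–5 items, domain range 4–20, aggregate 20–100) and the RAND
SF-36 v1 (eight 0–100 subscales from the published recode tables, with
norm-based component summaries PCS/MCS = 50 + 10·Σ w·z against a
configurable norm table).  Change scores Δ are *last completed timepoint
minus baseline*, resolved per instrument.

**Responder stratification** by minimal clinically important
differences:

- SF-36: responder if ≥ 2 of {ΔVT ≥ +3, ΔSF ≥ +3, ΔRP ≥ +3, ΔPCS ≥ +2},
  partial if exactly one;
- MFI: responder if ≥ 3 domains ≤ −2, or 2 domains ≤ −2 with aggregate
  ≤ −10 (= 5 × the per-domain MCID); partial if ≥ 2 domains ≤ −2, or one
  domain ≤ −2 with aggregate in (−10, 0);
- BAS: responder at Δ ≥ +10, non-responder at Δ ≤ 0;
- overall: ≥ 2 instrument responders → responder, else any partial or
  better → partial responder, else non-responder.

**Longitudinal statistics.**  Repeated-measures ANOVA with
Greenhouse-Geisser-corrected degrees of freedom on complete data; a REML
linear mixed model (random intercept per participant, categorical
timepoint) that coincides with the RM ANOVA on balanced data for
incomplete data; Dunnett many-to-one adjustment for each
timepoint-vs-baseline contrast; group × time interaction tests for onset
and responder subsets; Shapiro-Wilk and QQ diagnostics.

**Biomarkers.**  log2-transformed plasma BECLIN-1 (autophagy flux) and
pSer258-ATG13 (mTOR-impaired autophagy initiation), endpoint fold
changes, and a Spearman correlation panel of marker deltas against every
questionnaire delta, by subgroup.

**Prediction.**  KNN imputation (k = 2), 80/20 split, grid-searched
random forest (5-fold CV) over the stratification's own change scores,
with confusion matrix, per-class AUC and feature importances.

See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
simulated cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_score_instruments.py
python analysis/03_stratify_responders.py
python analysis/04_longitudinal_models.py
python analysis/05_biomarker_correlations.py
python analysis/06_predict_responders.py
```

which prints, stage by stage (seed 1):

```
funnel: 109 enrolled -> 86 initiated -> 70/55/46 completing T1/T2/T3; 40 analyzed
onset among analyzed: 36 viral / 4 non-viral
BAS mean 37.25 (BSL) -> 41.79 (T3): +12.20% change
strata: 17 responders / 16 partial / 7 non-responders (0 excluded)
bas                    F(2.29, 85.6) =    4.50  p = 0.011
mfi_aggregate          F(1.88, 70.2) =   98.29  p = 1.8e-20
patg13_log2            F(2.91, 113.4) =   74.67  p = 2.7e-26
BAS onset x time interaction: F(2.29, 83.3) = 0.45, p = 0.663
patg13: 2.46-fold reduction at T3 (mean log2 scale)
CV accuracy 0.94 | OOB 0.94 | train 0.94 | test 0.88
```

Reading it: of 109 simulated enrollees, 40 complete the protocol and are
analyzed; under the default planted effects the activity scale improves
~12%, the MCID rules recover roughly the planted 17/18/5 stratum split
despite item-level noise, every fatigue measure shows a strong
time effect (F with Geisser-Greenhouse-deflated degrees of freedom),
onset subgroups share the same time profile (null interaction, as
planted), pSer258-ATG13 falls about 2.5-fold by day 90, and the forest
classifies held-out participants' strata from their change scores.

The same stages are available as a CLI
(`mecfstrial simulate|score|stratify|longitudinal|correlate|predict|run-all`)
and as a single call, `mecfstrial.run_pipeline(seed=...)`.

A zero-noise cohort makes the ground truth exact — the generator is the
oracle the test suite uses:

```python
import mecfstrial as m

raw = m.generate_cohort(m.SyntheticCohortConfig.completers(), seed=42)
deltas = m.compute_cohort_deltas(m.score_cohort(raw))
calls, counts = m.stratify_cohort(deltas)
print(counts)   # {'responder': 17, 'partial': 18, 'non': 5, 'excluded': 0}
```

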