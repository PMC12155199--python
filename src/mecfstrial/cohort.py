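"""Synthetic cohort generation emulating the trial's data structure.

The generator produces raw item-level questionnaire responses (not
pre-computed scores), so the scoring code is exercised end to end.  Each
participant is assigned a responder stratum; the stratum determines
planted baseline-to-endpoint change patterns that satisfy the MCID
stratification rules *by construction*:

* responders improve on all three stratifying instruments (BAS +10/+20,
  three or more MFI domains by ≥ 2 points, and the SF-36 VT/SF/RP
  criteria);
* partial responders improve on exactly one MFI domain with an aggregate
  change in (−10, 0) and are flat elsewhere;
* non-responders are flat or decline.

With the noise knobs at zero, the planted strata are therefore recovered
exactly by the stratification stage — the generator doubles as the
ground-truth oracle for recovery tests.  Biomarker trajectories are
log-normal with stratum × time trends on the log2 scale (BECLIN-1 rising
under treatment, pSer258-ATG13 falling), and monotone dropout reproduces
the study's enrollment funnel (109 enrolled → 23 declined → 86 initiated
→ 70/55/46 completing T1/T2/T3, with 40 analyzed completers) in
expectation, or exactly when ``exact_funnel`` is set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .instruments import (
    DEFAULT_MFI_DOMAIN_MAP,
    MFI_DOMAINS,
    SF36_RECODE,
    SSS_SYMPTOMS,
    TIMEPOINTS,
    TIMEPOINT_DAYS,
    default_mfi_keying,
)

STRATA = ("responder", "partial", "non")

#: fraction of the endpoint effect realised at each timepoint
_INSTRUMENT_PROFILE = {"BSL": 0.0, "T1": 0.4, "T2": 0.7, "T3": 1.0}
_BECLIN1_PROFILE = {"BSL": 0.0, "T1": 0.3, "T2": 0.8, "T3": 1.0}
_PATG13_PROFILE = {"BSL": 0.0, "T1": 0.8, "T2": 0.7, "T3": 1.0}


@dataclass(frozen=True)
class BiomarkerTrend:
    """Log2-scale trajectory parameters for one plasma marker."""

    baseline_log2_mean: float
    baseline_log2_sd: float
    #: endpoint (T3) log2 shift per stratum
    t3_shift: Mapping[str, float]
    #: fraction of the endpoint shift realised at each timepoint
    profile: Mapping[str, float]
    noise_sd: float = 0.4


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generator parameters; defaults emulate the study conditions.

    The enrollment funnel, stratum split (17/18/5 of 40 analyzed
    completers) and viral-onset split (36/4) follow the reported cohort.
    Noise knobs perturb planted effects at the item level; setting them to
    zero makes stratum recovery exact.
    """

    n_enrolled: int = 109
    n_declined: int = 23
    funnel: tuple[int, int, int] = (70, 55, 46)   # completing T1, T2, T3
    n_analyzed: int = 40
    stratum_counts: tuple[int, int, int] = (17, 18, 5)   # responder/partial/non
    viral_count: int = 36        # among analyzed completers
    viral_fraction_other: float = 0.9

    noise_sd: float = 1.0                 # score-level jitter (MFI/SSS points)
    bas_jitter_prob: float = 0.15         # ±10-point BAS jitter probability
    sf36_item_flip_prob: float = 0.04     # per-item ±1-step jitter probability
    missing_instrument_prob: float = 0.03  # per instrument per follow-up visit
    exact_funnel: bool = False

    beclin1: BiomarkerTrend = field(default_factory=lambda: BiomarkerTrend(
        baseline_log2_mean=6.0, baseline_log2_sd=0.8,
        t3_shift={"responder": 1.5, "partial": 0.4, "non": 0.0},
        profile=_BECLIN1_PROFILE))
    patg13: BiomarkerTrend = field(default_factory=lambda: BiomarkerTrend(
        baseline_log2_mean=7.0, baseline_log2_sd=0.8,
        t3_shift={"responder": -1.8, "partial": -1.0, "non": -0.1},
        profile=_PATG13_PROFILE))
    #: spread of the per-participant latent treatment-response multiplier
    #: applied to biomarker shifts (within-stratum heterogeneity)
    latent_sd: float = 0.3

    def __post_init__(self) -> None:
        n_initiated = self.n_enrolled - self.n_declined
        t1, t2, t3 = self.funnel
        if not (0 < self.n_analyzed <= t3 <= t2 <= t1 <= n_initiated):
            raise ValueError("funnel must be monotone: initiated >= T1 >= T2 >= T3 >= analyzed")
        if sum(self.stratum_counts) != self.n_analyzed:
            raise ValueError("stratum counts must sum to the analyzed count")
        if not 0 <= self.viral_count <= self.n_analyzed:
            raise ValueError("viral count must not exceed the analyzed count")
        if self.noise_sd < 0 or any(s < 0 for s in (
                self.bas_jitter_prob, self.sf36_item_flip_prob,
                self.missing_instrument_prob, self.latent_sd)):
            raise ValueError("noise parameters must be non-negative")
        _validate_planted_effects()

    @classmethod
    def study_defaults(cls) -> "SyntheticCohortConfig":
        return cls()

    @classmethod
    def completers(
        cls,
        stratum_counts: tuple[int, int, int] = (17, 18, 5),
        viral_count: int = 36,
        noise_sd: float = 0.0,
        **overrides,
    ) -> "SyntheticCohortConfig":
        """A fully-retained analyzed cohort (no funnel, no dropout).

        With the default zero noise, planted strata are recovered exactly.
        """
        n = sum(stratum_counts)
        base = dict(
            n_enrolled=n, n_declined=0, funnel=(n, n, n), n_analyzed=n,
            stratum_counts=stratum_counts, viral_count=viral_count,
            noise_sd=noise_sd,
            bas_jitter_prob=0.0 if noise_sd == 0 else 0.15,
            sf36_item_flip_prob=0.0 if noise_sd == 0 else 0.04,
            missing_instrument_prob=0.0 if noise_sd == 0 else 0.03,
        )
        base.update(overrides)
        return cls(**base)

    def with_noise(self, noise_sd: float) -> "SyntheticCohortConfig":
        return replace(self, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# Planted per-stratum effects
# ---------------------------------------------------------------------------

#: endpoint MFI domain deltas per stratum (general, physical, reduced
#: activity, reduced motivation, mental) — responders satisfy the
#: three-domain rule, partials the one-domain + aggregate-in-(−10,0) rule
_MFI_DELTAS = {
    "responder": (-3, -3, -2, -1, -1),
    "partial": (-2, -1, -1, -1, 0),
    "non": (0, 0, 0, 0, 0),
}
_SSS_DELTAS = {"responder": -3, "partial": -1, "non": 0}
_BAS_BASELINES = ((20, 30, 40, 50), (0.15, 0.30, 0.35, 0.20))
_BAS_DELTAS = {
    "responder": ((10, 20), (0.7, 0.3)),
    "partial": ((0,), (1.0,)),
    "non": ((0, -10), (0.7, 0.3)),
}
_MFI_BASELINE_RANGE = (12, 16)    # inclusive, per domain
_SSS_BASELINE_RANGE = (5, 8)

#: SF-36 raw-response template for a moderately impaired baseline; keys are
#: 1-based item numbers, chosen with headroom for planted improvements.
_SF36_BASELINE_TEMPLATE: dict[int, int] = {}
for _i in (1, 2, 20, 22, 34, 36):
    _SF36_BASELINE_TEMPLATE[_i] = 4       # recode 25
for _i in range(3, 13):
    _SF36_BASELINE_TEMPLATE[_i] = 2       # recode 50
for _i in range(13, 20):
    _SF36_BASELINE_TEMPLATE[_i] = 1       # recode 0
for _i in (21, 23, 26, 27, 30):
    _SF36_BASELINE_TEMPLATE[_i] = 5       # recode 20
for _i in (24, 25, 28, 29, 31):
    _SF36_BASELINE_TEMPLATE[_i] = 2       # recode 20
for _i in (32, 33, 35):
    _SF36_BASELINE_TEMPLATE[_i] = 2       # recode 25

#: responder SF-36 item improvements (item, raw-step) with the timepoint at
#: which each first applies: ΔVT = +5 from T1, ΔSF = +12.5 and ΔPF = +10
#: from T2, ΔRP = +25 at T3 — two subscale criteria plus RP fire at T3.
_SF36_RESPONDER_STEPS = {
    "T1": ((23, -1),),                      # VT item, one step better
    "T2": ((32, 1), (3, 1), (4, 1)),        # SF item + two PF items
    "T3": ((13, 1),),                       # RP item
}

#: items held at the template baseline so the planted improvement steps
#: above always have headroom and never clip
_SF36_PROTECTED_ITEMS = frozenset({23, 32, 13})


def _validate_planted_effects() -> None:
    lo, hi = _MFI_BASELINE_RANGE
    for stratum, deltas in _MFI_DELTAS.items():
        for d in deltas:
            if not (4 <= lo + d and hi + d <= 20):
                raise ValueError(f"planted MFI delta {d} infeasible from baseline range {lo}..{hi}")
    lo, hi = _SSS_BASELINE_RANGE
    for stratum, d in _SSS_DELTAS.items():
        if not (0 <= lo + d <= 10 and 0 <= hi + d <= 10):
            raise ValueError(f"planted SSS delta {d} infeasible from baseline range {lo}..{hi}")
    for stratum, (vals, _) in _BAS_DELTAS.items():
        for b in _BAS_BASELINES[0]:
            for d in vals:
                if not 0 <= b + d <= 100:
                    raise ValueError(f"planted BAS delta {d} infeasible from baseline {b}")


# ---------------------------------------------------------------------------
# Item construction (scores -> raw responses)
# ---------------------------------------------------------------------------

def construct_mfi_items(domain_scores: Mapping[str, int]) -> list[int]:
    """Raw 20-item response vector whose default-keyed scoring yields the
    given domain scores exactly."""
    keying = default_mfi_keying()
    items = [0] * 20
    for domain, nums in DEFAULT_MFI_DOMAIN_MAP.items():
        s = int(domain_scores[domain])
        if not 4 <= s <= 20:
            raise ValueError(f"MFI domain score {s} outside 4..20")
        base, rem = divmod(s - 4, 4)
        for j, num in enumerate(nums):
            keyed = 1 + base + (1 if j < rem else 0)
            items[num - 1] = keyed if keying[num] == "direct" else 6 - keyed
    return items


def _clip_step(item_num: int, raw: int, step: int) -> int:
    legal = sorted(SF36_RECODE[item_num])
    return int(np.clip(raw + step, legal[0], legal[-1]))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _assign_funnel(config: SyntheticCohortConfig, rng: np.random.Generator,
                   n_other: int) -> list[str]:
    """Last completed timepoint for each non-analyzed initiated participant.

    Exact mode reproduces the funnel counts; stochastic mode draws
    per-interval retention so the *expected* counts match the funnel.
    """
    t1, t2, t3 = config.funnel
    n_a = config.n_analyzed
    counts = {"BSL": (config.n_enrolled - config.n_declined) - t1,
              "T1": t1 - t2, "T2": t2 - t3, "T3": t3 - n_a}
    if config.exact_funnel:
        pool = [tp for tp, c in counts.items() for _ in range(c)]
        assert len(pool) == n_other
        return list(rng.permutation(pool))
    # interval retention for the non-analyzed pool, conditional on the
    # analyzed participants always completing
    last = []
    probs = []
    remaining = [t1 - n_a, t2 - n_a, t3 - n_a]
    denom = n_other
    for r in remaining:
        probs.append(r / denom if denom > 0 else 0.0)
        denom = r
    for _ in range(n_other):
        lt = "BSL"
        if rng.random() < probs[0]:
            lt = "T1"
            if rng.random() < probs[1]:
                lt = "T2"
                if rng.random() < probs[2]:
                    lt = "T3"
        last.append(lt)
    return last


def _int_jitter(rng: np.random.Generator, sd: float) -> int:
    return int(np.rint(rng.normal(0.0, sd))) if sd > 0 else 0


def generate_cohort(config: SyntheticCohortConfig, seed: int) -> pd.DataFrame:
    """Generate a long-format raw cohort table (one row per participant ×
    completed timepoint) realising the configured study structure.

    Deterministic given (config, seed).
    """
    rng = np.random.default_rng(seed)
    n_initiated = config.n_enrolled - config.n_declined
    ids = [f"P{i + 1:03d}" for i in range(config.n_enrolled)]

    declined = set(rng.choice(config.n_enrolled, size=config.n_declined, replace=False))
    initiated_idx = [i for i in range(config.n_enrolled) if i not in declined]
    analyzed_idx = set(rng.choice(initiated_idx, size=config.n_analyzed, replace=False).tolist())
    other_idx = [i for i in initiated_idx if i not in analyzed_idx]

    # strata: exact counts for the analyzed set, same proportions elsewhere
    strata_pool = [s for s, c in zip(STRATA, config.stratum_counts) for _ in range(c)]
    analyzed_strata = dict(zip(sorted(analyzed_idx), rng.permutation(strata_pool)))
    frac = np.asarray(config.stratum_counts, dtype=float) / config.n_analyzed
    other_strata = dict(zip(other_idx, rng.choice(STRATA, size=len(other_idx), p=frac)))

    viral_ids = set(rng.choice(sorted(analyzed_idx), size=config.viral_count,
                               replace=False).tolist())
    other_last = dict(zip(other_idx, _assign_funnel(config, rng, len(other_idx))))

    tp_index = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    rows = []
    for i in range(config.n_enrolled):
        pid = ids[i]
        is_declined = i in declined
        analyzed = i in analyzed_idx
        stratum = analyzed_strata.get(i) or other_strata.get(i) or "non"
        if is_declined:
            last_tp = "BSL"
        elif analyzed:
            last_tp = "T3"
        else:
            last_tp = other_last[i]
        if analyzed:
            viral = i in viral_ids
        else:
            viral = rng.random() < config.viral_fraction_other

        age = float(np.clip(rng.normal(45, 12), 18, 75))
        sex = "F" if rng.random() < 0.75 else "M"
        bmi = float(np.clip(rng.normal(26, 4), 17, 45))
        duration = float(np.clip(rng.normal(16, 8), 1, 50))
        latent = rng.normal(0.0, 1.0)
        latent_mult = max(0.0, 1.0 + config.latent_sd * latent)

        # planted baselines and endpoint deltas
        bas0 = int(rng.choice(_BAS_BASELINES[0], p=_BAS_BASELINES[1]))
        bvals, bp = _BAS_DELTAS[stratum]
        bas_delta = int(rng.choice(bvals, p=bp))
        mfi0 = {d: int(rng.integers(_MFI_BASELINE_RANGE[0], _MFI_BASELINE_RANGE[1] + 1))
                for d in MFI_DOMAINS}
        mfi_delta = dict(zip(MFI_DOMAINS, _MFI_DELTAS[stratum]))
        sss0 = {s: int(rng.integers(_SSS_BASELINE_RANGE[0], _SSS_BASELINE_RANGE[1] + 1))
                for s in SSS_SYMPTOMS}
        sss_delta = _SSS_DELTAS[stratum]
        # baseline heterogeneity: jitter unprotected items one step either
        # way so every subscale varies across participants at baseline
        sf36_base = dict(_SF36_BASELINE_TEMPLATE)
        for num in sf36_base:
            if num not in _SF36_PROTECTED_ITEMS:
                sf36_base[num] = _clip_step(num, sf36_base[num],
                                            int(rng.choice((-1, 0, 1), p=(0.3, 0.4, 0.3))))

        bio0 = {}
        for marker, trend in (("beclin1", config.beclin1), ("patg13", config.patg13)):
            bio0[marker] = rng.normal(trend.baseline_log2_mean, trend.baseline_log2_sd)

        last_i = tp_index[last_tp]
        for tp in TIMEPOINTS[: last_i + 1]:
            f = _INSTRUMENT_PROFILE[tp]
            row: dict[str, object] = {
                "participant_id": pid, "timepoint": tp, "day": TIMEPOINT_DAYS[tp],
                "initiated": not is_declined, "analyzed": analyzed,
                "onset": "viral" if viral else "non_viral",
                "stratum_true": stratum,
                "age": round(age, 1), "sex": sex, "bmi": round(bmi, 1),
                "disease_duration_years": round(duration, 1),
            }

            bas = bas0 + int(np.rint(f * bas_delta / 10.0)) * 10
            if tp != "BSL" and rng.random() < config.bas_jitter_prob:
                bas += int(rng.choice((-10, 10)))
            row["bas"] = int(np.clip(bas, 0, 100))

            for s in SSS_SYMPTOMS:
                v = sss0[s] + int(np.rint(f * sss_delta))
                if tp != "BSL":
                    v += _int_jitter(rng, config.noise_sd * 0.5)
                row[f"sss_{s}"] = int(np.clip(v, 0, 10))

            dom_scores = {}
            for d in MFI_DOMAINS:
                v = mfi0[d] + int(np.rint(f * mfi_delta[d]))
                if tp != "BSL":
                    v += _int_jitter(rng, config.noise_sd * 0.5)
                dom_scores[d] = int(np.clip(v, 4, 20))
            for num, v in zip(range(1, 21), construct_mfi_items(dom_scores)):
                row[f"mfi_q{num:02d}"] = v

            sf_items = dict(sf36_base)
            if stratum == "responder":
                for tp_from, steps in _SF36_RESPONDER_STEPS.items():
                    if tp_index[tp] >= tp_index[tp_from]:
                        for num, step in steps:
                            sf_items[num] = _clip_step(num, sf_items[num], step)
            if tp != "BSL" and config.sf36_item_flip_prob > 0:
                for num in sf_items:
                    if rng.random() < config.sf36_item_flip_prob:
                        sf_items[num] = _clip_step(num, sf_items[num],
                                                   int(rng.choice((-1, 1))))
            for num in range(1, 37):
                row[f"sf36_q{num:02d}"] = sf_items[num]

            for marker, trend in (("beclin1", config.beclin1), ("patg13", config.patg13)):
                l2 = bio0[marker] + trend.profile[tp] * trend.t3_shift[stratum] * latent_mult
                if tp != "BSL" and trend.noise_sd > 0 and config.noise_sd > 0:
                    l2 += rng.normal(0.0, trend.noise_sd)
                row[f"{marker}_conc"] = float(2.0 ** l2)

            # instrument-level missingness at follow-up visits
            if tp != "BSL" and config.missing_instrument_prob > 0:
                for inst, cols in (
                    ("bas", ["bas"]),
                    ("sss", [f"sss_{s}" for s in SSS_SYMPTOMS]),
                    ("mfi", [f"mfi_q{n:02d}" for n in range(1, 21)]),
                    ("sf36", [f"sf36_q{n:02d}" for n in range(1, 37)]),
                ):
                    if rng.random() < config.missing_instrument_prob:
                        for c in cols:
                            row[c] = np.nan
            rows.append(row)

    return pd.DataFrame(rows)


def funnel_summary(raw: pd.DataFrame) -> dict[str, int]:
    """Enrollment-funnel bookkeeping counts from a raw cohort table."""
    per = raw.groupby("participant_id").agg(
        initiated=("initiated", "first"),
        tps=("timepoint", lambda s: set(s)),
    )
    out = {
        "enrolled": int(len(per)),
        "declined": int((~per["initiated"]).sum()),
        "initiated": int(per["initiated"].sum()),
    }
    for tp in TIMEPOINTS[1:]:
        out[f"completed_{tp}"] = int((per["initiated"] & per["tps"].map(lambda s: tp in s)).sum())
    if "analyzed" in raw.columns:
        out["analyzed"] = int(raw.groupby("participant_id")["analyzed"].first().sum())
    return out


def onset_split(raw: pd.DataFrame, analyzed_only: bool = True) -> dict[str, int]:
    """Viral / non-viral onset bookkeeping counts."""
    per = raw.groupby("participant_id").agg(onset=("onset", "first"),
                                            analyzed=("analyzed", "first"))
    if analyzed_only:
        per = per[per["analyzed"]]
    return {
        "total": int(len(per)),
        "viral": int((per["onset"] == "viral").sum()),
        "non_viral": int((per["onset"] == "non_viral").sum()),
    }


def plant_biomarker_coupling(
    raw: pd.DataFrame,
    couplings: Mapping[str, tuple[str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rewrite biomarker trajectories so each marker's log2 endpoint change
    tracks a chosen questionnaire change score.

    For each ``marker: (measure, coefficient)`` entry the marker's log2
    delta becomes ``coefficient × z(measure delta) + noise``, realised along
    the marker's time profile from the existing baseline.  A strictly
    monotone deterministic coupling (``noise_sd=0``) yields a Spearman
    correlation of exactly ±1 with the target measure.

    Participants whose target measure delta is missing keep their original
    trajectory.
    """
    from .instruments import compute_cohort_deltas, score_cohort

    scored = score_cohort(raw)
    deltas = compute_cohort_deltas(scored).set_index("participant_id")
    profiles = {"beclin1": _BECLIN1_PROFILE, "patg13": _PATG13_PROFILE}
    rng = np.random.default_rng(seed)
    out = raw.copy()

    for marker, (measure, coef) in couplings.items():
        if marker not in profiles:
            raise ValueError(f"unknown marker {marker!r}")
        if measure not in deltas.columns:
            raise ValueError(f"unknown measure {measure!r}")
        x = deltas[measure].astype(float)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else x * 0.0
        base = out[out["timepoint"] == "BSL"].set_index("participant_id")[f"{marker}_conc"]
        for pid, zval in z.items():
            if not np.isfinite(zval) or pid not in base.index or not np.isfinite(base[pid]):
                continue
            b_log2 = np.log2(base[pid])
            target = coef * zval + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            mask = out["participant_id"] == pid
            for tp in TIMEPOINTS[1:]:
                sel = mask & (out["timepoint"] == tp)
                if sel.any():
                    out.loc[sel, f"{marker}_conc"] = float(
                        2.0 ** (b_log2 + profiles[marker][tp] * target))
    return out
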