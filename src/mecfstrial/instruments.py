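"""Scoring of the four patient-reported outcome instruments.

The trial's primary endpoints are four self-report instruments:

* **BAS** — Bell Activity Scale, a single functional-ability rating on
  0–100 in steps of 10; higher is better.
* **SSS** — Specific Symptom Severity inventory: four hallmark ME/CFS
  symptoms (fatigue, disturbed sleep, post-exertional malaise,
  orthostatic intolerance), each rated 0–10; higher is worse.
* **MFI-20** — Multidimensional Fatigue Inventory: 20 items rated 1–5,
  four items per domain across five fatigue domains; each domain scores
  4–20 and the aggregate 20–100; higher is worse.
* **SF-36** — RAND 36-Item Short Form Health Survey v1: 36 items recoded
  to 0–100 and averaged into eight subscales; higher is better.  Norm-based
  physical and mental component summaries (PCS/MCS) are computed from
  subscale z-scores against a configurable norm table.

This module also computes baseline-to-last-completed-timepoint change
scores ("deltas") for every measure, the quantity on which responder
stratification operates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("BSL", "T1", "T2", "T3")
TIMEPOINT_DAYS = {"BSL": 0, "T1": 36, "T2": 60, "T3": 90}

# ---------------------------------------------------------------------------
# MFI-20
# ---------------------------------------------------------------------------

MFI_DOMAINS = (
    "general_fatigue",
    "physical_fatigue",
    "reduced_activity",
    "reduced_motivation",
    "mental_fatigue",
)

#: 1-based item numbers per domain (standard MFI-20 layout).
DEFAULT_MFI_DOMAIN_MAP: dict[str, tuple[int, int, int, int]] = {
    "general_fatigue": (1, 5, 12, 16),
    "physical_fatigue": (2, 8, 14, 20),
    "reduced_activity": (3, 6, 10, 17),
    "reduced_motivation": (4, 9, 15, 18),
    "mental_fatigue": (7, 11, 13, 19),
}

#: Items phrased positively ("I feel fit") and therefore reverse-keyed
#: (response r contributes 6 - r).  This is the standard MFI-20 keying;
#: a user-supplied keying map overrides it.
DEFAULT_MFI_REVERSED: frozenset[int] = frozenset({2, 5, 9, 10, 13, 14, 16, 17, 18, 19})


def default_mfi_keying() -> dict[int, str]:
    """Return the default item→{'direct','reversed'} keying map."""
    return {
        i: ("reversed" if i in DEFAULT_MFI_REVERSED else "direct")
        for i in range(1, 21)
    }


def score_mfi(
    items: Sequence[int],
    keying: Mapping[int, str] | None = None,
    domain_map: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, int]:
    """Score 20 MFI item responses into five domain scores and an aggregate.

    Parameters
    ----------
    items
        20 ordered integer responses, each in [1, 5]; ``items[i]`` is the
        response to item ``i + 1``.
    keying
        Map of 1-based item number to ``"direct"`` or ``"reversed"``.
        Reversed items are mapped r → 6 − r before summation.  Defaults to
        the standard MFI-20 keying.
    domain_map
        Map of domain name to the four 1-based item numbers it comprises.

    Returns
    -------
    dict with one entry per domain plus ``"aggregate"`` (sum of the five
    domains).  Higher scores indicate worse fatigue.
    """
    if len(items) != 20:
        raise ValueError(f"MFI requires exactly 20 items, got {len(items)}")
    keying = dict(keying) if keying is not None else default_mfi_keying()
    domain_map = dict(domain_map) if domain_map is not None else dict(DEFAULT_MFI_DOMAIN_MAP)

    if set(keying) != set(range(1, 21)):
        raise ValueError("keying must cover items 1..20 exactly")
    covered = sorted(i for its in domain_map.values() for i in its)
    if covered != list(range(1, 21)) or any(len(v) != 4 for v in domain_map.values()):
        raise ValueError("domain map must assign each of items 1..20 to exactly one domain, 4 per domain")

    keyed = {}
    for num, raw in zip(range(1, 21), items):
        r = int(raw)
        if r != raw or not 1 <= r <= 5:
            raise ValueError(f"MFI item {num} response {raw!r} outside 1..5")
        if keying[num] == "reversed":
            r = 6 - r
        elif keying[num] != "direct":
            raise ValueError(f"keying for item {num} must be 'direct' or 'reversed'")
        keyed[num] = r

    scores = {d: sum(keyed[i] for i in its) for d, its in domain_map.items()}
    scores["aggregate"] = sum(scores.values())
    return scores


# ---------------------------------------------------------------------------
# SF-36 (RAND v1)
# ---------------------------------------------------------------------------

SF36_SUBSCALES = ("PF", "RP", "RE", "VT", "MH", "SF", "BP", "GH")

# RAND v1 recode tables: raw response -> 0..100, per 1-based item number.
_RECODE_5_HIGH = {1: 100.0, 2: 75.0, 3: 50.0, 4: 25.0, 5: 0.0}
_RECODE_3 = {1: 0.0, 2: 50.0, 3: 100.0}
_RECODE_2 = {1: 0.0, 2: 100.0}
_RECODE_6_HIGH = {1: 100.0, 2: 80.0, 3: 60.0, 4: 40.0, 5: 20.0, 6: 0.0}
_RECODE_6_LOW = {1: 0.0, 2: 20.0, 3: 40.0, 4: 60.0, 5: 80.0, 6: 100.0}
_RECODE_5_LOW = {1: 0.0, 2: 25.0, 3: 50.0, 4: 75.0, 5: 100.0}

SF36_RECODE: dict[int, dict[int, float]] = {}
for _i in (1, 2, 20, 22, 34, 36):
    SF36_RECODE[_i] = _RECODE_5_HIGH
for _i in range(3, 13):
    SF36_RECODE[_i] = _RECODE_3
for _i in range(13, 20):
    SF36_RECODE[_i] = _RECODE_2
for _i in (21, 23, 26, 27, 30):
    SF36_RECODE[_i] = _RECODE_6_HIGH
for _i in (24, 25, 28, 29, 31):
    SF36_RECODE[_i] = _RECODE_6_LOW
for _i in (32, 33, 35):
    SF36_RECODE[_i] = _RECODE_5_LOW

SF36_SCALE_ITEMS: dict[str, tuple[int, ...]] = {
    "PF": tuple(range(3, 13)),
    "RP": (13, 14, 15, 16),
    "RE": (17, 18, 19),
    "VT": (23, 27, 29, 31),
    "MH": (24, 25, 26, 28, 30),
    "SF": (20, 32),
    "BP": (21, 22),
    "GH": (1, 33, 34, 35, 36),
}


@dataclass(frozen=True)
class ComponentNorms:
    """Reference means/SDs and weights for norm-based PCS/MCS summaries.

    The component summaries are computed as ``50 + 10 * Σ_s w_s * z_s``
    where ``z_s`` is the subscale z-score against ``mean``/``sd``.  The
    table is configuration, not ground truth: any population norms and
    factor weights of the user's choosing can be supplied.
    """

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    pcs_weights: Mapping[str, float]
    mcs_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for m in (self.mean, self.sd, self.pcs_weights, self.mcs_weights):
            if set(m) != set(SF36_SUBSCALES):
                raise ValueError("norm table must cover all eight SF-36 subscales")
        if any(v <= 0 for v in self.sd.values()):
            raise ValueError("norm SDs must be positive")


def default_component_norms() -> ComponentNorms:
    """Default PCS/MCS configuration: 1990 US general-population subscale
    norms with the published orthogonal factor-score coefficients.

    Shipped as a convenience default; studies with different reference
    populations should pass their own :class:`ComponentNorms`.
    """
    return ComponentNorms(
        mean={
            "PF": 84.52404, "RP": 81.19907, "BP": 75.49196, "GH": 72.21316,
            "VT": 61.05453, "SF": 83.59753, "RE": 81.29467, "MH": 74.84212,
        },
        sd={
            "PF": 22.89490, "RP": 33.79729, "BP": 23.55879, "GH": 20.16964,
            "VT": 20.86942, "SF": 22.37642, "RE": 33.02717, "MH": 18.01189,
        },
        pcs_weights={
            "PF": 0.42402, "RP": 0.35119, "BP": 0.31754, "GH": 0.24954,
            "VT": 0.02877, "SF": -0.00753, "RE": -0.19206, "MH": -0.22069,
        },
        mcs_weights={
            "PF": -0.22999, "RP": -0.12329, "BP": -0.09731, "GH": -0.01571,
            "VT": 0.23534, "SF": 0.26876, "RE": 0.43407, "MH": 0.48581,
        },
    )


def score_sf36(
    items: Sequence[float | None],
    norms: ComponentNorms | None = None,
) -> dict[str, float]:
    """Score 36 SF-36 v1 item responses into eight subscales plus PCS/MCS.

    Items are recoded to 0–100 per the RAND v1 recode tables; each subscale
    is the mean of its non-missing recoded items, scored when at least half
    of its items are present (person-mean imputation of the rest).  PCS and
    MCS are norm-based summaries computed only when all eight subscales are
    available and a norm table is supplied.

    Parameters
    ----------
    items
        36 ordered responses (``items[i]`` answers item ``i + 1``); ``None``
        or NaN marks a skipped item.
    norms
        Norm table for the component summaries.  ``None`` omits PCS/MCS.

    Returns
    -------
    dict mapping subscale name to score (NaN when unscorable), plus
    ``"PCS"``/``"MCS"`` when computable.  Higher = better health.
    """
    if len(items) != 36:
        raise ValueError(f"SF-36 requires exactly 36 items, got {len(items)}")

    recoded: dict[int, float] = {}
    for num, raw in zip(range(1, 37), items):
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            continue
        r = int(raw)
        if r != raw or r not in SF36_RECODE[num]:
            legal = sorted(SF36_RECODE[num])
            raise ValueError(f"SF-36 item {num} response {raw!r} outside legal range {legal}")
        recoded[num] = SF36_RECODE[num][r]

    out: dict[str, float] = {}
    for scale, its in SF36_SCALE_ITEMS.items():
        present = [recoded[i] for i in its if i in recoded]
        # half-scale rule: score if >= 50% of the scale's items answered
        if len(present) * 2 >= len(its) and present:
            out[scale] = float(np.mean(present))
        else:
            out[scale] = float("nan")

    if norms is not None:
        if all(math.isfinite(out[s]) for s in SF36_SUBSCALES):
            z = {s: (out[s] - norms.mean[s]) / norms.sd[s] for s in SF36_SUBSCALES}
            out["PCS"] = 50.0 + 10.0 * sum(norms.pcs_weights[s] * z[s] for s in SF36_SUBSCALES)
            out["MCS"] = 50.0 + 10.0 * sum(norms.mcs_weights[s] * z[s] for s in SF36_SUBSCALES)
        else:
            out["PCS"] = float("nan")
            out["MCS"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# SSS and BAS
# ---------------------------------------------------------------------------

SSS_SYMPTOMS = ("fatigue", "disturbed_sleep", "pem", "oi")


def score_sss(items: Mapping[str, int]) -> dict[str, int]:
    """Validate and pass through the four hallmark symptom severities.

    Each severity is an integer on 0 (not experienced) to 10 (very severe).
    """
    out = {}
    for sym in SSS_SYMPTOMS:
        if sym not in items:
            raise ValueError(f"SSS missing symptom {sym!r}")
        v = items[sym]
        if int(v) != v or not 0 <= v <= 10:
            raise ValueError(f"SSS {sym} severity {v!r} outside 0..10")
        out[sym] = int(v)
    return out


def validate_bas(value: float) -> int:
    """Validate a Bell Activity Scale score: a multiple of 10 on [0, 100]."""
    v = int(value)
    if v != value or v % 10 != 0 or not 0 <= v <= 100:
        raise ValueError(f"BAS score {value!r} must be a multiple of 10 in [0, 100]")
    return v


def compute_percent_change(mean_baseline: float, mean_later: float) -> float:
    """Percent change of a later mean relative to the baseline mean."""
    if mean_baseline == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline mean")
    return 100.0 * (mean_later - mean_baseline) / mean_baseline


# ---------------------------------------------------------------------------
# Cohort-level scoring and deltas
# ---------------------------------------------------------------------------

BIOMARKERS = {"beclin1": "beclin1_conc", "patg13": "patg13_conc"}

#: Scored-measure column names, grouped by the instrument whose completion
#: governs their "last completed timepoint".
MEASURE_GROUPS: dict[str, tuple[str, ...]] = {
    "bas": ("bas",),
    "sss": tuple(f"sss_{s}" for s in SSS_SYMPTOMS),
    "mfi": tuple(f"mfi_{d}" for d in MFI_DOMAINS) + ("mfi_aggregate",),
    "sf36": tuple(f"sf36_{s.lower()}" for s in SF36_SUBSCALES) + ("sf36_pcs", "sf36_mcs"),
    "beclin1": ("beclin1_log2",),
    "patg13": ("patg13_log2",),
}

ALL_MEASURES: tuple[str, ...] = tuple(m for g in MEASURE_GROUPS.values() for m in g)


def score_cohort(
    raw: pd.DataFrame,
    keying: Mapping[int, str] | None = None,
    norms: ComponentNorms | None = None,
) -> pd.DataFrame:
    """Score a long-format raw cohort table into per-timepoint measure scores.

    Expects one row per participant × timepoint with columns ``bas``,
    ``sss_<symptom>``, ``mfi_q01..mfi_q20``, ``sf36_q01..sf36_q36`` and
    biomarker concentrations; missing instruments are NaN.  Returns a long
    table with one column per scored measure (see :data:`ALL_MEASURES`),
    carrying over identifying and pass-through columns.
    """
    if norms is None:
        norms = default_component_norms()
    mfi_cols = [f"mfi_q{i:02d}" for i in range(1, 21)]
    sf36_cols = [f"sf36_q{i:02d}" for i in range(1, 37)]

    records = []
    for _, row in raw.iterrows():
        rec: dict[str, object] = {
            "participant_id": row["participant_id"],
            "timepoint": row["timepoint"],
        }
        for extra in ("onset", "analyzed", "initiated", "stratum_true"):
            if extra in raw.columns:
                rec[extra] = row[extra]

        rec["bas"] = validate_bas(row["bas"]) if pd.notna(row.get("bas")) else np.nan

        sss_vals = {s: row.get(f"sss_{s}") for s in SSS_SYMPTOMS}
        if all(pd.notna(v) for v in sss_vals.values()):
            for s, v in score_sss({k: int(v) for k, v in sss_vals.items()}).items():
                rec[f"sss_{s}"] = v
        else:
            for s in SSS_SYMPTOMS:
                rec[f"sss_{s}"] = np.nan

        mfi_vals = [row.get(c) for c in mfi_cols]
        if all(pd.notna(v) for v in mfi_vals):
            scores = score_mfi([int(v) for v in mfi_vals], keying=keying)
            for d in MFI_DOMAINS:
                rec[f"mfi_{d}"] = scores[d]
            rec["mfi_aggregate"] = scores["aggregate"]
        else:
            for d in MFI_DOMAINS:
                rec[f"mfi_{d}"] = np.nan
            rec["mfi_aggregate"] = np.nan

        sf_vals = [row.get(c) for c in sf36_cols]
        if any(pd.notna(v) for v in sf_vals):
            scores = score_sf36(
                [int(v) if pd.notna(v) else None for v in sf_vals], norms=norms
            )
            for s in SF36_SUBSCALES:
                rec[f"sf36_{s.lower()}"] = scores[s]
            rec["sf36_pcs"] = scores["PCS"]
            rec["sf36_mcs"] = scores["MCS"]
        else:
            for s in SF36_SUBSCALES:
                rec[f"sf36_{s.lower()}"] = np.nan
            rec["sf36_pcs"] = np.nan
            rec["sf36_mcs"] = np.nan

        from .biomarkers import log2_transform  # local import to avoid cycle

        for marker, col in BIOMARKERS.items():
            v = row.get(col)
            rec[f"{marker}_log2"] = log2_transform(float(v)) if pd.notna(v) else np.nan
        records.append(rec)

    return pd.DataFrame.from_records(records)


def compute_deltas(baseline: Mapping[str, float], last: Mapping[str, float]) -> dict[str, float]:
    """Signed change scores (last − baseline) over all shared scored measures.

    Measures missing at either end are NaN, never zero.
    """
    out = {}
    for m in ALL_MEASURES:
        b, l = baseline.get(m, np.nan), last.get(m, np.nan)
        out[m] = (l - b) if pd.notna(b) and pd.notna(l) else float("nan")
    return out


def compute_cohort_deltas(scored: pd.DataFrame) -> pd.DataFrame:
    """Baseline-to-last-completed-timepoint deltas for every participant.

    "Last completed" is resolved per instrument: an instrument's delta uses
    the latest timepoint at which that instrument was actually completed,
    since participants sometimes skipped individual questionnaires.
    Participants without a baseline row or without any post-baseline
    observation of a measure get NaN for that measure.

    Returns a wide table, one row per participant, with one delta column
    per measure plus ``last_timepoint_<group>`` bookkeeping columns.
    """
    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    rows = []
    for pid, grp in scored.groupby("participant_id", sort=True):
        grp = grp.sort_values("timepoint", key=lambda s: s.map(order))
        by_tp = {tp: r for tp, r in zip(grp["timepoint"], grp.to_dict("records"))}
        rec: dict[str, object] = {"participant_id": pid}
        for extra in ("onset", "analyzed", "stratum_true"):
            if extra in grp.columns:
                rec[extra] = grp[extra].iloc[0]
        base = by_tp.get("BSL")
        for group, measures in MEASURE_GROUPS.items():
            last_tp = None
            if base is not None:
                for tp in reversed(TIMEPOINTS[1:]):
                    r = by_tp.get(tp)
                    if r is not None and any(pd.notna(r.get(m)) for m in measures):
                        last_tp = tp
                        break
            rec[f"last_timepoint_{group}"] = last_tp
            for m in measures:
                if base is None or last_tp is None:
                    rec[m] = np.nan
                else:
                    b, l = base.get(m, np.nan), by_tp[last_tp].get(m, np.nan)
                    rec[m] = (l - b) if pd.notna(b) and pd.notna(l) else np.nan
        rows.append(rec)
    return pd.DataFrame.from_records(rows)
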