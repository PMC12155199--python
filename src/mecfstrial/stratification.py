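"""MCID-based responder stratification.

Participants are classified per instrument from their baseline-to-last-
timepoint change scores, using minimal clinically important differences
(MCIDs), and the per-instrument calls are combined into an overall
responder / partial responder / non-responder status:

* SF-36: criteria ΔVT ≥ +3, ΔSF ≥ +3, ΔRP ≥ +3, ΔPCS ≥ +2; two or more
  criteria → responder, one → partial responder, none → non-responder.
* MFI: responder if at least three of the five domain deltas are ≤ −2, or
  two domains are ≤ −2 together with an aggregate delta ≤ −10 (the
  per-domain MCID of −2 extrapolated over five domains); partial if at
  least two domains are ≤ −2, or one domain is ≤ −2 with the aggregate in
  (−10, 0); otherwise non-responder.
* BAS: responder at ΔBAS ≥ +10 (one step of the scale), non-responder at
  ΔBAS ≤ 0.  Deltas strictly inside (0, 10) cannot arise from valid BAS
  scores; they are called indeterminate and treated as non-responder.
* Overall: two or more instrument-level responder calls → responder;
  otherwise any partial-or-better call → partial responder; else
  non-responder.

The SSS plays no role in stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Per-instrument MCID thresholds (configurable; defaults are the trial's).
SF36_SUBSCALE_MCID = 3.0   # VT, SF, RP subscale deltas
SF36_PCS_MCID = 2.0
MFI_DOMAIN_MCID = -2       # per fatigue domain
MFI_AGGREGATE_MCID = 5 * MFI_DOMAIN_MCID   # = -10, extrapolated over 5 domains
BAS_MCID = 10

RESPONDER, PARTIAL, NON, INDETERMINATE = "responder", "partial", "non", "indeterminate"


@dataclass
class ResponderCall:
    """Per-instrument and overall responder status for one participant."""

    participant_id: object
    sf36_status: str
    mfi_status: str
    bas_status: str
    overall: str
    criteria_met: list[str] = field(default_factory=list)


def classify_sf36(
    vt_delta: float,
    sf_delta: float,
    rp_delta: float,
    pcs_delta: float,
    subscale_mcid: float = SF36_SUBSCALE_MCID,
    pcs_mcid: float = SF36_PCS_MCID,
) -> tuple[str, list[str]]:
    """Classify the SF-36 response from the VT/SF/RP subscale and PCS deltas.

    A missing delta simply fails its criterion.  Returns the status and the
    list of criteria that fired (the audit trail).
    """
    met = []
    for name, delta, thr in (
        ("sf36_vt", vt_delta, subscale_mcid),
        ("sf36_sf", sf_delta, subscale_mcid),
        ("sf36_rp", rp_delta, subscale_mcid),
        ("sf36_pcs", pcs_delta, pcs_mcid),
    ):
        if pd.notna(delta) and delta >= thr:
            met.append(f"{name}>=+{thr:g}")
    if len(met) >= 2:
        return RESPONDER, met
    if len(met) == 1:
        return PARTIAL, met
    return NON, met


def classify_mfi(
    domain_deltas: "list[float] | np.ndarray",
    aggregate_delta: float,
    domain_mcid: float = MFI_DOMAIN_MCID,
    aggregate_mcid: float = MFI_AGGREGATE_MCID,
) -> tuple[str, list[str]]:
    """Classify the MFI response from the five domain deltas and the aggregate.

    The responder rule is evaluated before the partial rule, so a pattern
    satisfying both is a responder.  Missing domain deltas are classified on
    the available domains and flagged in the audit list.
    """
    deltas = [d for d in domain_deltas if pd.notna(d)]
    met = []
    if len(deltas) < 5:
        met.append(f"only_{len(deltas)}_domains_available")
    n_improved = sum(d <= domain_mcid for d in deltas)
    agg_ok = pd.notna(aggregate_delta)

    if n_improved >= 3:
        met.append(f"{n_improved}_domains<={domain_mcid:g}")
        return RESPONDER, met
    if n_improved >= 2 and agg_ok and aggregate_delta <= aggregate_mcid:
        met.append(f"{n_improved}_domains<={domain_mcid:g}&aggregate<={aggregate_mcid:g}")
        return RESPONDER, met
    if n_improved >= 2:
        met.append(f"{n_improved}_domains<={domain_mcid:g}")
        return PARTIAL, met
    if n_improved == 1 and agg_ok and aggregate_mcid < aggregate_delta < 0:
        met.append(f"1_domain<={domain_mcid:g}&{aggregate_mcid:g}<aggregate<0")
        return PARTIAL, met
    return NON, met


def classify_bas(delta: float, mcid: float = BAS_MCID) -> tuple[str, list[str]]:
    """Classify the BAS response from its delta.

    Deltas in the open interval (0, mcid) — impossible for scores recorded
    in steps of ten, but possible for free-text entry — are called
    ``indeterminate``, which the overall rule treats as non-responder.
    """
    if pd.isna(delta):
        return NON, []
    if delta >= mcid:
        return RESPONDER, [f"bas>=+{mcid:g}"]
    if delta <= 0:
        return NON, []
    warnings.warn(
        f"BAS delta {delta:g} lies in the indeterminate gap (0, {mcid:g}); treated as non-responder",
        stacklevel=2,
    )
    return INDETERMINATE, [f"bas_in_(0,{mcid:g})"]


def classify_overall(sf36_status: str, mfi_status: str, bas_status: str) -> str:
    """Combine per-instrument calls into the overall responder status."""
    statuses = (sf36_status, mfi_status, bas_status)
    if sum(s == RESPONDER for s in statuses) >= 2:
        return RESPONDER
    if any(s in (RESPONDER, PARTIAL) for s in statuses):
        return PARTIAL
    return NON


def classify_participant(deltas: pd.Series | dict) -> ResponderCall:
    """Full per-participant classification from a row of measure deltas."""
    get = deltas.get
    sf_status, sf_met = classify_sf36(
        get("sf36_vt", np.nan), get("sf36_sf", np.nan),
        get("sf36_rp", np.nan), get("sf36_pcs", np.nan),
    )
    mfi_status, mfi_met = classify_mfi(
        [get(f"mfi_{d}", np.nan) for d in (
            "general_fatigue", "physical_fatigue", "reduced_activity",
            "reduced_motivation", "mental_fatigue")],
        get("mfi_aggregate", np.nan),
    )
    bas_status, bas_met = classify_bas(get("bas", np.nan))
    return ResponderCall(
        participant_id=get("participant_id"),
        sf36_status=sf_status,
        mfi_status=mfi_status,
        bas_status=bas_status,
        overall=classify_overall(sf_status, mfi_status, bas_status),
        criteria_met=sf_met + mfi_met + bas_met,
    )


def stratify_cohort(deltas: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every participant in a wide delta table.

    Participants with no usable deltas at all (no baseline or no
    post-baseline timepoint: every measure NaN) are excluded and reported
    with status ``excluded``.

    Returns
    -------
    calls : DataFrame
        One row per participant: per-instrument statuses, overall status,
        and the audit list of criteria met.
    counts : dict
        Participants per stratum (responder / partial / non / excluded).
    """
    measure_cols = [c for c in deltas.columns
                    if c.startswith(("bas", "mfi_", "sf36_", "sss_"))]
    rows = []
    counts = {RESPONDER: 0, PARTIAL: 0, NON: 0, "excluded": 0}
    for _, row in deltas.iterrows():
        if measure_cols and row[measure_cols].isna().all():
            rows.append({
                "participant_id": row["participant_id"],
                "sf36_status": "", "mfi_status": "", "bas_status": "",
                "overall": "excluded", "criteria_met": "",
            })
            counts["excluded"] += 1
            continue
        call = classify_participant(row)
        rows.append({
            "participant_id": call.participant_id,
            "sf36_status": call.sf36_status,
            "mfi_status": call.mfi_status,
            "bas_status": call.bas_status,
            "overall": call.overall,
            "criteria_met": ";".join(call.criteria_met),
        })
        counts[call.overall] += 1
    cols = ["participant_id", "sf36_status", "mfi_status", "bas_status",
            "overall", "criteria_met"]
    calls = pd.DataFrame(rows, columns=cols)
    return calls, counts


def pooled_percent(counts: dict[str, int], pooled: tuple[str, ...] = (RESPONDER, PARTIAL)) -> float:
    """Percentage of classified participants falling in a pooled grouping.

    The denominator is all classified (non-excluded) participants.  The
    default pools responders and partial responders — one reading of a
    "showed recovery" headline figure; the stratum counts themselves are
    always reported alongside.
    """
    total = sum(v for k, v in counts.items() if k != "excluded")
    if total == 0:
        raise ZeroDivisionError("no classified participants")
    return 100.0 * sum(counts.get(k, 0) for k in pooled) / total
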