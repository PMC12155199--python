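"""Autophagy biomarker transforms and biomarker-questionnaire correlation.

Plasma concentrations of BECLIN-1 (a pan-autophagy marker whose rise is
read as improved autophagy flux) and pSer258-ATG13 (ATG13 phosphorylated
by mTOR, a marker of impaired autophagy initiation) are log2-transformed
before analysis.  Baseline-to-endpoint changes on the log2 scale are
summarised as linear-scale fold changes and related to questionnaire
change scores by Spearman rank correlation and simple linear regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def log2_transform(concentration: float) -> float:
    """Base-2 logarithm of a positive concentration."""
    if not concentration > 0:
        raise ValueError(f"concentration must be positive, got {concentration!r}")
    return math.log2(concentration)


def fold_change(log2_baseline: float, log2_later: float) -> dict[str, float | str]:
    """Linear-scale fold change from two log2 values.

    Returns the ratio ``2 ** (later − baseline)`` together with a verbal
    descriptor: an x-fold *increase* for ratios above 1 and an x-fold
    *reduction* (x = baseline/later ratio) below 1.
    """
    if not (math.isfinite(log2_baseline) and math.isfinite(log2_later)):
        raise ValueError("both log2 values must be finite")
    ratio = 2.0 ** (log2_later - log2_baseline)
    if ratio > 1:
        return {"ratio": ratio, "direction": "increase", "fold": ratio}
    if ratio < 1:
        return {"ratio": ratio, "direction": "reduction", "fold": 1.0 / ratio}
    return {"ratio": 1.0, "direction": "unchanged", "fold": 1.0}


def spearman_delta_correlation(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation (mid-rank ties) between paired change scores.

    Pairs with a missing member are dropped; at least 4 complete pairs are
    required and constant vectors are rejected.  Returns (r_s, two-sided p,
    n pairs used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p), n


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def simple_linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue) ** 2, p=float(res.pvalue),
                            n=int(x.size))


#: Questionnaire measures entering the correlation panel, mirroring the
#: per-questionnaire summary tables of the trial report.
PANEL_MEASURES = (
    "bas",
    "sss_fatigue", "sss_disturbed_sleep", "sss_pem", "sss_oi",
    "mfi_general_fatigue", "mfi_physical_fatigue", "mfi_reduced_activity",
    "mfi_reduced_motivation", "mfi_mental_fatigue", "mfi_aggregate",
    "sf36_pf", "sf36_rp", "sf36_re", "sf36_vt", "sf36_mh", "sf36_sf",
    "sf36_bp", "sf36_gh", "sf36_pcs", "sf36_mcs",
)

PANEL_MARKERS = {"beclin1": "beclin1_log2", "patg13": "patg13_log2"}


def correlation_panel(
    deltas: pd.DataFrame,
    subgroups: dict[str, pd.Series] | None = None,
    min_n: int = 5,
    fdr: bool = False,
) -> pd.DataFrame:
    """Spearman r_s and p for each biomarker × questionnaire delta pair.

    One row per (marker, measure, subgroup) with the n actually used.
    Subgroups whose usable pair count falls below ``min_n`` are emitted as
    skipped rows (NaN statistics, reason noted) rather than silently
    dropped, matching how underpowered subsets are reported.  No
    multiplicity adjustment is applied by default; ``fdr=True`` appends
    Benjamini-Hochberg q-values.

    Parameters
    ----------
    deltas
        Wide per-participant delta table (one column per measure).
    subgroups
        Map of subgroup name to boolean mask over ``deltas`` rows; defaults
        to the single subgroup ``"all"``.
    """
    if subgroups is None:
        subgroups = {"all": pd.Series(True, index=deltas.index)}
    rows = []
    for sub_name, mask in subgroups.items():
        sub = deltas[mask.reindex(deltas.index, fill_value=False)]
        for marker, mcol in PANEL_MARKERS.items():
            for measure in PANEL_MEASURES:
                if measure not in sub.columns or mcol not in sub.columns:
                    continue
                x = sub[mcol].to_numpy(dtype=float)
                y = sub[measure].to_numpy(dtype=float)
                n_ok = int((np.isfinite(x) & np.isfinite(y)).sum())
                if n_ok < min_n:
                    rows.append({"marker": marker, "measure": measure,
                                 "subgroup": sub_name, "n": n_ok,
                                 "r_s": np.nan, "p": np.nan,
                                 "note": f"skipped: n < {min_n}"})
                    continue
                try:
                    r, p, n = spearman_delta_correlation(x, y)
                    rows.append({"marker": marker, "measure": measure,
                                 "subgroup": sub_name, "n": n,
                                 "r_s": r, "p": p, "note": ""})
                except ValueError as exc:
                    rows.append({"marker": marker, "measure": measure,
                                 "subgroup": sub_name, "n": n_ok,
                                 "r_s": np.nan, "p": np.nan,
                                 "note": f"skipped: {exc}"})
    panel = pd.DataFrame(rows)
    if fdr and len(panel):
        from statsmodels.stats.multitest import multipletests

        ok = panel["p"].notna()
        q = np.full(len(panel), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(panel.loc[ok, "p"], method="fdr_bh")[1]
        panel["q_bh"] = q
    return panel
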