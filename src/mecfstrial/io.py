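"""Cohort CSV readers/writers and the end-to-end pipeline.

The on-disk format is a long-format CSV with one row per participant ×
timepoint and columns for raw items (``mfi_q01``…``mfi_q20``,
``sf36_q01``…``sf36_q36``, ``sss_<symptom>``, ``bas``), biomarker
concentrations (``beclin1_conc``, ``patg13_conc``) and identifying
metadata.  Unknown columns (e.g. safety-lab panels) are preserved as
pass-through.  ``run_pipeline`` chains score → deltas → stratify →
longitudinal → correlate → predict and is fully deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers, instruments, longitudinal, predictor, stratification
from .cohort import SyntheticCohortConfig, funnel_summary, onset_split
from .instruments import TIMEPOINTS

log = logging.getLogger("mecfstrial")

_REQUIRED_COLUMNS = ("participant_id", "timepoint")


class CohortReadError(ValueError):
    """Malformed cohort file; message lists offending rows by line number."""


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Validates the header, timepoint labels and duplicate
    (participant, timepoint) rows, reporting 1-based file line numbers.
    Unknown columns are preserved untouched.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortReadError(f"{path}: missing required columns {missing}")
    errors = []
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    for idx in df.index[bad_tp]:
        errors.append(f"line {idx + 2}: unknown timepoint {df.at[idx, 'timepoint']!r}")
    dup = df.duplicated(subset=["participant_id", "timepoint"], keep="first")
    for idx in df.index[dup]:
        errors.append(
            f"line {idx + 2}: duplicate row for participant "
            f"{df.at[idx, 'participant_id']!r} at timepoint {df.at[idx, 'timepoint']!r}"
        )
    if errors:
        raise CohortReadError(f"{path}: " + "; ".join(errors))
    return df


def write_cohort_csv(raw: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; a write→read→write round trip is byte-identical."""
    raw.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Resolved settings for a full pipeline run."""

    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig.study_defaults)
    alpha: float = longitudinal.ALPHA
    min_correlation_n: int = 5
    forest: predictor.ForestConfig = field(default_factory=predictor.ForestConfig)
    #: measures carried into the longitudinal headline table
    headline_measures: tuple[str, ...] = (
        "bas", "sss_fatigue", "sss_pem", "mfi_aggregate", "sf36_vt",
        "beclin1_log2", "patg13_log2",
    )


def _long_measure(scored: pd.DataFrame, measure: str,
                  group_col: str | None = None) -> pd.DataFrame:
    out = pd.DataFrame({
        "participant": scored["participant_id"],
        "timepoint": scored["timepoint"],
        "value": scored[measure],
    })
    if group_col is not None:
        out["group"] = scored[group_col]
    return out.dropna(subset=["value"])


def run_pipeline(
    config: PipelineConfig | None = None,
    raw: pd.DataFrame | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full analysis chain and return the report bundle.

    Stages: simulate (unless ``raw`` is given) → score → deltas → stratify
    → longitudinal → correlate → predict.  Per-stage CSVs and a JSON
    summary are written when ``out_dir`` is set.  Any stage failure raises
    with a stage-tagged message.
    """
    from .cohort import generate_cohort

    if config is None:
        config = PipelineConfig()
    stage = "simulate"
    try:
        if raw is None:
            raw = generate_cohort(config.cohort, seed=seed)
        analyzed = raw[raw.get("analyzed", pd.Series(True, index=raw.index)).astype(bool)]

        stage = "score"
        scored = instruments.score_cohort(analyzed)

        stage = "deltas"
        deltas = instruments.compute_cohort_deltas(scored)

        stage = "stratify"
        calls, counts = stratification.stratify_cohort(deltas)
        strat_block = {
            "counts": counts,
            "percent_responder": round(100.0 * counts["responder"]
                                       / max(1, sum(counts[k] for k in ("responder", "partial", "non"))), 2),
            "percent_responder_or_partial": round(
                stratification.pooled_percent(counts), 2) if sum(counts.values()) else float("nan"),
        }

        stage = "longitudinal"
        headline = []
        for measure in config.headline_measures:
            long = _long_measure(scored, measure)
            if long["timepoint"].nunique() < 2:
                continue
            res = longitudinal.mixed_model_reml(long)
            wide = long.pivot_table(index="participant", columns="timepoint",
                                    values="value", aggfunc="first")
            wide = wide.reindex(columns=[tp for tp in TIMEPOINTS if tp in wide.columns])
            contrasts = longitudinal.dunnett_vs_baseline(
                wide.to_numpy(), list(wide.columns), seed=seed)
            entry = {
                "measure": measure, "F": res.F, "df_num": res.df_num,
                "df_den": res.df_den, "epsilon": res.epsilon, "p": res.p,
            }
            for c in contrasts:
                entry[f"p_adj_{c.timepoint}"] = c.p_adjusted
                entry[f"delta_{c.timepoint}"] = c.estimate
            headline.append(entry)
        headline_df = pd.DataFrame(headline)

        stage = "correlate"
        merged = deltas.merge(calls[["participant_id", "overall"]], on="participant_id", how="left")
        subgroups = {"all": pd.Series(True, index=merged.index)}
        if "onset" in merged.columns:
            subgroups["viral"] = merged["onset"] == "viral"
            subgroups["non_viral"] = merged["onset"] == "non_viral"
        for stratum in ("responder", "partial", "non"):
            subgroups[stratum] = merged["overall"] == stratum
        panel = biomarkers.correlation_panel(merged, subgroups,
                                             min_n=config.min_correlation_n)

        stage = "predict"
        forest_cfg = predictor.ForestConfig(
            n_neighbors=config.forest.n_neighbors,
            test_fraction=config.forest.test_fraction,
            cv_folds=config.forest.cv_folds,
            grid=config.forest.grid,
            seed=seed,
        )
        pred = predictor.run_predictor(deltas, calls, forest_cfg)
        pred_block = {k: v for k, v in pred.items() if k != "model"}
        pred_block["confusion_matrix"] = pred_block["confusion_matrix"].tolist()

        stage = "summarize"
        bas_bsl = scored.loc[scored["timepoint"] == "BSL", "bas"].mean()
        bas_t3 = scored.loc[scored["timepoint"] == "T3", "bas"].mean()
        summary = {
            "funnel": funnel_summary(raw),
            "onset": onset_split(raw) if "onset" in raw.columns else {},
            "bas": {
                "mean_baseline": round(float(bas_bsl), 2),
                "mean_T3": round(float(bas_t3), 2),
                "percent_change": round(
                    instruments.compute_percent_change(bas_bsl, bas_t3), 2),
            },
            "stratification": strat_block,
            "longitudinal": headline_df.to_dict(orient="records"),
            "correlation_panel_rows": int(len(panel)),
            "predictor": pred_block,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle = {
        "raw": raw, "scored": scored, "deltas": deltas, "calls": calls,
        "headline": headline_df, "panel": panel, "predictor": pred,
        "summary": summary,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(raw, out / "cohort_raw.csv")
        scored.to_csv(out / "cohort_scored.csv", index=False)
        deltas.to_csv(out / "cohort_deltas.csv", index=False)
        calls.to_csv(out / "responder_calls.csv", index=False)
        headline_df.to_csv(out / "longitudinal_headline.csv", index=False)
        panel.to_csv(out / "correlation_panel.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        log.info("pipeline outputs written to %s", out)
    return bundle
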