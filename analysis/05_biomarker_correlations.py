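#!/usr/bin/env python
"""Relate autophagy-marker changes to questionnaire changes.

Reports endpoint fold changes of BECLIN-1 and pSer258-ATG13 and the full
Spearman correlation panel (all / viral-onset / responder-stratum
subgroups), mirroring the per-questionnaire summary tables.
"""

import argparse
from pathlib import Path

import pandas as pd

import mecfstrial as m
from mecfstrial.biomarkers import correlation_panel

parser = argparse.ArgumentParser()
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

scored = pd.read_csv(args.out_dir / "cohort_scored.csv")
deltas = pd.read_csv(args.out_dir / "cohort_deltas.csv")
calls = pd.read_csv(args.out_dir / "responder_calls.csv")

for marker in ("beclin1", "patg13"):
    col = f"{marker}_log2"
    bsl = scored.loc[scored["timepoint"] == "BSL", col].mean()
    t3 = scored.loc[scored["timepoint"] == "T3", col].mean()
    fc = m.fold_change(bsl, t3)
    print(f"{marker}: {fc['fold']:.2f}-fold {fc['direction']} at T3 (mean log2 scale)")

merged = deltas.merge(calls[["participant_id", "overall"]], on="participant_id")
subgroups = {"all": pd.Series(True, index=merged.index),
             "viral": merged["onset"] == "viral",
             "non_viral": merged["onset"] == "non_viral"}
for stratum in ("responder", "partial", "non"):
    subgroups[stratum] = merged["overall"] == stratum
panel = correlation_panel(merged, subgroups)
panel.to_csv(args.out_dir / "correlation_panel.csv", index=False)

sig = panel[(panel["subgroup"] == "all") & (panel["p"] < 0.05)]
print(f"\n{len(sig)} significant marker x measure couplings in the full cohort:")
print(sig[["marker", "measure", "n", "r_s", "p"]].to_string(index=False))
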