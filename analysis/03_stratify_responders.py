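#!/usr/bin/env python
"""Classify responders by the MCID rules and summarise the strata."""

import argparse
import json
from pathlib import Path

import pandas as pd

import mecfstrial as m

parser = argparse.ArgumentParser()
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

deltas = pd.read_csv(args.out_dir / "cohort_deltas.csv")
calls, counts = m.stratify_cohort(deltas)
calls.to_csv(args.out_dir / "responder_calls.csv", index=False)
(args.out_dir / "stratification_summary.json").write_text(json.dumps({
    "counts": counts,
    "percent_responder_or_partial": m.pooled_percent(counts),
}, indent=2))

print(f"strata: {counts['responder']} responders / {counts['partial']} partial "
      f"/ {counts['non']} non-responders ({counts['excluded']} excluded)")
print(f"responder-or-partial: {m.pooled_percent(counts):.1f}% of classified")
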