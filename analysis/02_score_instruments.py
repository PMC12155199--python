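#!/usr/bin/env python
"""Score raw questionnaire items and compute baseline-to-endpoint deltas.

Reads the simulated cohort, applies the four instruments' scoring rules
(BAS validation, SSS, MFI-20 with standard keying, RAND SF-36 v1 with
norm-based PCS/MCS), log2-transforms the biomarkers, and writes both the
per-timepoint scores and the per-participant change scores.
"""

import argparse
from pathlib import Path

import mecfstrial as m

parser = argparse.ArgumentParser()
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

raw = m.read_cohort_csv(args.out_dir / "cohort_raw.csv")
analyzed = raw[raw["analyzed"]]
scored = m.score_cohort(analyzed)
deltas = m.compute_cohort_deltas(scored)
scored.to_csv(args.out_dir / "cohort_scored.csv", index=False)
deltas.to_csv(args.out_dir / "cohort_deltas.csv", index=False)

bas_bsl = scored.loc[scored["timepoint"] == "BSL", "bas"].mean()
bas_t3 = scored.loc[scored["timepoint"] == "T3", "bas"].mean()
pct = m.compute_percent_change(bas_bsl, bas_t3)
print(f"scored {scored['participant_id'].nunique()} analyzed completers")
print(f"BAS mean {bas_bsl:.2f} (BSL) -> {bas_t3:.2f} (T3): {pct:+.2f}% change")
print(f"MFI aggregate mean delta: {deltas['mfi_aggregate'].mean():+.2f}")
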