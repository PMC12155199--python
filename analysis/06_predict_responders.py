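#!/usr/bin/env python
"""Train the responder-stratum random forest and report its metrics.

KNN imputation (k=2), an 80/20 stratified split, grid-searched forest
hyperparameters (5-fold CV), refit with out-of-bag scoring, and held-out
evaluation with per-class one-vs-rest AUC and feature importances.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

import mecfstrial as m
from mecfstrial.predictor import ForestConfig, run_predictor

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()
warnings.filterwarnings("ignore")

deltas = pd.read_csv(args.out_dir / "cohort_deltas.csv")
calls = pd.read_csv(args.out_dir / "responder_calls.csv")
rep = run_predictor(deltas, calls, ForestConfig(seed=args.seed))

card = {k: v for k, v in rep.items() if k != "model"}
card["confusion_matrix"] = card["confusion_matrix"].tolist()
(args.out_dir / "predictor_card.json").write_text(json.dumps(card, indent=2))

print(f"chosen hyperparameters: {rep['chosen_hyperparameters']}")
print(f"CV accuracy {rep['cv_accuracy']:.2f} | OOB {rep['oob_accuracy']:.2f} | "
      f"train {rep['train_accuracy']:.2f} | test {rep['test_accuracy']:.2f}")
top = sorted(rep["feature_importances"].items(), key=lambda kv: -kv[1])[:3]
print("top features:", ", ".join(f"{k} ({v:.2f})" for k, v in top))
print("confusion matrix rows=true", rep["confusion_labels"], ":")
for lab, row in zip(rep["confusion_labels"], rep["confusion_matrix"]):
    print(f"  {lab:10s} {list(row)}")
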