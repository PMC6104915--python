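"""Fit both models on the training split (first 15 subjects per sex).

* linear reference: OLS of plasma concentration on Bazett QTc, one pooled
  model over all training replicates;
* deep model: the convolutional network on raw (12 x 5000) records, MSE +
  Adam, 10% internal validation, best-validation checkpoint kept.

Writes results/models/ (split.json, linear_model.json, deep_model/).

Run after 02:  python analysis/03_fit_models.py [--epochs 30]
"""

import argparse
import json
from pathlib import Path

from ecglevel.linear import LinearModelArtifact
from ecglevel.pipeline import RunConfig, stage_train

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--epochs", type=int, default=None)
    args = ap.parse_args()

    cfg = RunConfig.from_yaml(RESULTS / "run_config.yaml")
    if args.epochs:
        cfg.epochs = args.epochs
    models = stage_train(cfg, RESULTS / "cohort", RESULTS / "delineation.csv",
                         RESULTS / "models")
    split = json.loads((models / "split.json").read_text())
    lin = LinearModelArtifact.from_json(models / "linear_model.json")
    print(f"split: {len(split['train'])} train / {len(split['test'])} test")
    print(f"linear model: concentration = {lin.slope:.2f} * QTc "
          f"{lin.intercept:+.0f}  (n = {lin.n_pairs} replicate pairs)")
    hist = models / "deep_model" / "history.csv"
    if hist.exists():
        import pandas as pd
        h = pd.read_csv(hist)
        print(f"deep model: {len(h)} epochs, best validation MSE "
              f"{h.val_mse.min():.4f} (standardized)")


if __name__ == "__main__":
    main()
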