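"""Evaluate both models on the 12 held-out subjects.

Protocol: each replicate ECG is predicted separately; the median of the
triplicate predictions is the estimate for the blood draw; draw-level
estimates are correlated with measured levels (Pearson r) and summarized
as mean +/- SD absolute error in pg/ml.  Also writes the per-subject
baseline/peak QTc table and time-course plots.

Run after 03:  python analysis/04_evaluate.py
"""

import json
from pathlib import Path

from ecglevel.pipeline import RunConfig, stage_evaluate

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = RunConfig.from_yaml(RESULTS / "run_config.yaml")
    report_dir = stage_evaluate(cfg, RESULTS / "cohort",
                                RESULTS / "delineation.csv",
                                RESULTS / "models", RESULTS / "report")
    metrics = json.loads((report_dir / "report.json").read_text())["metrics"]
    print(f"report written to {report_dir}")
    for model_id, m in metrics.items():
        print(f"  {model_id:11s} r = {m['pearson_r']:.3f}   "
              f"|error| = {m['error_mean_pg_ml']:.0f} +/- "
              f"{m['error_sd_pg_ml']:.0f} pg/ml  (n = {m['n_pairs']} draws)")


if __name__ == "__main__":
    main()
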