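"""Optional harness: rerun the full analysis on locally downloaded trial data.

The two source databases (PhysioNet ``ecgrdvq`` — protocol A, and
``ecgdmmld`` — protocol B) are not downloaded by this package.  To use this
harness, fetch a database locally and prepare an annotation table in this
package's schema (one row per blood draw)::

    subject_id,sex,arm,protocol,timepoint_h,concentration_pg_ml,record_1,record_2,record_3

where ``record_k`` are WFDB record base paths (without the ``.hea``/``.dat``
extension) relative to ``--records-root``.  The mapping from each database's
native file layout to this table is deliberately left to the user ("best
effort"): the deposited metadata schemas are not described in the analysis
this package reimplements, so no automatic mapping is claimed or tested.

The harness then runs the standard pipeline — delineate, 30/12 split by
study-id order within sex, fit linear QTc + train the network, evaluate on
the held-out subjects — and prints both models' Pearson r next to the
published reference values (QTc-linear r = 0.64, deep r = 0.85) for a
qualitative comparison.  Expect differences: the published hyperparameters
are not fully specified.

Run:  python analysis/05_real_data_harness.py --annotation ann.csv \
          --records-root data/ecgrdvq --out results/real_data [--epochs 60]
"""

import argparse
import json
from pathlib import Path

from ecglevel.io import assemble_cohort, write_cohort_bundle
from ecglevel.pipeline import (RunConfig, stage_delineate, stage_evaluate,
                               stage_train)

PUBLISHED = {"linear_qtc": 0.64, "deep": 0.85}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--annotation", required=True)
    ap.add_argument("--records-root", required=True)
    ap.add_argument("--out", default="results/real_data")
    ap.add_argument("--epochs", type=int, default=60)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--network", default="default",
                    help='"default" (full-size) or "demo"')
    args = ap.parse_args()

    out = Path(args.out)
    cohort = assemble_cohort(args.annotation, args.records_root,
                             check_grid=False, dialect="wfdb")
    print(f"loaded {len(cohort.samples)} draws from "
          f"{len(cohort.subject_ids)} subjects")
    cohort_dir = write_cohort_bundle(cohort, out / "cohort")

    cfg = RunConfig(network=args.network, epochs=args.epochs,
                    generator_seed=args.seed, train_seed=args.seed + 1,
                    outdir=str(out))
    delin = stage_delineate(cohort_dir, out / "delineation.csv")
    models = stage_train(cfg, cohort_dir, delin, out / "models")
    report_dir = stage_evaluate(cfg, cohort_dir, delin, models, out / "report")
    metrics = json.loads((report_dir / "report.json").read_text())["metrics"]
    print("\nmodel        this run   published")
    for model_id, ref in PUBLISHED.items():
        r = metrics.get(model_id, {}).get("pearson_r")
        shown = "n/a" if r is None else f"{r:8.3f}"
        print(f"{model_id:12s} {shown}   {ref:.2f}")


if __name__ == "__main__":
    main()
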