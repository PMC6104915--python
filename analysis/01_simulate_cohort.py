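"""Generate the synthetic study cohort.

Emulates the source trial's protocol A: 42 healthy subjects (21 M / 21 F),
triplicate 10-s 12-lead ECGs at the predose draw and 15 post-dose time
points, with matched plasma dofetilide concentrations (pg/ml) from a
one-compartment oral PK model and sigmoid-Emax concentration-QT coupling.
Writes the cohort bundle (plus ground truth) under results/cohort/.

Run:  python analysis/01_simulate_cohort.py [--seed 101] [--subjects 42]
"""

import argparse
from pathlib import Path

from ecglevel.pipeline import RunConfig, stage_simulate

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=101)
    ap.add_argument("--subjects", type=int, default=42)
    ap.add_argument("--effect", default="duration_plus_morphology",
                    choices=["duration_only", "duration_plus_morphology"])
    args = ap.parse_args()

    cfg = RunConfig(n_subjects=args.subjects, protocol="A",
                    effect_config=args.effect, generator_seed=args.seed,
                    train_seed=args.seed + 1, outdir=str(RESULTS))
    cfg.validate()
    cohort_dir = stage_simulate(cfg, RESULTS)
    cfg.to_yaml(RESULTS / "run_config.yaml")
    print(f"wrote cohort bundle to {cohort_dir}")
    print(f"subjects: {args.subjects}, blood draws: {args.subjects * 16}, "
          f"records: {args.subjects * 16 * 3}")


if __name__ == "__main__":
    main()
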