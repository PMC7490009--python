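#!/usr/bin/env python
"""Run the full translation-site pipeline over the synthetic experiment.

Simulates 24 cells for each drug-condition preset (in memory, deterministic
in the seed), runs spot detection in both channels, calibrates the single-
peptide intensity unit per cell, quantifies every mRNA's translation site,
and writes the per-cell table to results/per_cell.csv.  The per-cell
colocalized fraction is the statistic every later stage consumes.
"""

import argparse
import logging
from pathlib import Path

from tsquant.pipeline import ExperimentConfig, run_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cells", type=int, default=24)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")

    config = ExperimentConfig(master_seed=args.seed, n_cells=args.cells)
    report = run_experiment(config)
    args.out.mkdir(parents=True, exist_ok=True)
    report.per_cell.to_csv(args.out / "per_cell.csv", index=False)
    config.to_yaml(args.out / "experiment_config.yaml")

    print(f"\nper-cell table -> {args.out / 'per_cell.csv'}")
    for cond, s in report.summaries.items():
        print(
            f"{cond:>20s}: mean fraction {100 * s['mean_fraction']:5.1f}% "
            f"(SEM {100 * s['sem_fraction']:.1f}%, {s['n_cells']} cells)"
        )


if __name__ == "__main__":
    main()
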