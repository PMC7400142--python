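"""How well does the quorum-and-mean rule recover a known ground truth?

Sweeps rating noise and edge-dropout over synthetic six-expert panels on
10-factor ground-truth models and scores edge recovery, under both
readings of the group average (over all experts vs over positive raters
only).  Finding: recovery is near-perfect without noise and degrades
smoothly; with dropout, averaging over all experts systematically shrinks
the group mean by the factor (1 - miss_prob), which suppresses true edges
whose weight sits just above the 5.0 retention threshold - the
raters-only mean does not have this bias and recovers ~10 points more
sensitivity at the reference condition (sd=1, miss=0.1).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from panelfcm import (ConsensusConfig, PanelSimConfig, aggregate_panel,
                      recovery_metrics, simulate_panel, generate_truth)

RESULTS = Path(__file__).resolve().parent.parent / "results"

NOISE_LEVELS = (0.0, 0.5, 1.0, 2.0)
MISS_LEVELS = (0.0, 0.1, 0.3)


def sweep(seed: int, reps: int) -> pd.DataFrame:
    rows = []
    configs = {"all_experts": ConsensusConfig(),
               "raters_only": ConsensusConfig(mean_over="raters_only")}
    for noise in NOISE_LEVELS:
        for miss in MISS_LEVELS:
            for k in range(reps):
                sim = PanelSimConfig(n_factors=10, n_experts=6,
                                     rating_noise_sd=noise, miss_prob=miss,
                                     seed=seed + k)
                truth = generate_truth(sim)
                panel = simulate_panel(truth, sim)
                for name, cfg in configs.items():
                    rep = recovery_metrics(truth, aggregate_panel(panel, cfg))
                    rows.append({"noise_sd": noise, "miss_prob": miss,
                                 "replicate": k, "mean_over": name,
                                 **rep.as_dict()})
    return pd.DataFrame(rows)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--reps", type=int, default=50)
    args = ap.parse_args()

    RESULTS.mkdir(exist_ok=True)
    df = sweep(args.seed, args.reps)
    df.to_csv(RESULTS / "recovery_sweep.csv", index=False)
    summary = (df.groupby(["noise_sd", "miss_prob", "mean_over"])
               [["sensitivity", "specificity", "f1", "weight_rmse"]]
               .mean().round(3))
    summary.to_csv(RESULTS / "recovery_summary.csv")
    print(f"{args.reps} replicates per condition, seed {args.seed}")
    print(summary.to_string())
    ref = summary.loc[(1.0, 0.1)]
    print("\nreference condition (noise sd 1.0, miss 0.1):")
    print(ref.to_string())


if __name__ == "__main__":
    main()
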