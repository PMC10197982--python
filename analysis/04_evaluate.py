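"""Assemble the evaluation surface and the pairwise DeLong comparisons.

Reads the per-family held-out score tables, computes accuracy, precision,
sensitivity, specificity, F1 and AUC with DeLong 95% CIs per family and
threshold, runs the paired DeLong test between all family pairs at each
threshold, and prints the resulting grid along with the AUC-vs-threshold
trend.

Run from the repository root after 03_train_models.py:
    python analysis/04_evaluate.py [--seed 1] [--outdir results/main_experiment]
"""

import argparse
from pathlib import Path

import pandas as pd

from ecgkalemia.pipeline import PipelineConfig, stage_evaluate


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path,
                        default=Path("results/main_experiment"))
    args = parser.parse_args()
    cfg = PipelineConfig(seed=args.seed, outdir=str(args.outdir))
    report_path = stage_evaluate(cfg, args.outdir / "scores", args.outdir)

    metrics = pd.read_csv(report_path)
    cols = ["family", "threshold", "accuracy", "precision", "sensitivity",
            "specificity", "f1", "auc", "auc_ci_low", "auc_ci_high"]
    print(metrics[cols].round(3).to_string(index=False))

    auc = metrics.pivot(index="family", columns="threshold", values="auc")
    drop = auc[5.0] - auc[6.5]
    print("\nAUC drop from threshold 5.0 to 6.5 per family:")
    print(drop.round(3).to_string())

    delong = pd.read_csv(args.outdir / "delong_tests.csv")
    sig = delong[(delong["threshold"] == 5.0) & (delong["p_value"] < 0.05)]
    print(f"\npairwise DeLong tests at 5.0 mmol/L: "
          f"{len(sig)}/{len(delong[delong['threshold'] == 5.0])} "
          f"pairs significant at p < 0.05")


if __name__ == "__main__":
    main()
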