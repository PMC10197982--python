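"""Tune and train the five model families at each diagnostic threshold.

For each threshold in 5.0/5.5/6.0/6.5 mmol/L the labels are binarised
(positive iff K >= threshold), split 8:2 with stratification, and LR, SVM,
XGB, AdaBoost and the convolutional network are tuned by 5-fold
cross-validated AUC before refitting. Held-out score tables and the chosen
hyperparameters are written under the output directory.

Run from the repository root after 02_extract_features.py:
    python analysis/03_train_models.py [--seed 1] [--outdir results/main_experiment]
"""

import argparse
import json
from pathlib import Path

from ecgkalemia.pipeline import PipelineConfig, stage_train


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path,
                        default=Path("results/main_experiment"))
    args = parser.parse_args()
    cfg = PipelineConfig(seed=args.seed, outdir=str(args.outdir))
    scores_dir = stage_train(cfg, args.outdir / "features.csv", args.outdir)

    chosen = json.loads((args.outdir / "chosen_hyperparameters.json").read_text())
    print(f"score tables -> {scores_dir}")
    print("chosen hyperparameters (per family, threshold 5.0 mmol/L):")
    for fam, per_thr in chosen.items():
        print(f"  {fam}: {per_thr.get('5', per_thr)}")


if __name__ == "__main__":
    main()
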