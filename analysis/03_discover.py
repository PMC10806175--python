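#!/usr/bin/env python
"""Discovery phase on the training cohort: screen features by ROC
(AUC >= 0.7, p < 0.05), collapse correlated groups (|r| >= 0.7), train the
five classifiers on the group representatives, and derive the Youden cutoff
from the random-forest out-of-bag scores.

Writes results/screening.csv, results/groups.json,
results/selected_features.txt, results/training_roc.json and the trained
models to scratch/models.pkl.
"""

import argparse
import json
import pickle
from pathlib import Path

import pandas as pd

from radcrt.pipeline import PipelineConfig, discover

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    results = ROOT / "results"
    features = pd.read_csv(results / "features.csv", index_col="case_id")
    clinical = pd.read_csv(results / "clinical.csv", index_col="case_id")
    cfg = PipelineConfig.with_seed(args.seed)
    disc = discover(features, clinical, cfg)

    disc.screening.to_csv(results / "screening.csv")
    (results / "groups.json").write_text(json.dumps(
        {g.representative: list(g.members) for g in disc.groups}, indent=1))
    (results / "selected_features.txt").write_text("\n".join(disc.selected) + "\n")
    (results / "training_roc.json").write_text(json.dumps({
        "roc": {a: {"auc": r.auc, "ci95": r.ci95} for a, r in disc.training_roc.items()},
        "cutoff": disc.cutoff.threshold,
        "cutoff_metrics": disc.cutoff_metrics,
    }, indent=1))
    with open(ROOT / "scratch" / "models.pkl", "wb") as fh:
        pickle.dump({"models": disc.models, "cutoff": disc.cutoff,
                     "selected": disc.selected,
                     "training_scores": disc.training_scores}, fh)

    print(f"screened {len(disc.candidates)} candidate features "
          f"(AUC >= {cfg.selection.auc_threshold}) out of {features.shape[1]}")
    print(f"collapsed into {len(disc.groups)} correlation groups; "
          f"representatives: {', '.join(disc.selected[:6])}...")
    for alg, r in disc.training_roc.items():
        print(f"  {alg}: training AUC {r.auc:.3f} "
              f"[{r.ci95[0]:.2f}-{r.ci95[1]:.2f}]")
    print(f"Youden cutoff {disc.cutoff.threshold:.3f} "
          f"(sens {disc.cutoff_metrics['sensitivity']:.2f}, "
          f"spec {disc.cutoff_metrics['specificity']:.2f})")


if __name__ == "__main__":
    main()
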