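#!/usr/bin/env python
"""Validation phase: score the held-out cohort with the trained models,
compare ROC curves pairwise with DeLong's test and report the cutoff
metrics.

Writes results/model_comparison.json and results/scores.csv.
"""

import argparse
import json
import pickle
from pathlib import Path

import pandas as pd

from radcrt.pipeline import DiscoveryResult, PipelineConfig, validate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    results = ROOT / "results"
    features = pd.read_csv(results / "features.csv", index_col="case_id")
    clinical = pd.read_csv(results / "clinical.csv", index_col="case_id")
    with open(ROOT / "scratch" / "models.pkl", "rb") as fh:
        payload = pickle.load(fh)
    disc = DiscoveryResult(
        screening=pd.DataFrame(), candidates=[], groups=[],
        selected=payload["selected"], models=payload["models"],
        training_scores=payload["training_scores"], training_roc={},
        cutoff=payload["cutoff"], cutoff_metrics={})
    val = validate(disc, features, clinical, PipelineConfig.with_seed(args.seed))

    rows = [{"case_id": s.case_id, "algorithm": a, "score": s.score,
             "source": s.source}
            for a, ss in val.scores.items() for s in ss]
    pd.DataFrame(rows).to_csv(results / "scores.csv", index=False)
    (results / "model_comparison.json").write_text(json.dumps({
        "roc": {a: {"auc": r.auc, "ci95": r.ci95} for a, r in val.roc.items()},
        "delong_p": val.delong_matrix.round(4).to_dict(),
        "cutoff_metrics": val.cutoff_metrics,
        "best": val.best_algorithm,
    }, indent=1))

    for alg, r in val.roc.items():
        m = val.cutoff_metrics[alg]
        print(f"  {alg}: validation AUC {r.auc:.3f} "
              f"[{r.ci95[0]:.2f}-{r.ci95[1]:.2f}], "
              f"accuracy {100 * m['accuracy']:.1f}%")
    print(f"best model: {val.best_algorithm}")


if __name__ == "__main__":
    main()
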