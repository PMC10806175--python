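#!/usr/bin/env python
"""Development phase: stratify cases into high/low prediction-score groups
at the Youden cutoff and run the survival analysis (Kaplan-Meier medians,
log-rank, univariate and multivariate Cox) on the validation cohort and on
all cases.

Writes results/survival_report.json.
"""

import argparse
import json
import pickle
from pathlib import Path

import pandas as pd

from radcrt.pipeline import DiscoveryResult, PipelineConfig, prognosis, validate

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
    cfg = PipelineConfig.with_seed(args.seed)
    val = validate(disc, features, clinical, cfg)
    report = prognosis(disc, val, clinical, cfg)
    (results / "survival_report.json").write_text(
        json.dumps(report, indent=1, default=str))

    for section in ("validation", "all_cases"):
        rep = report[section]
        print(f"{section} (n={rep['n']}):")
        for ep, r in rep["endpoints"].items():
            high = r["median_high"] if r["median_high"] is not None else "not reached"
            print(f"  {ep.upper()}: median high {high} vs low "
                  f"{r['median_low']} months, log-rank p {r['logrank_p']:.4g}")
            sg = r["univariate"]["score_group"]
            if sg["hr"] is not None:
                print(f"    score group HR {sg['hr']:.2f} "
                      f"[{sg['ci'][0]:.2f}-{sg['ci'][1]:.2f}], p {sg['p']:.4g}")


if __name__ == "__main__":
    main()
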