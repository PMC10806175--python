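#!/usr/bin/env python
"""Extract the 476-feature radiomics vector for every case of the simulated
cohort (crop -> 3D wavelet -> 2 mm resample -> 25 HU requantization ->
shape/histogram/GLCM/GLRLM/GLSZM), reading the NIfTI files written by
01_simulate_cohort.py.

Writes results/features.csv (one row per case, 476 columns) and the feature
catalog to results/feature_catalog.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from radcrt.catalog import build_catalog
from radcrt.extract import extract_case, features_to_frame
from radcrt.preprocess import read_case

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser().parse_args()
    cohort = ROOT / "scratch" / "cohort"
    clinical = pd.read_csv(cohort / "clinical.csv", index_col="case_id")
    vectors = []
    for cid in clinical.index:
        vol, mask = read_case(cohort / "images" / f"{cid}.nii.gz",
                              cohort / "masks" / f"{cid}.nii.gz")
        vectors.append(extract_case(vol, mask, case_id=cid))
    frame = features_to_frame(vectors)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    frame.to_csv(results / "features.csv")
    (results / "feature_catalog.json").write_text(
        json.dumps(build_catalog().to_records(), indent=1))
    n_missing = int(frame.isna().any().sum())
    print(f"extracted {frame.shape[0]} cases x {frame.shape[1]} features "
          f"-> {results / 'features.csv'}")
    print(f"features carrying missing-value flags in >=1 case: {n_missing}")


if __name__ == "__main__":
    main()
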