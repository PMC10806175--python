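"""Three-phase orchestration: discovery (screen, group, train), validation
(held-out ROC, DeLong comparison, cutoff metrics) and development
(prognosis on the validation cohort and on all cases).

One seed controls the synthetic cohort, classifier training and every
report, so a full run is reproducible bit-for-bit.  All functions work on
in-memory frames; the CLI layer adds the on-disk artifact handling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .extract import ExtractionConfig, extract_case, features_to_frame
from .models import ALGORITHMS, PredictionScore, delong_compare, evaluate_roc, score_cases, train
from .roc import CutoffRule, youden_cutoff
from .selection import SelectionConfig, correlation_group, screen_features, screening_table
from .survival import run_prognosis
from .synthetic import CohortBundle, CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "DiscoveryResult", "ValidationResult",
           "extract_cohort", "discover", "validate", "prognosis", "run_all"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs with the study-protocol defaults."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    algorithms: tuple[str, ...] = ALGORITHMS
    seed: int = 0
    survival_alpha: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def with_seed(cls, seed: int, **overrides) -> "PipelineConfig":
        cohort = overrides.pop("cohort", None) or CohortConfig(seed=seed)
        return cls(cohort=cohort, seed=seed, **overrides)


@dataclass
class DiscoveryResult:
    screening: pd.DataFrame
    candidates: list[str]
    groups: list
    selected: list[str]
    models: dict
    training_scores: dict[str, list[PredictionScore]]
    training_roc: dict
    cutoff: CutoffRule
    cutoff_metrics: dict


@dataclass
class ValidationResult:
    scores: dict[str, list[PredictionScore]]
    roc: dict
    delong_matrix: pd.DataFrame
    cutoff_metrics: dict
    best_algorithm: str


def extract_cohort(bundle: CohortBundle,
                   config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Extract the 476-feature vector for every case of a cohort bundle."""
    vectors = [
        extract_case(bundle.volumes[cid], bundle.masks[cid],
                     config=config, case_id=cid)
        for cid in bundle.clinical.index
    ]
    return features_to_frame(vectors)


def _cohort_split(features: pd.DataFrame, clinical: pd.DataFrame):
    train_ids = clinical.index[clinical["cohort"] == "training"]
    val_ids = clinical.index[clinical["cohort"] == "validation"]
    return features.loc[train_ids], features.loc[val_ids]


def discover(features: pd.DataFrame, clinical: pd.DataFrame,
             config: PipelineConfig) -> DiscoveryResult:
    """Discovery phase on the training cohort: screen features, collapse
    correlated groups, train the five classifiers and derive the Youden
    cutoff from the random-forest training (out-of-bag) scores."""
    x_train, _ = _cohort_split(features, clinical)
    y_train = clinical.loc[x_train.index, "response"].to_numpy(dtype=int)
    if y_train.sum() < 2:
        raise ValueError("discovery needs at least 2 responders in training")

    scr = screening_table(x_train, y_train)
    candidates = screen_features(x_train, y_train, config.selection)
    groups = correlation_group(x_train, candidates, y_train, config.selection)
    selected = [g.representative for g in groups]
    if not selected:
        raise ValueError("no feature survived screening; cannot train models")

    models = {}
    training_scores = {}
    training_roc = {}
    for alg in config.algorithms:
        m = train(alg, x_train[selected], y_train, seed=config.seed)
        s = score_cases(m, x_train[selected])
        models[alg] = m
        training_scores[alg] = s
        training_roc[alg] = evaluate_roc(s, y_train)

    rf_like = "RF" if "RF" in models else list(models)[0]
    cutoff, metrics = youden_cutoff(
        [s.score for s in training_scores[rf_like]], y_train
    )
    return DiscoveryResult(scr, candidates, groups, selected, models,
                           training_scores, training_roc, cutoff, metrics)


def validate(disc: DiscoveryResult, features: pd.DataFrame,
             clinical: pd.DataFrame, config: PipelineConfig) -> ValidationResult:
    """Validation phase: held-out scores, per-model ROC, the pairwise DeLong
    matrix and cutoff metrics, with a train/validation leakage guard."""
    _, x_val = _cohort_split(features, clinical)
    y_val = clinical.loc[x_val.index, "response"].to_numpy(dtype=int)
    train_ids = set(next(iter(disc.models.values())).training_index)
    overlap = train_ids & set(x_val.index)
    if overlap:
        raise ValueError(f"leakage: cases in both cohorts: {sorted(overlap)[:5]}")

    scores = {alg: score_cases(m, x_val[disc.selected])
              for alg, m in disc.models.items()}
    roc = {alg: evaluate_roc(s, y_val) for alg, s in scores.items()}
    algs = list(disc.models)
    mat = pd.DataFrame(np.ones((len(algs), len(algs))), index=algs, columns=algs)
    for i, a in enumerate(algs):
        for b in algs[i + 1:]:
            p = delong_compare(scores[a], scores[b], y_val)
            mat.loc[a, b] = mat.loc[b, a] = p

    cutoff_metrics = {}
    for alg, s in scores.items():
        pred = disc.cutoff.apply([x.score for x in s])
        sens = float(pred[y_val == 1].mean()) if (y_val == 1).any() else float("nan")
        spec = float((1 - pred[y_val == 0]).mean()) if (y_val == 0).any() else float("nan")
        acc = float((pred == y_val).mean())
        cutoff_metrics[alg] = {"sensitivity": sens, "specificity": spec,
                               "accuracy": acc}
    best = max(algs, key=lambda a: roc[a].auc)
    return ValidationResult(scores, roc, mat, cutoff_metrics, best)


def prognosis(disc: DiscoveryResult, val: ValidationResult,
              clinical: pd.DataFrame, config: PipelineConfig,
              algorithm: str | None = None) -> dict:
    """Development phase: KM/log-rank/Cox reports on the validation cohort
    and on all cases, stratified by the Youden cutoff of the chosen model
    (training cases use out-of-bag scores, validation cases held-out ones).
    """
    alg = algorithm or ("RF" if "RF" in disc.models else val.best_algorithm)
    score_map = {s.case_id: s.score for s in disc.training_scores[alg]}
    score_map.update({s.case_id: s.score for s in val.scores[alg]})
    scores = pd.Series(score_map).reindex(clinical.index)
    if scores.isna().any():
        missing = list(clinical.index[scores.isna()])[:5]
        raise ValueError(f"cases without a prediction score: {missing}")
    for col in ("pfs_months", "pfs_event", "os_months", "os_event"):
        if col not in clinical.columns:
            raise ValueError(f"clinical table lacks survival column {col!r}")

    val_clin = clinical[clinical["cohort"] == "validation"]
    report = {
        "algorithm": alg,
        "threshold": disc.cutoff.threshold,
        "validation": run_prognosis(val_clin, scores.loc[val_clin.index],
                                    disc.cutoff.threshold,
                                    alpha=config.survival_alpha),
        "all_cases": run_prognosis(clinical, scores,
                                   disc.cutoff.threshold,
                                   alpha=config.survival_alpha),
    }
    return report


def run_all(config: PipelineConfig, out_dir=None) -> dict:
    """Simulate, extract, discover, validate and run prognosis in one call."""
    bundle = generate_cohort(config.cohort, out_dir=out_dir)
    features = extract_cohort(bundle, config.extraction)
    disc = discover(features, bundle.clinical, config)
    val = validate(disc, features, bundle.clinical, config)
    prog = prognosis(disc, val, bundle.clinical, config)
    return {
        "bundle": bundle,
        "features": features,
        "discovery": disc,
        "validation": val,
        "prognosis": prog,
    }
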