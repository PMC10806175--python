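"""ROC primitives shared by feature screening and model comparison:
Mann-Whitney AUC with rank-sum p-value, DeLong variance/CI, the paired
DeLong test, and the Youden-index cutoff.

The DeLong machinery is implemented here from the structural-component
formulation (placement values), since no installed package exposes it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "CutoffRule",
    "auc_with_p",
    "delong_test",
    "youden_cutoff",
]


@dataclass(frozen=True)
class ROCResult:
    """AUC with its rank-sum p-value and DeLong 95% confidence interval."""

    auc: float
    p_value: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
            raise ValueError(f"CI {self.ci95} does not bracket AUC {self.auc}")


@dataclass(frozen=True)
class CutoffRule:
    """Score threshold with the convention score >= threshold -> positive."""

    threshold: float

    def apply(self, scores: np.ndarray) -> np.ndarray:
        return (np.asarray(scores, dtype=float) >= self.threshold).astype(int)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (per positive), V01 (per negative)."""
    m, n = len(pos), len(neg)
    # pairwise comparison with ties counting 1/2
    cmp = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp.mean())
    v10 = cmp.mean(axis=1)  # length m
    v01 = cmp.mean(axis=0)  # length n
    return v10, v01, auc


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _split(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            f"need both classes: {len(pos)} positives, {len(neg)} negatives"
        )
    return pos, neg


def auc_with_p(values, labels) -> ROCResult:
    """Mann-Whitney c-statistic, two-sided tie-corrected rank-sum p, and
    DeLong 95% CI (clipped to [0, 1])."""
    pos, neg = _split(values, labels)
    v10, v01, auc = _placements(pos, neg)
    # two-sided normal-approximated rank-sum p with tie correction
    pooled = np.concatenate([pos, neg])
    if np.ptp(pooled) == 0:
        p = 1.0
    else:
        res = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
    var = _delong_variance(v10, v01)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return ROCResult(auc, p, ci, len(pos), len(neg))


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided p-value of DeLong's paired test for the AUC difference of
    two scorers evaluated on the same cases.

    Identical score rankings (zero variance of the difference) return
    p = 1 by convention.
    """
    labels = np.asarray(labels).astype(int)
    a_pos, a_neg = _split(scores_a, labels)
    b_pos, b_neg = _split(scores_b, labels)
    va10, va01, auc_a = _placements(a_pos, a_neg)
    vb10, vb01, auc_b = _placements(b_pos, b_neg)
    m, n = len(va10), len(va01)
    if m > 1:
        s10 = np.cov(np.vstack([va10, vb10]))  # 2x2
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([va01, vb01]))
    else:
        s01 = np.zeros((2, 2))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var_diff <= 0:
        logger.info("DeLong test: zero variance of the AUC difference "
                    "(identical rankings); p = 1 by convention")
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))


def youden_cutoff(scores, labels) -> tuple[CutoffRule, dict]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive distinct
    observed scores; ties in J are broken toward higher sensitivity (the
    lower threshold).  Returns the rule and the metrics at that threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _split(scores, labels)  # class presence check
    uniq = np.unique(scores)
    if len(uniq) == 1:
        warnings.warn("all scores identical; Youden J = 0, degenerate cutoff")
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for thr in candidates:
        pred = scores >= thr
        sens = float(pred[labels == 1].mean())
        spec = float((~pred[labels == 0]).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    j, thr, sens, spec = best
    pred = scores >= thr
    acc = float((pred == labels.astype(bool)).mean())
    return CutoffRule(float(thr)), {
        "youden_j": j,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
    }
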