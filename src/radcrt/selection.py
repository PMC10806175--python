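"""Discovery-phase feature selection: per-feature ROC screening followed by
Pearson-correlation redundancy grouping with highest-AUC representatives.

Screening keeps features with AUC >= 0.7 and rank-sum p < 0.05 (the raw,
unflipped AUC: features predictive only in the negative direction are
excluded, matching the literal screening rule; enable ``two_sided`` to
screen on max(AUC, 1 - AUC) instead).  Grouping then walks the survivors in
descending-AUC order and merges each feature into the first group whose
representative correlates with it at |r| >= 0.7 (p < 0.05); a feature that
matches no group founds a new one and becomes its representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .roc import ROCResult, auc_with_p

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "FeatureGroup",
    "screen_features",
    "correlation_group",
    "screening_table",
]


@dataclass(frozen=True)
class SelectionConfig:
    auc_threshold: float = 0.7
    alpha: float = 0.05
    r_threshold: float = 0.7
    method: str = "greedy"  # or "connected"
    two_sided: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        for name in ("auc_threshold", "r_threshold"):
            v = getattr(self, name)
            # values above 1 are allowed: they simply select nothing
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.method not in ("greedy", "connected"):
            raise ValueError(f"unknown grouping method {self.method!r}")


@dataclass(frozen=True)
class FeatureGroup:
    """A cluster of mutually redundant features and its best member."""

    representative: str
    members: tuple[str, ...]
    representative_auc: float

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be one of the members")


def screening_table(table: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-feature ROC results as a frame (auc, p, ci_low, ci_high).

    Features carrying missing-value flags (NaN) are dropped with a warning.
    """
    labels = np.asarray(labels).astype(int)
    rows = {}
    dropped = []
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            dropped.append(col)
            continue
        r: ROCResult = auc_with_p(vals, labels)
        rows[col] = (r.auc, r.p_value, r.ci95[0], r.ci95[1])
    if dropped:
        logger.warning("dropped %d feature(s) with missing values: %s%s",
                       len(dropped), dropped[:5],
                       "..." if len(dropped) > 5 else "")
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["auc", "p", "ci_low", "ci_high"]
    )
    frame.index.name = "feature"
    return frame


def screen_features(table: pd.DataFrame, labels,
                    config: SelectionConfig | None = None) -> list[str]:
    """Feature ids passing the AUC/p screen, sorted by descending AUC
    (ties broken lexicographically by id)."""
    cfg = config or SelectionConfig()
    scr = screening_table(table, labels)
    auc = scr["auc"]
    if cfg.two_sided:
        auc = np.maximum(auc, 1.0 - auc)
    keep = scr[(auc >= cfg.auc_threshold) & (scr["p"] < cfg.alpha)]
    if keep.empty:
        logger.warning("no feature passed the AUC >= %.2f / p < %.2f screen",
                       cfg.auc_threshold, cfg.alpha)
        return []
    order = sorted(keep.index, key=lambda f: (-keep.loc[f, "auc"], f))
    return order


def _corr_ok(x: np.ndarray, y: np.ndarray, cfg: SelectionConfig) -> bool:
    if x.std() == 0 or y.std() == 0:
        return False
    r, p = stats.pearsonr(x, y)
    return abs(r) >= cfg.r_threshold and p < cfg.alpha


def correlation_group(table: pd.DataFrame, candidates: list[str], labels,
                      config: SelectionConfig | None = None) -> list[FeatureGroup]:
    """Group redundant candidates; return groups with their representatives.

    ``candidates`` must be sorted by descending AUC (as from
    :func:`screen_features`).  The default greedy policy assigns each
    feature to the first group whose *representative* it matches; the
    ``connected`` variant instead takes connected components of the
    |r| >= threshold graph and picks the highest-AUC member of each.
    """
    cfg = config or SelectionConfig()
    labels = np.asarray(labels).astype(int)
    if not candidates:
        return []
    aucs = {f: auc_with_p(table[f].to_numpy(dtype=float), labels).auc
            for f in candidates}
    cols = {f: table[f].to_numpy(dtype=float) for f in candidates}
    for f in candidates:
        if cols[f].std() == 0:
            logger.warning("feature %s is constant; correlation undefined, "
                           "it forms its own group", f)

    if cfg.method == "connected":
        import networkx as nx  # stdlib-adjacent; used only for this variant

        g = nx.Graph()
        g.add_nodes_from(candidates)
        for i, f in enumerate(candidates):
            for h in candidates[i + 1:]:
                if _corr_ok(cols[f], cols[h], cfg):
                    g.add_edge(f, h)
        groups = []
        for comp in nx.connected_components(g):
            members = sorted(comp, key=lambda f: (-aucs[f], f))
            groups.append(FeatureGroup(members[0], tuple(members), aucs[members[0]]))
        groups.sort(key=lambda gr: (-gr.representative_auc, gr.representative))
        return groups

    groups: list[dict] = []
    for f in candidates:  # already in descending-AUC order
        placed = False
        for grp in groups:
            if _corr_ok(cols[f], cols[grp["rep"]], cfg):
                grp["members"].append(f)
                placed = True
                break
        if not placed:
            groups.append({"rep": f, "members": [f]})
    return [
        FeatureGroup(g["rep"], tuple(g["members"]), aucs[g["rep"]])
        for g in groups
    ]
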