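"""Correlation-based feature selection with redundancy pruning.

A feature is retained when its Pearson correlation with the binary FOG label
(point-biserial, since the label is 0/1) satisfies |r| >= threshold with
p < 0.05; the threshold is 0.35 for the subject-independent analysis (at
least moderate correlation) and 0.4 for the subject-dependent one. Absolute
correlation is used: strongly negatively correlated features (e.g. locomotion
band power, which drops during FOG) are as informative as positive ones.

Redundant features — pairwise |r| >= 0.86 between feature columns — are then
pruned greedily in descending |label r|: the strongest candidate is kept and
claims (removes) every remaining candidate redundant with it. Ties are broken
by feature name, making the result invariant to column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SIA_R_THRESHOLD = 0.35
SDA_R_THRESHOLD = 0.4
P_THRESHOLD = 0.05
CROSS_R_THRESHOLD = 0.86


@dataclass
class SelectionResult:
    """Outcome of selection: retained names, per-feature statistics, prunes."""

    retained: list[str]
    r: pd.Series
    p: pd.Series
    dropped_redundant: list[tuple[str, str, float]] = field(default_factory=list)
    mode: str = "SIA"

    def to_frame(self) -> pd.DataFrame:
        replaced_by = {d: k for d, k, _ in self.dropped_redundant}
        return pd.DataFrame(
            {
                "feature": self.r.index,
                "r": self.r.values,
                "p": self.p.values,
                "retained": [f in set(self.retained) for f in self.r.index],
                "replaced_by": [replaced_by.get(f, "") for f in self.r.index],
            }
        )


def pointbiserial(features: pd.DataFrame, labels: np.ndarray) -> tuple[pd.Series, pd.Series]:
    """Pearson r of every column against the 0/1 label, with two-sided
    p-values from the exact t-transform (n - 2 degrees of freedom)."""
    y = np.asarray(labels, dtype=float)
    n = y.size
    if n != len(features):
        raise ValueError("labels misaligned with feature rows")
    X = features.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(sx > 0, (Xc * yc[:, None]).sum(axis=0) / np.where(sx > 0, sx, 1.0) / sy, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return (
        pd.Series(r, index=features.columns),
        pd.Series(p, index=features.columns),
    )


def correlation_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    r_thresh: float = SIA_R_THRESHOLD,
    p_thresh: float = P_THRESHOLD,
    mode: str = "SIA",
) -> SelectionResult:
    """Retain columns with |r| >= r_thresh (inclusive) and p < p_thresh."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("selection requires both classes among the labels")
    r, p = pointbiserial(features, labels)
    retained = [
        c for c in features.columns
        if abs(r[c]) >= r_thresh and p[c] < p_thresh and np.isfinite(r[c])
    ]
    return SelectionResult(retained, r, p, mode=mode)


def redundancy_prune(
    features: pd.DataFrame,
    selection: SelectionResult,
    cross_thresh: float = CROSS_R_THRESHOLD,
) -> SelectionResult:
    """Greedy redundancy pruning among the retained features.

    Candidates are visited in descending |label r| (ties by name); a visited
    candidate is kept iff its cross-correlation with every already-kept
    feature stays below the threshold, so no retained pair is redundant.
    """
    cand = sorted(selection.retained, key=lambda c: (-abs(selection.r[c]), c))
    if not cand:
        return SelectionResult([], selection.r, selection.p, [], selection.mode)
    X = features[cand].to_numpy(dtype=float)
    C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    kept_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for i in range(len(cand)):
        partner = None
        for j in kept_idx:
            if abs(C[i, j]) >= cross_thresh:
                partner = j
                break
        if partner is None:
            kept_idx.append(i)
        else:
            dropped.append((cand[i], cand[partner], float(C[i, partner])))
    return SelectionResult(
        [cand[i] for i in kept_idx], selection.r, selection.p, dropped,
        selection.mode,
    )


def select_features(
    features: pd.DataFrame,
    labels: np.ndarray,
    mode: str = "SIA",
    r_thresh: float | None = None,
    p_thresh: float = P_THRESHOLD,
    cross_thresh: float = CROSS_R_THRESHOLD,
) -> SelectionResult:
    """Full selection: correlation thresholding then redundancy pruning."""
    if r_thresh is None:
        r_thresh = SIA_R_THRESHOLD if mode == "SIA" else SDA_R_THRESHOLD
    pre = correlation_select(features, labels, r_thresh, p_thresh, mode)
    return redundancy_prune(features, pre, cross_thresh)


__all__ = [
    "SIA_R_THRESHOLD",
    "SDA_R_THRESHOLD",
    "P_THRESHOLD",
    "CROSS_R_THRESHOLD",
    "SelectionResult",
    "pointbiserial",
    "correlation_select",
    "redundancy_prune",
    "select_features",
]
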