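"""Group-wise accuracy and bias diagnostics.

The central metric is the predictive coefficient of determination (COD)
with a pooled training denominator: for group g,
``COD_g = 1 - SSE_g / SST`` where ``SSE_g = mean((y - y_hat)^2)`` over the
group's test subjects and ``SST = mean((y_j - mean(y))^2)`` over the pooled
matched training subjects of both compared groups — the total behavioral
variance learned from the training set, deliberately not group-specific.
Both use population (1/N) denominators.

The companion diagnostics explain why COD and Pearson correlation can
disagree: a group-wise *prediction shift* (squared mean signed error) raises
SSE without touching r, and a larger true-score *behavioral variance* in one
group raises its SSE against the shared SST; Levene's test flags the latter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupAccuracy",
    "training_sst",
    "predictive_cod",
    "pearson_accuracy",
    "prediction_shift",
    "levene_test",
    "summarize_groups",
]


@dataclass
class GroupAccuracy:
    """Accuracy/bias summary for one group in one evaluation unit."""

    group: str
    sse: float
    sst: float
    predictive_cod: float
    pearson_r: float
    prediction_shift: float
    behavioral_variance: float
    n: int


def training_sst(y_train_matched: np.ndarray) -> float:
    """Pooled training variance (population denominator) of the matched
    training subjects of both compared groups."""
    y = np.asarray(y_train_matched, float)
    if y.size < 2:
        raise ValueError("need >= 2 training subjects")
    sst = float(np.mean((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("constant training scores: SST = 0, COD undefined")
    return sst


def predictive_cod(y_true: np.ndarray, y_pred: np.ndarray, sst: float) -> float:
    """1 - mean squared error / SST; unbounded below."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    if sst <= 0:
        raise ValueError("sst must be > 0")
    return float(1.0 - np.mean((y_true - y_pred) ** 2) / sst)


def pearson_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Sample Pearson r; NaN (with a warning) when either vector is constant."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        warnings.warn("constant vector: Pearson accuracy undefined")
        return float("nan")
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def prediction_shift(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Square of the mean signed prediction error, (mean(y_hat - y))^2."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    return float(np.mean(y_pred - y_true) ** 2)


def levene_test(y_a: np.ndarray, y_b: np.ndarray) -> tuple[float, float]:
    """Levene's W for equality of variances, mean-centered (original Levene).

    Degenerate case: when both groups' absolute deviations are constant but
    differ between groups, W diverges; reported as (inf, 0.0) — a rejection.
    """
    y_a = np.asarray(y_a, float)
    y_b = np.asarray(y_b, float)
    if y_a.size < 2 or y_b.size < 2:
        raise ValueError("each group needs n >= 2")
    da = np.abs(y_a - y_a.mean())
    db = np.abs(y_b - y_b.mean())
    within = np.sum((da - da.mean()) ** 2) + np.sum((db - db.mean()) ** 2)
    if within == 0.0:
        if da.mean() == db.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    W, p = stats.levene(y_a, y_b, center="mean")
    return float(W), float(p)


def behavioral_variance(y: np.ndarray) -> float:
    """Population-denominator variance of the true scores."""
    y = np.asarray(y, float)
    return float(np.mean((y - y.mean()) ** 2))


def _group_accuracy(
    y_true: np.ndarray, y_pred: np.ndarray, sst: float, group: str
) -> GroupAccuracy:
    sse = float(np.mean((y_true - y_pred) ** 2))
    r = pearson_accuracy(y_true, y_pred) if y_true.size >= 3 else float("nan")
    return GroupAccuracy(
        group=group,
        sse=sse,
        sst=sst,
        predictive_cod=1.0 - sse / sst,
        pearson_r=r,
        prediction_shift=prediction_shift(y_true, y_pred),
        behavioral_variance=behavioral_variance(y_true),
        n=int(y_true.size),
    )


def summarize_groups(
    result,
    design,
    groups: tuple[str, str] = ("minority", "majority"),
) -> pd.DataFrame:
    """Per-split GroupAccuracy rows for each matched group.

    Only matched test subjects enter the group metrics. For the single-site
    scheme, metrics are computed per fold with that fold's SST and averaged
    across folds within each split; multi-site per-split values are emitted
    directly. Columns: split, group, sse, sst, predictive_cod, pearson_r,
    prediction_shift, behavioral_variance, n.
    """
    table = result.table
    rows = []
    for split in sorted(table["split"].unique()):
        sub = table[table["split"] == split]
        pairs = design.pairs[split if design.scheme == "hcp_splits" else 0]
        matched_of = {g: set() for g in groups}
        for a, b in pairs:
            matched_of[groups[0]].add(a)
            matched_of[groups[1]].add(b)
        per_fold: dict[str, list[GroupAccuracy]] = {g: [] for g in groups}
        for fold in sorted(sub["fold"].unique()):
            fsub = sub[sub["fold"] == fold]
            sst = result.split_meta[split]["sst"][
                fold if design.scheme == "hcp_splits" else 0
            ]
            for g in groups:
                gsub = fsub[
                    (fsub["group"] == g)
                    & fsub["subject_id"].isin(matched_of[g])
                ]
                if gsub.empty:
                    raise ValueError(
                        f"group {g!r} missing from split {split} fold {fold}"
                    )
                per_fold[g].append(
                    _group_accuracy(
                        gsub["y_true"].to_numpy(),
                        gsub["y_pred"].to_numpy(),
                        sst,
                        g,
                    )
                )
        for g in groups:
            accs = per_fold[g]
            rows.append(
                {
                    "split": split,
                    "group": g,
                    "sse": float(np.mean([a.sse for a in accs])),
                    "sst": float(np.mean([a.sst for a in accs])),
                    "predictive_cod": float(
                        np.mean([a.predictive_cod for a in accs])
                    ),
                    "pearson_r": float(np.nanmean([a.pearson_r for a in accs])),
                    "prediction_shift": float(
                        np.mean([a.prediction_shift for a in accs])
                    ),
                    "behavioral_variance": float(
                        np.mean([a.behavioral_variance for a in accs])
                    ),
                    "n": int(np.sum([a.n for a in accs])),
                }
            )
    return pd.DataFrame(rows)
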