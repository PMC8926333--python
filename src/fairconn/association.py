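"""Brain-behavior association patterns and their validity.

Kernel ridge weights are not directly interpretable; the Haufe-style
inversion recovers an interpretable pattern as the covariance between each
(demeaned) FC edge and the model's in-sample predictions — the
*model-learned* association. The *true* association of a group is the
per-edge covariance with the group's observed test scores. The Pearson
correlation across edges between learned and true maps is the pattern
validity; its group difference is related to the group accuracy difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssociationMap",
    "model_learned_association",
    "true_association",
    "association_similarity",
    "similarity_accuracy_relation",
]


@dataclass
class AssociationMap:
    """Per-edge covariance vector with provenance."""

    values: np.ndarray
    source: str  # model_learned | true_group
    group: str | None = None
    split: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.isfinite(self.values).all():
            raise ValueError("association map must be finite")


def _edge_covariance(fc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-edge population-denominator covariance, both arguments demeaned."""
    fc = np.asarray(fc, float)
    y = np.asarray(y, float)
    if fc.shape[0] != y.size:
        raise ValueError("subject counts differ between FC and scores")
    fc_c = fc - fc.mean(axis=0)
    y_c = y - y.mean()
    return fc_c.T @ y_c / y.size


def model_learned_association(
    train_fc: np.ndarray, y_pred_train: np.ndarray, split: int | None = None
) -> AssociationMap:
    """Covariance of each training FC edge with the in-sample predictions."""
    return AssociationMap(
        values=_edge_covariance(train_fc, y_pred_train),
        source="model_learned",
        split=split,
    )


def true_association(
    test_fc_group: np.ndarray,
    y_true_group: np.ndarray,
    group: str,
    split: int | None = None,
) -> AssociationMap:
    """Covariance of each test-group FC edge with the observed scores."""
    if np.asarray(y_true_group).size < 3:
        raise ValueError("need >= 3 group test subjects")
    return AssociationMap(
        values=_edge_covariance(test_fc_group, y_true_group),
        source="true_group",
        group=group,
        split=split,
    )


def association_similarity(map_a: AssociationMap, map_b: AssociationMap) -> float:
    """Pearson correlation across edges between two maps; NaN when either is
    constant (scale- and positive-rescaling-invariant otherwise)."""
    a, b = map_a.values, map_b.values
    if a.size != b.size:
        raise ValueError("maps differ in edge count")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant association map: similarity undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def similarity_accuracy_relation(
    per_behavior: dict[str, tuple[float, float]],
) -> tuple[float, pd.DataFrame]:
    """Cross-behavior relation between pattern-validity and accuracy gaps.

    ``per_behavior`` maps behavior → (delta_similarity, delta_accuracy),
    where delta_similarity = sim(learned, true_majority) − sim(learned,
    true_minority) and delta_accuracy = COD_majority − COD_minority
    (split-averaged). Returns their Pearson correlation and the scatter
    table; behaviors with missing values are dropped with a warning, and a
    constant delta yields NaN.
    """
    rows = []
    for name, (dsim, dacc) in per_behavior.items():
        if not (np.isfinite(dsim) and np.isfinite(dacc)):
            warnings.warn(f"behavior {name!r} dropped: missing values")
            continue
        rows.append({"behavior": name, "delta_similarity": dsim,
                     "delta_accuracy": dacc})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need >= 3 behaviors with complete values")
    ds = table["delta_similarity"].to_numpy()
    da = table["delta_accuracy"].to_numpy()
    if np.std(ds) == 0 or np.std(da) == 0:
        warnings.warn("constant deltas: correlation undefined")
        return float("nan"), table
    return float(np.corrcoef(ds, da)[0, 1]), table
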