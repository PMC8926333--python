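"""Confound regression and ridge-family prediction of behavior from FC.

The predictor is kernel ridge regression with a correlation kernel: the
similarity of two participants is the Pearson correlation of their
vectorized FC, and a test participant's score is predicted as a
regularization-weighted average of training participants' scores,
``alpha = (K + lambda I)^{-1} y``, ``y_hat = K_test,train alpha``. Linear
ridge regression on the edge features is the auxiliary primal counterpart
(identical to kernel ridge with the linear kernel at matched lambda).

Confounds are regressed from both the behavioral score and every FC edge,
with coefficients estimated on training subjects only and applied to test
subjects (fit-on-train / apply-to-test; whole-sample residualization would
leak test information into training).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .matching import MatchedDesign

__all__ = [
    "ConfoundModel",
    "KernelModel",
    "PredictionResult",
    "fit_confound_model",
    "apply_confound_model",
    "correlation_kernel",
    "fit_krr",
    "predict_krr",
    "fit_linear_ridge",
    "predict_linear_ridge",
    "nested_cv_select_lambda",
    "default_lambda_grid",
    "subsample_training_population",
    "run_prediction",
    "abcd_split_folds",
]


@dataclass
class ConfoundModel:
    """OLS fits of the target and every FC edge on the confound matrix."""

    names: list[str]
    y_coef: np.ndarray  # (n_confounds + 1,), intercept first
    fc_coef: np.ndarray  # (n_confounds + 1, n_edges)


@dataclass
class KernelModel:
    """Fitted kernel (or linear) ridge predictor."""

    lam: float
    dual_coef: np.ndarray
    training_fc: np.ndarray
    training_y: np.ndarray
    kernel: str = "correlation"
    confound_model: ConfoundModel | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.dual_coef.shape[0] != self.training_y.shape[0]:
            raise ValueError("dual coefficient length must equal training count")


def _design(confounds: np.ndarray) -> np.ndarray:
    confounds = np.atleast_2d(np.asarray(confounds, float))
    return np.column_stack([np.ones(confounds.shape[0]), confounds])


def fit_confound_model(
    train_y: np.ndarray,
    train_fc: np.ndarray,
    train_confounds: np.ndarray,
    names: Sequence[str] | None = None,
) -> ConfoundModel:
    """OLS of the score and of each edge on the confounds (with intercept),
    on training subjects only."""
    X = _design(train_confounds)
    n, k = X.shape
    if n < k + 1:
        raise ValueError("need at least n_confounds + 2 training subjects")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        labels = list(names) if names else [f"c{i}" for i in range(k - 1)]
        # pinpoint columns whose removal restores full column rank
        collinear = [
            labels[j - 1]
            for j in range(1, k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient confound matrix; collinear: {collinear}")
    y_coef, *_ = np.linalg.lstsq(X, np.asarray(train_y, float), rcond=None)
    fc_coef, *_ = np.linalg.lstsq(X, np.asarray(train_fc, float), rcond=None)
    return ConfoundModel(
        names=list(names) if names else [f"c{i}" for i in range(k - 1)],
        y_coef=y_coef,
        fc_coef=fc_coef,
    )


def apply_confound_model(
    model: ConfoundModel,
    y: np.ndarray,
    fc: np.ndarray,
    confounds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the training-estimated confound fits from supplied data."""
    X = _design(confounds)
    if X.shape[1] != model.y_coef.shape[0]:
        raise ValueError("confound column count does not match fitted model")
    return (
        np.asarray(y, float) - X @ model.y_coef,
        np.asarray(fc, float) - X @ model.fc_coef,
    )


def correlation_kernel(fc_a: np.ndarray, fc_b: np.ndarray) -> np.ndarray:
    """Entry (s, i) = Pearson correlation of subject s's and i's FC vectors."""
    fc_a = np.atleast_2d(np.asarray(fc_a, float))
    fc_b = np.atleast_2d(np.asarray(fc_b, float))
    if fc_a.shape[1] != fc_b.shape[1] or fc_a.shape[1] < 2:
        raise ValueError("FC matrices must share an edge count >= 2")

    def _standardize(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(c, axis=1, keepdims=True)
        if (norm == 0).any():
            raise ValueError("zero-variance FC row")
        return c / norm

    return np.clip(_standardize(fc_a) @ _standardize(fc_b).T, -1.0, 1.0)


def fit_krr(kernel_train: np.ndarray, y_train: np.ndarray, lam: float) -> np.ndarray:
    """Dual coefficients solving (K + lambda I) alpha = y."""
    K = np.asarray(kernel_train, float)
    y = np.asarray(y_train, float)
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if not (np.isfinite(K).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    A = K + lam * np.eye(K.shape[0])
    try:
        return scipy.linalg.solve(A, y, assume_a="pos")
    except np.linalg.LinAlgError:  # kernel indefinite at tiny lambda
        return scipy.linalg.solve(A, y, assume_a="sym")


def predict_krr(model: KernelModel, kernel_test_train: np.ndarray) -> np.ndarray:
    K = np.atleast_2d(np.asarray(kernel_test_train, float))
    if K.shape[1] != model.dual_coef.shape[0]:
        raise ValueError("kernel column count must equal training count")
    return K @ model.dual_coef


def fit_linear_ridge(fc_train: np.ndarray, y_train: np.ndarray, lam: float) -> np.ndarray:
    """Primal ridge weights solving (X'X + lambda I) w = X'y."""
    X = np.asarray(fc_train, float)
    y = np.asarray(y_train, float)
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    p = X.shape[1]
    return scipy.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y, assume_a="pos")


def predict_linear_ridge(weights: np.ndarray, fc: np.ndarray) -> np.ndarray:
    return np.asarray(fc, float) @ np.asarray(weights, float)


def default_lambda_grid(n_train: int) -> np.ndarray:
    """15 log-spaced values in [1e-3, 1e3] scaled by training size."""
    return n_train * np.logspace(-3, 3, 15)


def _inner_group_folds(
    groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Family/site-preserving fold index lists, sizes balanced greedily."""
    uniq: dict = {}
    for i, g in enumerate(groups):
        uniq.setdefault(g, []).append(i)
    keys = list(uniq)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(uniq[k]))
    n_folds = min(n_folds, len(keys))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for k in keys:
        sizes = [len(f) for f in folds]
        folds[int(np.argmin(sizes))].extend(uniq[k])
    return [np.asarray(sorted(f), int) for f in folds]


def nested_cv_select_lambda(
    fc_train: np.ndarray,
    y_train: np.ndarray,
    grid: Sequence[float],
    groups: np.ndarray | None = None,
    n_folds: int = 10,
    kernel: str = "correlation",
    metric: str = "cod",
    seed: int = 0,
) -> float:
    """Inner-CV selection of the ridge penalty.

    For each lambda, predictions for all inner-validation subjects are pooled
    across the inner folds and scored (predictive COD against the inner
    training variance by default, Pearson r when ``metric='correlation'``);
    the best lambda wins, ties going to the smallest.
    """
    grid = np.asarray(list(grid), float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    fc_train = np.asarray(fc_train, float)
    y_train = np.asarray(y_train, float)
    n = y_train.size
    if groups is None:
        groups = np.arange(n)
    rng = np.random.default_rng(seed)
    folds = _inner_group_folds(np.asarray(groups), n_folds, rng)

    K_full = (
        correlation_kernel(fc_train, fc_train)
        if kernel == "correlation"
        else fc_train @ fc_train.T
    )
    preds = np.zeros((grid.size, n))
    for val_idx in folds:
        tr_idx = np.setdiff1d(np.arange(n), val_idx)
        K_tr = K_full[np.ix_(tr_idx, tr_idx)]
        K_val = K_full[np.ix_(val_idx, tr_idx)]
        for gi, lam in enumerate(grid):
            alpha = fit_krr(K_tr, y_train[tr_idx], lam)
            preds[gi, val_idx] = K_val @ alpha

    sst = np.var(y_train)
    scores = np.empty(grid.size)
    for gi in range(grid.size):
        if metric == "correlation":
            scores[gi] = np.corrcoef(y_train, preds[gi])[0, 1]
        else:
            scores[gi] = 1.0 - np.mean((y_train - preds[gi]) ** 2) / sst
    best = np.flatnonzero(scores == scores.max())
    return float(grid[best[np.argmin(grid[best])]])


def subsample_training_population(
    train_table: pd.DataFrame,
    mode: Literal["minority_only", "majority_only", "balanced"],
    seed: int = 0,
    group_col: str = "group",
    site_col: str = "site",
    id_col: str = "subject_id",
    minority_label: str = "minority",
    majority_label: str = "majority",
) -> list[str]:
    """Training-population arms.

    ``minority_only``: all training minority. ``majority_only``: within each
    site holding training minority, an equal-count random majority sample;
    sites with fewer majority than minority instead trim random minority
    down to the majority count, and the sampled majority count follows the
    trimmed number. ``balanced``: the union of both selections.
    """
    rng = np.random.default_rng(seed)
    chosen_minority: list[str] = []
    chosen_majority: list[str] = []
    for site, sub in train_table.groupby(site_col, sort=True):
        mino = sub[sub[group_col] == minority_label][id_col].astype(str).tolist()
        majo = sub[sub[group_col] == majority_label][id_col].astype(str).tolist()
        if not mino:
            continue
        if len(majo) < len(mino):
            keep = rng.choice(len(mino), size=len(majo), replace=False)
            mino = [mino[i] for i in sorted(keep)]
        if not mino:
            continue
        take = rng.choice(len(majo), size=len(mino), replace=False)
        chosen_minority.extend(mino)
        chosen_majority.extend(majo[i] for i in sorted(take))
    if mode == "minority_only":
        return chosen_minority
    if mode == "majority_only":
        return chosen_majority
    if mode == "balanced":
        return chosen_minority + chosen_majority
    raise ValueError(f"unknown mode {mode!r}")


def abcd_split_folds(n_folds: int = 10, n_test: int = 3) -> list[tuple[int, ...]]:
    """All C(n_folds, n_test) test-fold combinations (120 for 10 choose 3)."""
    return list(itertools.combinations(range(n_folds), n_test))


@dataclass
class PredictionResult:
    """Per-subject predictions for every split, plus split-level metadata.

    ``table`` columns: split, fold, subject_id, group, y_true, y_pred
    (y_true on the residualized scale when confounds were regressed).
    ``split_meta`` maps split id → {"lambda": ..., "sst": ..., "train_ids": ...}.
    ``aggregate_splits`` records the reporting convention: single-site
    results are fold-averaged within each split; multi-site per-split values
    are reported directly, never averaged.
    """

    table: pd.DataFrame
    split_meta: dict[int, dict]
    scheme: str
    model_type: str
    confound_policy: str
    aggregate_splits: bool = True
    meta: dict = field(default_factory=dict)


def _fit_predict(
    fc_tr: np.ndarray,
    y_tr: np.ndarray,
    fc_te: np.ndarray,
    lam: float,
    model_type: str,
) -> np.ndarray:
    if model_type == "kernel":
        K = correlation_kernel(fc_tr, fc_tr)
        alpha = fit_krr(K, y_tr, lam)
        model = KernelModel(lam=lam, dual_coef=alpha, training_fc=fc_tr, training_y=y_tr)
        return predict_krr(model, correlation_kernel(fc_te, fc_tr))
    if model_type == "linear":
        w = fit_linear_ridge(fc_tr, y_tr, lam)
        return predict_linear_ridge(w, fc_te)
    raise ValueError(f"unknown model_type {model_type!r}")


def run_prediction(
    dataset,
    design: MatchedDesign,
    behavior: str = "y",
    model_type: str = "kernel",
    confound_policy: str = "regress",
    lambda_grid: Sequence[float] | None = None,
    training_arm: str = "full",
    inner_folds: int = 5,
    seed: int = 0,
) -> PredictionResult:
    """Run the full cross-validated prediction for one behavior.

    Single-site scheme (``hcp_splits``): per split, each of the design's
    folds serves as test once with the rest training. Multi-site scheme
    (``abcd_sites``): every combination of 3 test folds out of 10 forms one
    split (120 splits over the single fold assignment).

    Per training set: confounds are fitted and regressed (unless
    ``confound_policy='none'``), the penalty is selected by inner
    family/site-grouped CV, and the model predicts the residualized test
    scores. ``training_arm`` restricts the training set to a
    population-subsample arm. Deterministic given ``seed``.
    """
    ids = np.asarray(dataset.subject_ids)
    id_index = {s: i for i, s in enumerate(ids)}
    y_all = np.asarray(dataset.scores[behavior], float)
    fc_all = dataset.fc
    conf_all = dataset.confounds.to_numpy(float)
    conf_names = list(dataset.confounds.columns)
    groups_all = np.asarray(dataset.groups)
    table = dataset.table()

    if design.scheme == "hcp_splits":
        split_fold_pairs = [
            (split, fold)
            for split in design.splits
            for fold in range(design.n_folds)
        ]
        grouping = np.asarray(dataset.families)
    elif design.scheme == "abcd_sites":
        combos = abcd_split_folds(design.n_folds, 3)
        split_fold_pairs = [(i, combo) for i, combo in enumerate(combos)]
        grouping = np.asarray(dataset.sites)
    else:
        raise ValueError(f"unknown scheme {design.scheme!r}")

    rows = []
    split_meta: dict[int, dict] = {}
    rng = np.random.default_rng(seed)
    for split, fold in split_fold_pairs:
        fold_of = design.fold_of_subject[split if design.scheme == "hcp_splits" else 0]
        folds = np.asarray([fold_of[s] for s in ids])
        if design.scheme == "hcp_splits":
            test_mask = folds == fold
            pairs = design.pairs[split]
        else:
            test_mask = np.isin(folds, list(fold))
            pairs = design.pairs[0]
        train_mask = ~test_mask
        train_ids = set(ids[train_mask])

        if training_arm != "full":
            arm_ids = subsample_training_population(
                table[table["subject_id"].isin(train_ids)],
                mode=training_arm,
                seed=int(rng.integers(2**31)),
            )
            train_idx = np.asarray([id_index[s] for s in arm_ids], int)
        else:
            train_idx = np.flatnonzero(train_mask)
        test_idx = np.flatnonzero(test_mask)

        y_tr, fc_tr = y_all[train_idx], fc_all[train_idx]
        y_te, fc_te = y_all[test_idx], fc_all[test_idx]
        cm = None
        if confound_policy == "regress":
            cm = fit_confound_model(y_tr, fc_tr, conf_all[train_idx], conf_names)
            y_tr, fc_tr = apply_confound_model(cm, y_tr, fc_tr, conf_all[train_idx])
            y_te, fc_te = apply_confound_model(cm, y_te, fc_te, conf_all[test_idx])
        elif confound_policy != "none":
            raise ValueError(f"unknown confound_policy {confound_policy!r}")

        grid = (
            np.asarray(lambda_grid, float)
            if lambda_grid is not None
            else default_lambda_grid(len(train_idx))
        )
        lam = nested_cv_select_lambda(
            fc_tr,
            y_tr,
            grid,
            groups=grouping[train_idx],
            n_folds=inner_folds,
            kernel="correlation" if model_type == "kernel" else "linear",
            seed=int(rng.integers(2**31)),
        )
        y_hat = _fit_predict(fc_tr, y_tr, fc_te, lam, model_type)

        # pooled SST over the matched train-group subjects, residualized scale
        matched = {a for a, _ in pairs} | {b for _, b in pairs}
        sst_idx = np.asarray(
            [id_index[s] for s in ids[train_mask] if s in matched], int
        )
        y_sst = y_all[sst_idx]
        if cm is not None:
            y_sst = y_sst - _design(conf_all[sst_idx]) @ cm.y_coef
        from .metrics import training_sst

        sst = training_sst(y_sst)

        fold_label = fold if design.scheme == "hcp_splits" else -1
        for j, idx in enumerate(test_idx):
            rows.append(
                {
                    "split": split,
                    "fold": fold_label,
                    "subject_id": ids[idx],
                    "group": groups_all[idx],
                    "y_true": y_te[j],
                    "y_pred": y_hat[j],
                }
            )
        split_meta.setdefault(split, {"lambda": {}, "sst": {}, "n_train": {}})
        key = fold if design.scheme == "hcp_splits" else 0
        split_meta[split]["lambda"][key] = lam
        split_meta[split]["sst"][key] = sst
        split_meta[split]["n_train"][key] = int(len(train_idx))

    return PredictionResult(
        table=pd.DataFrame(rows),
        split_meta=split_meta,
        scheme=design.scheme,
        model_type=model_type,
        confound_policy=confound_policy,
        aggregate_splits=design.scheme == "hcp_splits",
        meta={"behavior": behavior, "seed": seed, "training_arm": training_arm},
    )
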