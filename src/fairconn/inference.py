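"""Permutation inference for predictability and group accuracy differences.

Two permutation schemes:

* *multilevel block permutation* for whether a behavior is predictable at
  all: predicted scores are shuffled 1000 times under exchangeability
  blocks — whole families are swapped only with same-size families and
  orderings are shuffled within families — so dependent observations move
  together;
* *flip-label permutation* for the group accuracy difference: within each
  matched minority/majority pair the two labels are swapped independently
  with probability 1/2 and both group metrics recomputed, preserving the
  matched design under the null.

P-values use the add-one estimator (never exactly zero); multiple
comparisons are controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "PermutationResult",
    "block_permutation_predictability",
    "flip_label_test",
    "fdr_bh",
    "classify_predictable",
]


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")
        if self.null_values.size != self.n_perm:
            raise ValueError("null_values length must equal n_perm")


def _block_permutations(
    blocks: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) index matrix of exchangeability-block permutations.

    Blocks are grouped by size; block order is permuted within each size
    class and member order is permuted within each block.
    """
    blocks = np.asarray(blocks)
    n = blocks.size
    by_size: dict[int, list[np.ndarray]] = {}
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        by_size.setdefault(idx.size, []).append(idx)
    out = np.empty((n_perm, n), dtype=np.int64)
    for size, members in by_size.items():
        pos = np.stack(members)  # (n_blocks, size): target slots
        m = pos.shape[0]
        for k in range(n_perm):
            order = rng.permutation(m)
            src = pos[order]  # blocks permuted among same-size blocks
            if size > 1:
                within = np.argsort(rng.random((m, size)), axis=1)
                src = np.take_along_axis(src, within, axis=1)
            out[k, pos.ravel()] = src.ravel()
    return out


def block_permutation_predictability(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    blocks: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> PermutationResult:
    """One-sided block-permutation test of prediction accuracy.

    The default statistic is Pearson r between true and predicted scores;
    the null is built by permuting the predicted scores under the
    exchangeability blocks. With all-singleton blocks this reduces to an
    ordinary permutation test. p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    blocks = np.asarray(blocks)
    if not (y_true.shape == y_pred.shape == blocks.shape):
        raise ValueError("y_true, y_pred and blocks must be aligned")
    rng = np.random.default_rng(seed)
    perms = _block_permutations(blocks, n_perm, rng)

    if statistic is None:
        yc = y_true - y_true.mean()
        pc = y_pred - y_pred.mean()
        denom = np.linalg.norm(yc) * np.linalg.norm(pc)
        observed = float(yc @ pc / denom)
        # permutation leaves the prediction vector's mean/norm unchanged
        null = (y_pred[perms] - y_pred.mean()) @ yc / denom
    else:
        observed = float(statistic(y_true, y_pred))
        null = np.asarray(
            [statistic(y_true, y_pred[perms[k]]) for k in range(n_perm)]
        )
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed=observed, null_values=np.asarray(null, float),
        p=float(p), n_perm=n_perm, seed=seed,
    )


def flip_label_test(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    y_true_a: np.ndarray,
    y_pred_a: np.ndarray,
    y_true_b: np.ndarray,
    y_pred_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    pairwise: bool = True,
) -> PermutationResult:
    """Two-sided flip-label permutation test of metric(A) - metric(B).

    Inputs are aligned by matched pair (element i of the A arrays is matched
    to element i of the B arrays). Each permutation swaps the group labels
    within each pair independently with probability 1/2 (``pairwise=False``
    instead reshuffles the pooled subjects into two groups of the original
    sizes) and recomputes both group metrics. p counts symmetric tails.
    """
    y_true_a = np.asarray(y_true_a, float)
    y_pred_a = np.asarray(y_pred_a, float)
    y_true_b = np.asarray(y_true_b, float)
    y_pred_b = np.asarray(y_pred_b, float)
    n = y_true_a.size
    if pairwise and not (y_true_b.size == y_pred_a.size == y_pred_b.size == n):
        raise ValueError("pairwise flips need aligned equal-length pair arrays")
    if n < 2 or y_true_b.size < 2:
        raise ValueError("need at least 2 pairs")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(metric_fn(y_true_a, y_pred_a) - metric_fn(y_true_b, y_pred_b))

    null = np.empty(n_perm)
    if pairwise:
        for k in range(n_perm):
            flip = rng.random(n) < 0.5
            ta = np.where(flip, y_true_b, y_true_a)
            pa = np.where(flip, y_pred_b, y_pred_a)
            tb = np.where(flip, y_true_a, y_true_b)
            pb = np.where(flip, y_pred_a, y_pred_b)
            null[k] = metric_fn(ta, pa) - metric_fn(tb, pb)
    else:
        t_all = np.concatenate([y_true_a, y_true_b])
        p_all = np.concatenate([y_pred_a, y_pred_b])
        for k in range(n_perm):
            perm = rng.permutation(t_all.size)
            ia, ib = perm[:n], perm[n:]
            null[k] = metric_fn(t_all[ia], p_all[ia]) - metric_fn(
                t_all[ib], p_all[ib]
            )
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return PermutationResult(
        observed=observed, null_values=null, p=float(p), n_perm=n_perm, seed=seed
    )


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return np.zeros(0, bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return np.asarray(reject, bool)


def classify_predictable(
    per_behavior: Mapping[str, Mapping],
    q: float = 0.05,
    r_threshold: float = 0.15,
) -> "pd.DataFrame":
    """Predictability classification across behaviors.

    A behavior is predictable iff (i) its whole-test-set accuracy survives
    the FDR-corrected block-permutation test across behaviors and (ii) its
    mean split accuracy is positive in at least one matched group. The
    headline subset further requires mean whole-test-set Pearson r strictly
    above ``r_threshold``.

    ``per_behavior`` maps behavior → dict with keys ``permutation_p``,
    ``mean_accuracy_minority``, ``mean_accuracy_majority``, ``mean_r``.
    """
    import pandas as pd

    names = list(per_behavior)
    if not names:
        raise ValueError("no behaviors supplied")
    required = {
        "permutation_p", "mean_accuracy_minority", "mean_accuracy_majority",
        "mean_r",
    }
    for name in names:
        missing = required - set(per_behavior[name])
        if missing:
            raise ValueError(f"behavior {name!r} missing inputs: {sorted(missing)}")
    p = np.asarray([per_behavior[b]["permutation_p"] for b in names], float)
    survives = fdr_bh(p, q=q)
    rows = []
    for i, b in enumerate(names):
        d = per_behavior[b]
        positive = (
            d["mean_accuracy_minority"] > 0 or d["mean_accuracy_majority"] > 0
        )
        predictable = bool(survives[i] and positive)
        rows.append(
            {
                "behavior": b,
                "permutation_p": float(p[i]),
                "fdr_pass": bool(survives[i]),
                "positive_in_a_group": bool(positive),
                "predictable": predictable,
                "headline": bool(predictable and d["mean_r"] > r_threshold),
            }
        )
    return pd.DataFrame(rows)
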