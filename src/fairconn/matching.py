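"""Matched minority/majority test-pair construction and validation.

Accuracy comparisons between groups are only attributable to group
membership if the compared test sets agree on confounds and on the target
behavior itself. This module builds such matched designs two ways:

* a single-site scheme (HCP-like): the minority group is randomly split into
  family-preserving folds, equal-size majority draws are Hungarian-matched
  within each fold over many iterations, and the draw minimizing the maximum
  per-fold cost is kept; repeated over many random splits;
* a multi-site scheme (ABCD-like): iterative within-site Hungarian matching
  that progressively excludes hard-to-match minority subjects, with sites
  then merged into folds balancing matched-pair counts.

Match quality is validated by paired t tests with Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchCostSpec",
    "MatchedDesign",
    "compute_cost_matrix",
    "hungarian_match",
    "iterative_site_match",
    "merge_sites_to_folds",
    "select_matched_splits_hcp",
    "validate_matching",
]

INFEASIBLE_COST = 1e9


@dataclass(frozen=True)
class MatchCostSpec:
    """Which variables enter the pair cost and how.

    Continuous variables are z-scored over the union of the two groups and
    enter as absolute differences; ``categorical_vars`` require exact
    agreement (mismatch gets ``infeasible_cost``).
    """

    variables: Sequence[str]
    standardize: bool = True
    categorical_vars: Sequence[str] = ()
    infeasible_cost: float = INFEASIBLE_COST

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("variables must be non-empty")
        extra = set(self.categorical_vars) - set(self.variables)
        if extra:
            raise ValueError(f"categorical_vars not in variables: {sorted(extra)}")


@dataclass
class MatchedDesign:
    """Matched pairs plus fold assignments for one matching scheme.

    ``pairs`` maps split id → list of (minority_id, majority_id);
    ``fold_of_subject`` maps split id → {subject_id: fold}.
    """

    scheme: str
    pairs: dict[int, list[tuple[str, str]]]
    fold_of_subject: dict[int, dict[str, int]]
    splits: list[int]
    excluded_minority_ids: list[str] = field(default_factory=list)
    n_folds: int = 10
    meta: dict = field(default_factory=dict)

    def validate(self, families: Mapping[str, int] | None = None) -> None:
        for split, plist in self.pairs.items():
            seen: set[str] = set()
            for a, b in plist:
                if a in seen or b in seen:
                    raise ValueError(f"subject repeated within split {split}")
                seen.update((a, b))
            if families is not None:
                folds = self.fold_of_subject[split]
                fam_fold: dict[int, int] = {}
                for sid, fold in folds.items():
                    fam = families.get(sid)
                    if fam is None:
                        continue
                    if fam in fam_fold and fam_fold[fam] != fold:
                        raise ValueError(
                            f"family {fam} straddles folds in split {split}"
                        )
                    fam_fold.setdefault(fam, fold)


def compute_cost_matrix(
    minority: pd.DataFrame, majority: pd.DataFrame, spec: MatchCostSpec
) -> np.ndarray:
    """Pairwise matching cost: summed absolute (standardized) differences over
    the cost variables, with categorical mismatches set infeasible."""
    for df, name in ((minority, "minority"), (majority, "majority")):
        missing = [v for v in spec.variables if v not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing variables: {missing}")
        sub = df[list(spec.variables)]
        if sub.isna().any().any():
            raise ValueError(f"missing values in {name} cost variables")

    cost = np.zeros((len(minority), len(majority)))
    continuous = [v for v in spec.variables if v not in spec.categorical_vars]
    for var in continuous:
        a = minority[var].to_numpy(float)
        b = majority[var].to_numpy(float)
        if spec.standardize:
            pool = np.concatenate([a, b])
            mu, sd = pool.mean(), pool.std()
            if sd > 0:
                a = (a - mu) / sd
                b = (b - mu) / sd
        cost += np.abs(a[:, None] - b[None, :])
    infeasible = np.zeros(cost.shape, bool)
    for var in spec.categorical_vars:
        a = minority[var].to_numpy()
        b = majority[var].to_numpy()
        infeasible |= a[:, None] != b[None, :]
    cost[infeasible] = spec.infeasible_cost
    return cost


def hungarian_match(
    cost: np.ndarray, infeasible_cost: float = INFEASIBLE_COST
) -> tuple[list[tuple[int, int]], float]:
    """Minimum-total-cost injective assignment of rows to columns.

    Rows whose optimal pairing hits ``infeasible_cost`` are reported
    unmatched (dropped from the returned pairs and the total).
    """
    cost = np.asarray(cost, float)
    if cost.size == 0:
        raise ValueError("empty cost matrix")
    if cost.shape[0] > cost.shape[1]:
        raise ValueError("need at least as many columns (majority) as rows")
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < infeasible_cost
    ]
    total = float(sum(cost[r, c] for r, c in pairs))
    return pairs, total


def iterative_site_match(
    site_subjects: pd.DataFrame,
    spec: MatchCostSpec,
    group_col: str = "group",
    minority_label: str = "minority",
    majority_label: str = "majority",
    id_col: str = "subject_id",
    max_rounds: int = 100,
    rel_tol: float = 0.05,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Within-site iterative Hungarian matching (multi-site scheme).

    Each round matches all remaining minority subjects, then drops the ones
    that could not be matched at all plus the single highest-cost minority;
    iteration stops at ``max_rounds`` rounds or when the total cost decrease
    falls below ``rel_tol`` of the previous round's cost. Returns the final
    pairs and the exclusion log. A site with an empty group yields no pairs.
    """
    minority = site_subjects[site_subjects[group_col] == minority_label]
    majority = site_subjects[site_subjects[group_col] == majority_label]
    if minority.empty or majority.empty:
        return [], list(minority[id_col])

    remaining = minority.reset_index(drop=True)
    excluded: list[str] = []
    prev_cost: float | None = None
    final_pairs: list[tuple[str, str]] = []
    for _ in range(max_rounds):
        if remaining.empty:
            break
        n_min, n_maj = len(remaining), len(majority)
        cost = compute_cost_matrix(remaining, majority, spec)
        if n_min > n_maj:
            # more minority than majority: matchable subset only
            pairs, total = hungarian_match(cost.T, spec.infeasible_cost)
            pairs = [(c, r) for r, c in pairs]
        else:
            pairs, total = hungarian_match(cost, spec.infeasible_cost)
        matched_rows = {r for r, _ in pairs}
        unmatched = [i for i in range(n_min) if i not in matched_rows]
        id_pairs = [
            (str(remaining[id_col].iloc[r]), str(majority[id_col].iloc[c]))
            for r, c in pairs
        ]
        drop_rows = set(unmatched)
        # the mandatory highest-cost drop; a lone matched pair is kept, else
        # the procedure could never emit a single-pair site
        if len(pairs) > 1:
            worst = max(pairs, key=lambda rc: cost[rc[0], rc[1]])[0]
            drop_rows.add(worst)
        final_pairs = [
            ip for (r, _), ip in zip(pairs, id_pairs) if r not in drop_rows
        ]
        excluded.extend(str(remaining[id_col].iloc[i]) for i in sorted(drop_rows))
        remaining = remaining.drop(index=sorted(drop_rows)).reset_index(drop=True)
        if total == 0.0:
            break
        if prev_cost is not None and prev_cost - total < rel_tol * prev_cost:
            break
        prev_cost = total
    return final_pairs, excluded


def merge_sites_to_folds(
    site_pair_counts: Mapping[int, int], n_folds: int
) -> dict[int, int]:
    """Greedy largest-first site → fold mapping balancing matched-pair counts.

    Sites are taken in decreasing pair count (ties by site id) and each is
    placed into the currently smallest fold (ties by fold index);
    deterministic.
    """
    if len(site_pair_counts) < n_folds:
        raise ValueError("fewer sites than folds")
    totals = [0] * n_folds
    mapping: dict[int, int] = {}
    order = sorted(site_pair_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for site, count in order:
        fold = int(np.argmin(totals))
        mapping[site] = fold
        totals[fold] += count
    return mapping


def _family_preserving_folds(
    ids: Sequence[str],
    families: Mapping[str, int],
    n_folds: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Randomly assign whole families to folds, balancing fold sizes."""
    fam_members: dict[int, list[str]] = {}
    for sid in ids:
        fam_members.setdefault(families[sid], []).append(sid)
    fams = list(fam_members)
    rng.shuffle(fams)
    fams.sort(key=lambda f: -len(fam_members[f]))
    counts = [0] * n_folds
    out: dict[str, int] = {}
    for fam in fams:
        members = fam_members[fam]
        candidates = np.flatnonzero(np.asarray(counts) == min(counts))
        fold = int(rng.choice(candidates))
        for sid in members:
            out[sid] = fold
        counts[fold] += len(members)
    return out


def _hard_to_match_prepass(
    data: pd.DataFrame,
    behaviors: Sequence[str],
    confounds: Sequence[str],
    spec_template: MatchCostSpec,
    group_col: str,
    minority_label: str,
    majority_label: str,
    id_col: str,
    percentile: float = 90.0,
    behavior_fraction: float = 0.8,
) -> list[str]:
    """Minority subjects whose minimal attainable pair cost exceeds the given
    percentile of minimal costs in at least ``behavior_fraction`` of the
    behaviors are flagged hard-to-match and excluded from matching."""
    minority = data[data[group_col] == minority_label]
    majority = data[data[group_col] == majority_label]
    flags = np.zeros(len(minority), int)
    for beh in behaviors:
        spec = MatchCostSpec(
            variables=list(confounds) + [beh],
            standardize=spec_template.standardize,
            categorical_vars=spec_template.categorical_vars,
            infeasible_cost=spec_template.infeasible_cost,
        )
        cost = compute_cost_matrix(minority, majority, spec)
        min_costs = cost.min(axis=1)
        thr = np.percentile(min_costs, percentile)
        flags += (min_costs > thr).astype(int)
    need = behavior_fraction * len(behaviors)
    hard = minority[id_col].to_numpy()[flags >= need]
    return [str(s) for s in hard]


def select_matched_splits_hcp(
    data: pd.DataFrame,
    spec: MatchCostSpec,
    n_folds: int = 10,
    n_iter: int = 10000,
    n_splits: int = 40,
    seed: int = 0,
    group_col: str = "group",
    minority_label: str = "minority",
    majority_label: str = "majority",
    id_col: str = "subject_id",
    family_col: str = "family",
    behaviors_for_prepass: Sequence[str] | None = None,
    confounds_for_prepass: Sequence[str] | None = None,
    max_attempts_factor: int = 10,
) -> MatchedDesign:
    """Single-site matched-split construction.

    Per split: the minority group is randomly partitioned into ``n_folds``
    family-preserving folds; over ``n_iter`` random equal-size majority
    draws, each fold is Hungarian-matched and the draw minimizing the maximum
    per-fold cost is retained. A split is rejected when its best draw leaves
    any fold with an infeasible match or splits a matched-majority family
    across folds. Unmatched majority, excluded minority and other groups are
    then distributed into the folds with families intact.
    """
    rng = np.random.default_rng(seed)
    families = dict(zip(data[id_col].astype(str), data[family_col].astype(int)))

    excluded: list[str] = []
    if behaviors_for_prepass:
        excluded = _hard_to_match_prepass(
            data, behaviors_for_prepass, confounds_for_prepass or [],
            spec, group_col, minority_label, majority_label, id_col,
        )
    minority = data[
        (data[group_col] == minority_label) & ~data[id_col].astype(str).isin(excluded)
    ].reset_index(drop=True)
    majority = data[data[group_col] == majority_label].reset_index(drop=True)
    if len(minority) < n_folds:
        raise ValueError("minority count below n_folds")
    if len(majority) < len(minority):
        raise ValueError("majority count below minority count")

    min_ids = minority[id_col].astype(str).to_numpy()
    maj_ids = majority[id_col].astype(str).to_numpy()
    full_cost = compute_cost_matrix(minority, majority, spec)

    # Draws are stratified over the categorical cells (e.g. gender): within
    # each cell the draw takes as many majority subjects as the minority has.
    # An unstratified equal-size draw would have to hit the minority's cell
    # counts exactly by chance, which makes almost every draw infeasible
    # under the exact-match constraint.
    if spec.categorical_vars:
        min_cells = minority[list(spec.categorical_vars)].astype(str).agg(
            "|".join, axis=1
        ).to_numpy()
        maj_cells = majority[list(spec.categorical_vars)].astype(str).agg(
            "|".join, axis=1
        ).to_numpy()
        cell_quota = {
            c: int((min_cells == c).sum()) for c in np.unique(min_cells)
        }
        cell_pools = {
            c: np.flatnonzero(maj_cells == c) for c in cell_quota
        }
        for c, quota in cell_quota.items():
            if cell_pools[c].size < quota:
                raise ValueError(
                    f"majority pool too small in categorical cell {c!r}: "
                    f"{cell_pools[c].size} < {quota}"
                )
    else:
        cell_quota, cell_pools = {"": len(min_ids)}, {"": np.arange(len(maj_ids))}

    maj_family = np.asarray(
        [families[s] for s in maj_ids], dtype=np.int64
    )

    def _draw_majority(rng: np.random.Generator) -> np.ndarray | None:
        # at most one member per majority family: two matched same-family
        # subjects would almost always be assigned different folds, which the
        # family-intact constraint forbids
        used: set[int] = set()
        parts: list[int] = []
        for c, q in cell_quota.items():
            pool = rng.permutation(cell_pools[c])
            take = []
            for i in pool:
                if maj_family[i] not in used:
                    take.append(int(i))
                    used.add(int(maj_family[i]))
                    if len(take) == q:
                        break
            if len(take) < q:
                return None
            parts.extend(take)
        return np.asarray(parts, dtype=np.int64)

    all_pairs: dict[int, list[tuple[str, str]]] = {}
    fold_maps: dict[int, dict[str, int]] = {}
    split_ids: list[int] = []
    attempts = 0
    budget = max_attempts_factor * n_splits
    while len(split_ids) < n_splits:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could not assemble {n_splits} matched splits within "
                f"{budget} attempts (got {len(split_ids)})"
            )
        min_folds = _family_preserving_folds(min_ids, families, n_folds, rng)
        fold_rows = [
            np.flatnonzero([min_folds[s] == f for s in min_ids])
            for f in range(n_folds)
        ]
        best = None
        for _ in range(n_iter):
            draw = _draw_majority(rng)
            if draw is None:
                continue
            # Hungarian assignment over the whole draw; each matched majority
            # subject inherits its minority partner's fold, so the per-fold
            # matching is induced by the global optimum
            sub = full_cost[:, draw]
            pairs, _ = hungarian_match(sub, spec.infeasible_cost)
            if len(pairs) < len(min_ids):
                continue  # some fold would hold an infeasible match
            fold_costs = np.zeros(n_folds)
            draw_pairs = []
            for r, c in pairs:
                fold_costs[min_folds[min_ids[r]]] += sub[r, c]
                draw_pairs.append((int(r), int(draw[c])))
            max_cost = float(fold_costs.max())
            if best is None or max_cost < best[0]:
                best = (max_cost, draw_pairs)
        if best is None:
            continue
        _, draw_pairs = best
        # family consistency among matched majority
        fold_of: dict[str, int] = dict(min_folds)
        ok = True
        fam_fold: dict[int, int] = {}
        for r, c in draw_pairs:
            fold = min_folds[min_ids[r]]
            fam = families[maj_ids[c]]
            if fam_fold.get(fam, fold) != fold:
                ok = False
                break
            fam_fold[fam] = fold
            fold_of[maj_ids[c]] = fold
        if not ok:
            continue
        # distribute everyone else, families intact; families already pinned
        # by a matched member go to that member's fold
        rest = [
            s for s in data[id_col].astype(str) if s not in fold_of
        ]
        fam_pin = {families[s]: f for s, f in fold_of.items()}
        pinned = [s for s in rest if families[s] in fam_pin]
        free = [s for s in rest if families[s] not in fam_pin]
        for s in pinned:
            fold_of[s] = fam_pin[families[s]]
        fold_of.update(_family_preserving_folds(free, families, n_folds, rng))
        split = len(split_ids)
        all_pairs[split] = [
            (str(min_ids[r]), str(maj_ids[c])) for r, c in draw_pairs
        ]
        fold_maps[split] = fold_of
        split_ids.append(split)

    design = MatchedDesign(
        scheme="hcp_splits",
        pairs=all_pairs,
        fold_of_subject=fold_maps,
        splits=split_ids,
        excluded_minority_ids=excluded,
        n_folds=n_folds,
        meta={"seed": seed, "n_iter": n_iter, "attempts": attempts},
    )
    design.validate(families)
    return design


def validate_matching(
    pairs_values: Mapping[str, tuple[np.ndarray, np.ndarray]],
    q: float = 0.05,
) -> pd.DataFrame:
    """Paired t test per variable on matched (minority − majority)
    differences, BH-corrected over the supplied family of tests.

    ``pairs_values`` maps variable name → (minority values, majority values)
    aligned by pair. Zero-variance differences report t=0, p=1 with a
    warning.
    """
    from .inference import fdr_bh

    rows = []
    for var, (a, b) in pairs_values.items():
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.shape != b.shape or a.size < 2:
            raise ValueError(f"{var}: need >= 2 aligned pairs")
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            if not np.allclose(diff, 0.0):
                warnings.warn(
                    f"{var}: constant nonzero paired difference; t set to 0"
                )
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        rows.append({"variable": var, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["rejected"] = fdr_bh(out["p"].to_numpy(), q=q)
    return out
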