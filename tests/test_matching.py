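"""Matched-pair construction: cost matrices, Hungarian assignment, designs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fairconn.matching import (
    MatchCostSpec,
    compute_cost_matrix,
    hungarian_match,
    iterative_site_match,
    merge_sites_to_folds,
    select_matched_splits_hcp,
    validate_matching,
)


def brute_force_assignment(cost):
    """Exhaustive minimum over all injective row -> column maps."""
    n_rows, n_cols = cost.shape
    best = np.inf
    for perm in itertools.permutations(range(n_cols), n_rows):
        total = sum(cost[i, j] for i, j in enumerate(perm))
        best = min(best, total)
    return best


class TestCostMatrix:
    def test_identical_subjects_zero_cost(self):
        df = pd.DataFrame({"age": [1.0, 2.0], "y": [0.5, 0.7]})
        cost = compute_cost_matrix(df, df.copy(), MatchCostSpec(["age", "y"]))
        assert np.allclose(np.diag(cost), 0.0)

    def test_single_variable_absolute_difference(self):
        a = pd.DataFrame({"v": [1.0]})
        b = pd.DataFrame({"v": [3.5]})
        spec = MatchCostSpec(["v"], standardize=False)
        assert compute_cost_matrix(a, b, spec)[0, 0] == pytest.approx(2.5)

    def test_categorical_mismatch_infeasible(self):
        a = pd.DataFrame({"gender": [0], "v": [1.0]})
        b = pd.DataFrame({"gender": [1], "v": [1.0]})
        spec = MatchCostSpec(["gender", "v"], categorical_vars=["gender"])
        assert compute_cost_matrix(a, b, spec)[0, 0] == spec.infeasible_cost

    def test_standardization_is_scale_free(self, rng):
        a = pd.DataFrame({"v": rng.normal(size=8)})
        b = pd.DataFrame({"v": rng.normal(size=8)})
        spec = MatchCostSpec(["v"])
        c1 = compute_cost_matrix(a, b, spec)
        c2 = compute_cost_matrix(a * 100, b * 100, spec)
        assert np.allclose(c1, c2)

    def test_missing_values_rejected(self):
        a = pd.DataFrame({"v": [np.nan]})
        b = pd.DataFrame({"v": [1.0]})
        with pytest.raises(ValueError, match="missing"):
            compute_cost_matrix(a, b, MatchCostSpec(["v"]))


class TestHungarianMatch:
    def test_two_by_two_diagonal(self):
        pairs, total = hungarian_match(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert sorted(pairs) == [(0, 0), (1, 1)]
        assert total == 2.0

    def test_zero_cost_assignment(self):
        _, total = hungarian_match(np.array([[0.0, 5.0], [5.0, 0.0]]))
        assert total == 0.0

    def test_matches_brute_force_on_rectangular(self, rng):
        cost = rng.integers(0, 50, size=(5, 7)).astype(float)
        _, total = hungarian_match(cost)
        assert total == brute_force_assignment(cost)

    def test_infeasible_pairs_reported_unmatched(self):
        big = 1e9
        cost = np.array([[1.0, big], [big, big]])
        pairs, total = hungarian_match(cost, infeasible_cost=big)
        assert pairs == [(0, 0)]
        assert total == 1.0

    def test_empty_and_wide_constraints(self):
        with pytest.raises(ValueError):
            hungarian_match(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            hungarian_match(np.zeros((3, 2)))


def _site(n_min, n_maj, rng, extra_min_cost=0.0):
    vals_maj = rng.normal(size=n_maj)
    vals_min = rng.normal(size=n_min) + extra_min_cost
    return pd.DataFrame(
        {
            "subject_id": [f"m{i}" for i in range(n_min)]
            + [f"M{i}" for i in range(n_maj)],
            "group": ["minority"] * n_min + ["majority"] * n_maj,
            "v": np.concatenate([vals_min, vals_maj]),
        }
    )


class TestIterativeSiteMatch:
    SPEC = MatchCostSpec(["v"], standardize=False)

    def test_zero_costs_stop_after_first_round_with_mandatory_drop(self):
        df = pd.DataFrame(
            {
                "subject_id": ["m0", "m1", "m2", "M0", "M1", "M2"],
                "group": ["minority"] * 3 + ["majority"] * 3,
                "v": [1.0] * 6,
            }
        )
        pairs, excluded = iterative_site_match(df, self.SPEC)
        assert len(pairs) == 2  # one mandatory highest-cost drop
        assert len(excluded) == 1

    def test_single_compatible_pair_kept(self):
        df = pd.DataFrame(
            {
                "subject_id": ["m0", "M0"],
                "group": ["minority", "majority"],
                "v": [1.0, 1.2],
            }
        )
        pairs, excluded = iterative_site_match(df, self.SPEC)
        assert pairs == [("m0", "M0")]
        assert excluded == []

    def test_pigeonhole_more_minority_than_majority(self, rng):
        df = _site(4, 2, rng)
        pairs, excluded = iterative_site_match(df, self.SPEC)
        assert len(pairs) <= 2
        assert len(excluded) >= 2

    def test_empty_group_yields_no_pairs(self, rng):
        df = _site(3, 0, rng)
        pairs, excluded = iterative_site_match(df, self.SPEC)
        assert pairs == []
        assert sorted(excluded) == ["m0", "m1", "m2"]

    def test_cost_sequence_non_increasing(self, rng):
        # round costs recomputed via the matching components
        df = _site(12, 20, rng)
        spec = self.SPEC
        remaining = df[df.group == "minority"].reset_index(drop=True)
        majority = df[df.group == "majority"].reset_index(drop=True)
        totals = []
        for _ in range(6):
            if len(remaining) < 2:
                break
            cost = compute_cost_matrix(remaining, majority, spec)
            pairs, total = hungarian_match(cost, spec.infeasible_cost)
            totals.append(total)
            worst = max(pairs, key=lambda rc: cost[rc[0], rc[1]])[0]
            remaining = remaining.drop(index=worst).reset_index(drop=True)
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestMergeSitesToFolds:
    def test_equal_sites_spread_zero(self):
        mapping = merge_sites_to_folds({0: 30, 1: 30, 2: 30}, 3)
        assert sorted(mapping.values()) == [0, 1, 2]

    def test_greedy_hand_trace_and_brute_force(self):
        counts = {0: 8, 1: 7, 2: 5, 3: 4, 4: 3, 5: 3}
        mapping = merge_sites_to_folds(counts, 3)
        totals = [0, 0, 0]
        for site, fold in mapping.items():
            totals[fold] += counts[site]
        # hand trace of largest-first greedy: 8->A(8), 7->B(7), 5->C(5),
        # 4->C(9), 3->B(10), 3->A(11); totals {11, 10, 9}
        assert sorted(totals) == [9, 10, 11]
        # brute force: greedy attains the optimal max-min spread
        best = min(
            max(t) - min(t)
            for assignment in itertools.product(range(3), repeat=6)
            if len(set(assignment)) == 3
            for t in [
                [
                    sum(c for (s, c), f in zip(counts.items(), assignment) if f == k)
                    for k in range(3)
                ]
            ]
        )
        assert max(totals) - min(totals) == best

    def test_single_fold(self):
        assert set(merge_sites_to_folds({0: 5, 1: 2}, 1).values()) == {0}

    def test_fewer_sites_than_folds(self):
        with pytest.raises(ValueError):
            merge_sites_to_folds({0: 5}, 2)


@pytest.fixture(scope="module")
def table(tiny_dataset):
    return tiny_dataset.table()


@pytest.fixture(scope="module")
def spec():
    return MatchCostSpec(
        ["age", "mean_fd", "gender", "y"], categorical_vars=["gender"]
    )


@pytest.fixture(scope="module")
def design(table, spec):
    return select_matched_splits_hcp(
        table, spec, n_folds=4, n_iter=20, n_splits=3, seed=11
    )


class TestSelectMatchedSplitsHcp:

    def test_families_never_straddle_folds(self, design, table):
        fams = dict(zip(table.subject_id.astype(str), table.family))
        design.validate(fams)  # raises on violation
        for split in design.splits:
            folds = design.fold_of_subject[split]
            by_fam = {}
            for sid, fold in folds.items():
                by_fam.setdefault(fams[sid], set()).add(fold)
            assert all(len(v) == 1 for v in by_fam.values())

    def test_no_repetition_and_correct_groups(self, design, table):
        grp = dict(zip(table.subject_id.astype(str), table.group))
        for split in design.splits:
            seen = set()
            for a, b in design.pairs[split]:
                assert grp[a] == "minority" and grp[b] == "majority"
                assert a not in seen and b not in seen
                seen.update((a, b))

    def test_every_subject_has_a_fold(self, design, table):
        for split in design.splits:
            assert set(design.fold_of_subject[split]) == set(
                table.subject_id.astype(str)
            )

    def test_seeded_determinism(self, table, spec, design):
        again = select_matched_splits_hcp(
            table, spec, n_folds=4, n_iter=20, n_splits=3, seed=11
        )
        assert again.pairs == design.pairs
        assert again.fold_of_subject == design.fold_of_subject

    def test_zero_cost_when_minority_duplicates_majority(self):
        # majority pool is an exact copy of the minority: every draw admits
        # a perfect matching
        n = 12
        base = pd.DataFrame(
            {
                "age": np.linspace(20, 40, n),
                "gender": [0, 1] * (n // 2),
                "y": np.linspace(-1, 1, n),
            }
        )
        mino = base.copy()
        mino["subject_id"] = [f"m{i}" for i in range(n)]
        mino["group"] = "minority"
        majo = base.copy()
        majo["subject_id"] = [f"M{i}" for i in range(n)]
        majo["group"] = "majority"
        table = pd.concat([mino, majo], ignore_index=True)
        table["family"] = np.arange(len(table))
        table["site"] = 0
        spec = MatchCostSpec(["age", "gender", "y"], categorical_vars=["gender"])
        design = select_matched_splits_hcp(
            table, spec, n_folds=3, n_iter=5, n_splits=1, seed=0
        )
        vals = table.set_index("subject_id")[["age", "gender", "y"]]
        for a, b in design.pairs[0]:
            assert np.allclose(vals.loc[a], vals.loc[b])


class TestValidateMatching:
    def test_identical_pairs_no_rejections(self):
        x = np.arange(10.0)
        out = validate_matching({"v": (x, x.copy()), "w": (x, x.copy())})
        assert (out["t"] == 0).all()
        assert (out["p"] == 1).all()
        assert not out["rejected"].any()

    def test_constant_nonzero_differences_degenerate(self):
        a = np.array([2.0, 3.0, 4.0, 5.0])
        b = a - 1.0
        with pytest.warns(UserWarning, match="constant"):
            out = validate_matching({"v": (a, b)})
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_null_calibration_rejection_rate(self):
        rng = np.random.default_rng(77)
        rejections = 0
        for _ in range(500):
            a = rng.normal(size=100)
            b = a + rng.normal(size=100)  # paired null differences ~ N(0,1)
            out = validate_matching({"v": (a, b)})
            rejections += bool(out["rejected"].iloc[0])
        assert 0.03 <= rejections / 500 <= 0.07
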