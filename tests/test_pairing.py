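import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deltamol.chemdata import MoleculeRecord
from deltamol.pairing import (
    FoldPlan,
    cross_merge,
    leakage_check,
    make_fold_plan,
    pairs_for_fold,
    pairset_to_frame,
)


def make_records(values):
    return [MoleculeRecord(f"m{i:03d}", "CCO", v) for i, v in enumerate(values)]


class TestCrossMerge:
    def test_counts_with_and_without_self_pairs(self):
        recs = make_records(range(3))
        assert len(cross_merge(recs, True)) == 9
        assert len(cross_merge(recs, False)) == 6

    @pytest.mark.parametrize("n", [2, 5, 17, 50])
    def test_counts_match_closed_forms(self, n):
        recs = make_records(range(n))
        assert len(cross_merge(recs, True)) == n * n
        assert len(cross_merge(recs, False)) == n * (n - 1)

    def test_antisymmetry_of_ground_truth(self):
        recs = make_records([1.0, 3.0])
        ps = {(p.first, p.second): p.true_delta for p in cross_merge(recs).pairs}
        assert ps[("m000", "m001")] == 2.0
        assert ps[("m001", "m000")] == -2.0

    def test_single_molecule_without_self_pairs_errors(self):
        with pytest.raises(ValueError):
            cross_merge(make_records([1.0]), include_self_pairs=False)

    def test_duplicate_ids_rejected(self):
        recs = [MoleculeRecord("a", "CCO", 1.0), MoleculeRecord("a", "CCN", 2.0)]
        with pytest.raises(ValueError):
            cross_merge(recs)

    def test_pair_order_deterministic(self):
        recs = make_records(range(4))
        a = [(p.first, p.second) for p in cross_merge(recs).pairs]
        b = [(p.first, p.second) for p in cross_merge(list(reversed(recs))).pairs]
        assert a == b

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_pairwise_identities_hold_for_any_values(self, values):
        recs = make_records(values)
        ps = {(p.first, p.second): p.true_delta for p in cross_merge(recs).pairs}
        ids = [r.mol_id for r in recs]
        for a in ids:
            assert ps[(a, a)] == 0.0
        for a in ids:
            for b in ids:
                assert ps[(a, b)] + ps[(b, a)] == 0.0  # exact IEEE negation
        a, b, c = ids[0], ids[1], ids[-1]
        assert ps[(a, b)] + ps[(b, c)] == pytest.approx(ps[(a, c)], abs=1e-9)


class TestFoldPlan:
    def test_balanced_fold_sizes(self):
        recs = make_records(range(100))
        plan = make_fold_plan(recs, 10, 1, seed=3)
        sizes = [len(plan.fold_members(0, f)) for f in range(10)]
        assert sizes == [10] * 10

    def test_uneven_sizes_differ_by_at_most_one(self):
        plan = make_fold_plan(make_records(range(23)), 5, 1, seed=3)
        sizes = sorted(len(plan.fold_members(0, f)) for f in range(5))
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 23

    def test_same_seed_reproduces_assignment(self):
        recs = make_records(range(40))
        assert make_fold_plan(recs, 5, 2, seed=9).assignment == make_fold_plan(recs, 5, 2, seed=9).assignment

    def test_repeats_are_distinct_shuffles(self):
        plan = make_fold_plan(make_records(range(30)), 5, 2, seed=9)
        assert plan.assignment[0] != plan.assignment[1]

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(make_records(range(5)), 10, 1, seed=0)

    def test_json_roundtrip(self, tmp_path):
        plan = make_fold_plan(make_records(range(12)), 3, 2, seed=5)
        plan.to_json(tmp_path / "plan.json")
        back = FoldPlan.from_json(tmp_path / "plan.json")
        assert back.assignment == plan.assignment and back.seed == plan.seed


class TestPairsForFold:
    def test_train_and_test_molecules_disjoint(self):
        recs = make_records(range(50))
        plan = make_fold_plan(recs, 5, 1, seed=2)
        for fold in range(5):
            train, test = pairs_for_fold(plan, 0, fold, recs)
            assert leakage_check(train, test)

    def test_pair_counts_for_balanced_folds(self):
        recs = make_records(range(100))
        plan = make_fold_plan(recs, 10, 1, seed=2)
        train, test = pairs_for_fold(plan, 0, 0, recs)
        assert len(train) == 90 * 90
        assert len(test) == 10 * 10

    def test_test_molecules_cover_dataset_across_folds(self):
        recs = make_records(range(30))
        plan = make_fold_plan(recs, 5, 1, seed=2)
        seen = set()
        for fold in range(5):
            _, test = pairs_for_fold(plan, 0, fold, recs)
            seen |= test.molecule_ids
        assert seen == {r.mol_id for r in recs}

    def test_shared_molecule_fails_leakage_check(self):
        recs = make_records(range(4))
        all_pairs = cross_merge(recs)
        assert not leakage_check(all_pairs, all_pairs)

    def test_bad_indices_rejected(self):
        recs = make_records(range(10))
        plan = make_fold_plan(recs, 5, 1, seed=2)
        with pytest.raises(IndexError):
            pairs_for_fold(plan, 1, 0, recs)
        with pytest.raises(IndexError):
            pairs_for_fold(plan, 0, 5, recs)


def test_pairset_csv_export_columns(tmp_path):
    recs = make_records([1.0, 2.0])
    frame = pairset_to_frame(cross_merge(recs), {"m000": "CCO", "m001": "CCN"})
    assert list(frame.columns) == ["smiles_1", "smiles_2", "delta"]
    assert len(frame) == 4
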