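import numpy as np
import pytest
from scipy.stats import pearsonr

from deltamol.models import (
    DeltaOracle,
    ModelConfig,
    load_model,
    predict_delta,
    predict_delta_by_subtraction,
    save_model,
    train_delta_tabular,
    train_model,
    train_traditional,
)
from deltamol.pairing import cross_merge, make_fold_plan, pairs_for_fold


def split(synth, n_folds=5, seed=1):
    recs = synth.dataset.records
    plan = make_fold_plan(recs, n_folds, 1, seed=seed)
    train_pairs, test_pairs = pairs_for_fold(plan, 0, 0, recs)
    amap = plan.assignment[0]
    train_recs = [r for r in recs if amap[r.mol_id] != 0]
    test_recs = [r for r in recs if amap[r.mol_id] == 0]
    return train_recs, test_recs, train_pairs, test_pairs


class TestTraditional:
    @pytest.mark.parametrize("family", ["forest_traditional", "gbm_traditional"])
    def test_fit_predict_finite_and_deterministic(self, family, synth50_clean):
        cfg = ModelConfig(family=family, n_trees=50, seed=3)
        m1 = train_traditional(synth50_clean.dataset.records, cfg)
        m2 = train_traditional(synth50_clean.dataset.records, cfg)
        ids = [r.mol_id for r in synth50_clean.dataset.records[:5]]
        p1, p2 = m1.predict_value(ids), m2.predict_value(ids)
        assert np.all(np.isfinite(p1))
        assert np.array_equal(p1, p2)

    def test_single_record_rejected(self, toy_records):
        with pytest.raises(ValueError):
            train_traditional(toy_records[:1], ModelConfig(family="forest_traditional"))

    def test_constant_target_warns_but_fits(self, toy_records):
        from deltamol.chemdata import MoleculeRecord

        recs = [MoleculeRecord(r.mol_id, r.canonical_smiles, 1.5) for r in toy_records]
        with pytest.warns(UserWarning):
            m = train_traditional(recs, ModelConfig(family="forest_traditional", n_trees=10))
        assert m.predict_value(["a"])[0] == pytest.approx(1.5)

    def test_subtraction_telescopes_exactly(self, toy_records):
        m = train_traditional(toy_records, ModelConfig(family="forest_traditional", n_trees=20))
        pairs = cross_merge(toy_records)
        preds = {(p.first, p.second): v for p, v in zip(pairs.pairs, predict_delta_by_subtraction(m, pairs))}
        for a in "abc":
            assert preds[(a, a)] == 0.0
        for a in "abc":
            for b in "abc":
                assert preds[(a, b)] == -preds[(b, a)]
        assert preds[("a", "b")] + preds[("b", "c")] == pytest.approx(preds[("a", "c")], abs=1e-12)

    def test_offset_shift_leaves_forest_deltas_unchanged(self, synth50_clean):
        from deltamol.chemdata import MoleculeRecord

        recs = synth50_clean.dataset.records
        shifted = [MoleculeRecord(r.mol_id, r.canonical_smiles, r.value + 5.0) for r in recs]
        cfg = ModelConfig(family="forest_traditional", n_trees=100, seed=4)
        pairs = cross_merge(recs[:20])
        d0 = predict_delta(train_traditional(recs, cfg), pairs)
        d5 = predict_delta(train_traditional(shifted, cfg), pairs)
        sd = np.std([r.value for r in recs])
        assert np.max(np.abs(d5 - d0)) <= 0.1 * sd


class TestDeltaTabular:
    def test_fit_on_tiny_pair_set(self, toy_records):
        pairs = cross_merge(toy_records)
        smiles = {r.mol_id: r.canonical_smiles for r in toy_records}
        m = train_delta_tabular(pairs, smiles, ModelConfig(family="gbm_delta", seed=0))
        preds = predict_delta(m, pairs)
        assert preds.shape == (9,) and np.all(np.isfinite(preds))

    def test_same_seed_and_data_identical_fit(self, synth100):
        train_recs, _, train_pairs, test_pairs = split(synth100)
        cfg = ModelConfig(family="gbm_delta", seed=5)
        smiles = {r.mol_id: r.canonical_smiles for r in synth100.dataset.records}
        p1 = predict_delta(train_delta_tabular(train_pairs, smiles, cfg), test_pairs)
        p2 = predict_delta(train_delta_tabular(train_pairs, smiles, cfg), test_pairs)
        assert np.array_equal(p1, p2)

    def test_recovers_additive_property_on_held_out_pairs(self, synth100):
        train_recs, _, train_pairs, test_pairs = split(synth100)
        m = train_model(ModelConfig(family="gbm_delta", seed=1), train_recs, train_pairs)
        m.register_molecules(synth100.dataset.records)
        r = pearsonr(predict_delta(m, test_pairs), test_pairs.true_deltas).statistic
        assert r >= 0.8

    def test_wrong_family_rejected(self, toy_records):
        pairs = cross_merge(toy_records)
        with pytest.raises(ValueError):
            train_delta_tabular(pairs, {}, ModelConfig(family="forest_traditional"))


class TestDispatch:
    def test_prediction_length_and_order(self, toy_records):
        oracle = DeltaOracle({r.mol_id: r.value for r in toy_records})
        pairs = cross_merge(toy_records)
        preds = predict_delta(oracle, pairs)
        assert preds.shape == (len(pairs),)
        assert np.array_equal(preds, pairs.true_deltas)

    def test_traditional_routes_through_subtraction(self, toy_records):
        m = train_traditional(toy_records, ModelConfig(family="forest_traditional", n_trees=10))
        pairs = cross_merge(toy_records)
        assert np.array_equal(predict_delta(m, pairs), predict_delta_by_subtraction(m, pairs))


class TestSaveLoad:
    @pytest.mark.parametrize("family", ["forest_traditional", "gbm_delta", "graph_delta"])
    def test_roundtrip_preserves_predictions(self, family, toy_records, tmp_path):
        cfg = ModelConfig(family=family, n_trees=10, epochs=1, hidden_size=8, seed=2)
        pairs = cross_merge(toy_records)
        m = train_model(cfg, toy_records, pairs)
        p1 = predict_delta(m, pairs)
        save_model(m, tmp_path / "bundle")
        m2 = load_model(tmp_path / "bundle")
        assert np.allclose(predict_delta(m2, pairs), p1, atol=1e-12)
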