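import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deltamol.evaluation import (
    compare_repeat_metrics,
    compute_metrics,
    magnitude_analysis,
    murcko_scaffold,
    run_cv,
    scaffold_partition,
    similarity_analysis,
    summarize_cv,
)
from deltamol.models import ModelConfig
from deltamol.pairing import cross_merge, make_fold_plan


class TestComputeMetrics:
    def test_perfect_prediction(self):
        r = compute_metrics([1.0, -2.0, 3.0], [1.0, -2.0, 3.0])
        assert r.pearson_r == pytest.approx(1.0)
        assert r.mae == 0.0 and r.rmse == 0.0 and r.sign_accuracy == 1.0

    def test_hand_computed_toy_vectors(self):
        r = compute_metrics([1.0, 2.0], [2.0, 4.0])
        assert r.mae == pytest.approx(1.5)
        assert r.rmse == pytest.approx(np.sqrt(2.5))

    def test_anti_predictor(self):
        r = compute_metrics([1.0, -2.0, 3.0], [-1.0, 2.0, -3.0])
        assert r.pearson_r == pytest.approx(-1.0)
        assert r.sign_accuracy == 0.0

    def test_zero_variance_yields_nan_r_with_warning(self):
        with pytest.warns(UserWarning):
            r = compute_metrics([1.0, 1.0, 1.0], [0.5, 1.0, 1.5])
        assert np.isnan(r.pearson_r) and r.mae == pytest.approx(0.5 * 2 / 3)

    def test_sign_accuracy_excludes_true_zeros(self):
        r = compute_metrics([0.0, 1.0, -1.0], [5.0, 2.0, 1.0])
        assert r.sign_accuracy == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0], [1.0, 2.0])

    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_rmse_dominates_mae(self, true, seed):
        pred = np.asarray(true) + np.random.default_rng(seed).normal(0, 1, len(true))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = compute_metrics(true, pred)
        assert r.rmse >= r.mae - 1e-12


class TestRunCV:
    def test_oracle_is_perfect_on_every_fold(self, synth100):
        plan = make_fold_plan(synth100.dataset.records, 4, 2, seed=1)
        preds = {}
        reports = run_cv(synth100.dataset, [ModelConfig(family="oracle")], plan, predictions_out=preds)
        assert len(reports) == 8
        for r in reports:
            assert r.pearson_r == pytest.approx(1.0, abs=1e-12)
            assert r.mae == pytest.approx(0.0, abs=1e-12)
            assert r.sign_accuracy == 1.0
        (summary,) = summarize_cv(reports, preds)
        assert summary.pearson_r_mean == pytest.approx(1.0, abs=1e-12)
        assert summary.mae_mean == pytest.approx(0.0, abs=1e-12)
        assert summary.n_repeats == 2

    def test_fold_report_count_matches_plan(self, synth100):
        plan = make_fold_plan(synth100.dataset.records, 5, 1, seed=2)
        reports = run_cv(synth100.dataset, [ModelConfig(family="oracle")], plan)
        assert {(r.repeat, r.fold) for r in reports} == {(0, f) for f in range(5)}


class TestScaffoldPartition:
    def test_shared_benzene_scaffold(self):
        assert murcko_scaffold("Cc1ccccc1") == murcko_scaffold("CCc1ccccc1")

    def test_acyclic_scaffold_is_empty(self):
        assert murcko_scaffold("CCO") == ""

    def test_partition_covers_all_pairs(self, synth100):
        recs = synth100.dataset.records[:40]
        pairs = cross_merge(recs)
        smiles = {r.mol_id: r.canonical_smiles for r in recs}
        groups = scaffold_partition(pairs, smiles)
        assert len(groups["same_scaffold"]) + len(groups["different_scaffold"]) == len(pairs)
        assert len(groups["same_scaffold"]) >= len(recs)  # at least the self-pairs

    def test_same_vs_different_ring_systems(self):
        from deltamol.chemdata import MoleculeRecord

        recs = [
            MoleculeRecord("tol", "Cc1ccccc1", 1.0),
            MoleculeRecord("eb", "CCc1ccccc1", 2.0),
            MoleculeRecord("pyr", "Cc1ccncc1", 3.0),
        ]
        groups = scaffold_partition(cross_merge(recs), {r.mol_id: r.canonical_smiles for r in recs})
        # 3 self-pairs + tol<->eb both ways are 'same'; 4 pairs involving pyridine differ
        assert len(groups["same_scaffold"]) == 5
        assert len(groups["different_scaffold"]) == 4


class TestMagnitudeAnalysis:
    def test_exact_decile_sizes(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0, 1, 100)
        out = magnitude_analysis(t, t + rng.normal(0, 0.1, 100))
        assert out["n_per_decile"] == 10

    def test_perfect_prediction_gives_zero_decile_mae_and_nan_corr(self):
        t = np.linspace(-2, 2, 40)
        out = magnitude_analysis(t, t)
        assert out["top_decile_mae"] == 0.0 and out["bottom_decile_mae"] == 0.0
        assert np.isnan(out["error_vs_delta_r"])

    def test_error_proportional_to_magnitude_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        t = rng.normal(0, 1, 20)
        pred = t + 0.1 * np.abs(t)
        out = magnitude_analysis(t, pred)
        assert out["error_vs_delta_r"] == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            magnitude_analysis([1.0] * 5, [1.0] * 5)


class TestSimilarityAnalysis:
    def test_row_count_and_self_pairs(self, toy_records):
        pairs = cross_merge(toy_records)
        smiles = {r.mol_id: r.canonical_smiles for r in toy_records}
        preds = pairs.true_deltas
        df = similarity_analysis(pairs, preds, smiles)
        assert len(df) == len(pairs)
        self_rows = df[[p.first == p.second for p in pairs.pairs]]
        assert (self_rows["tanimoto"] == 1.0).all()
        assert (self_rows["true_delta"] == 0.0).all()
        assert "sim_vs_error_r" in df.attrs


class TestCompareRepeats:
    def test_identical_vectors_not_significant(self):
        out = compare_repeat_metrics([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert out["wilcoxon_p"] == 1.0

    def test_clear_separation_detected(self):
        out = compare_repeat_metrics([0.9, 0.91, 0.92, 0.93, 0.94], [0.5, 0.51, 0.52, 0.53, 0.54])
        assert out["t_test_p"] < 0.01
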