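"""Cross-validated benchmarking and difference-centric analyses.

Repeated molecule-level k-fold cross-validation (default 5 x 10-fold)
drives all benchmarking: within each fold, models train on pairs (or
molecules) drawn only from the training molecules and are scored on the
exhaustive ordered pairs of the held-out molecules. Fold-level metric
reports are pooled per repeat and summarized as mean +/- SD over repeats;
model families are compared by paired tests over the repeat-level values.

Difference-centric analyses stratify test pairs by Bemis-Murcko scaffold
identity (scaffold-hopping potential), by difference magnitude deciles
(large-change prediction), and against Tanimoto similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy import stats

from .chemdata import MoleculeRecord, PropertyDataset
from .features import morgan_fingerprint, tanimoto
from .models import ModelConfig, TrainedModel, predict_delta, train_model
from .pairing import FoldPlan, PairSet, pairs_for_fold

__all__ = [
    "MetricReport",
    "CVSummary",
    "compute_metrics",
    "run_cv",
    "summarize_cv",
    "murcko_scaffold",
    "scaffold_partition",
    "magnitude_analysis",
    "similarity_analysis",
    "compare_repeat_metrics",
]


@dataclass(frozen=True)
class MetricReport:
    """Difference-prediction quality on one pair set."""

    pearson_r: float
    mae: float
    rmse: float
    sign_accuracy: float
    n_pairs: int
    dataset: str = ""
    family: str = ""
    repeat: int = -1
    fold: int = -1


def compute_metrics(
    true_deltas: Sequence[float],
    pred_deltas: Sequence[float],
    **labels,
) -> MetricReport:
    """Pearson r, MAE, RMSE and sign accuracy for one prediction vector.

    Sign accuracy is the fraction of pairs whose predicted difference has
    the same sign as the true one, computed over pairs with a nonzero true
    difference (the sign of zero is undefined; self-pairs are thus ignored
    here while still contributing to MAE/RMSE). If either vector has zero
    variance the correlation is undefined and reported as NaN.
    """
    t = np.asarray(true_deltas, dtype=float)
    p = np.asarray(pred_deltas, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or not len(t):
        raise ValueError("true and predicted vectors must be equal-length, nonempty 1-D")
    err = p - t
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        warnings.warn("zero variance; Pearson r undefined, reporting NaN")
        r = float("nan")
    else:
        r = float(stats.pearsonr(t, p).statistic)
    nz = t != 0
    sign_acc = float(np.mean(np.sign(p[nz]) == np.sign(t[nz]))) if nz.any() else float("nan")
    return MetricReport(pearson_r=r, mae=mae, rmse=rmse, sign_accuracy=sign_acc,
                        n_pairs=len(t), **labels)


@dataclass
class CVSummary:
    """Mean +/- SD over repeats of repeat-level pooled metrics."""

    dataset: str
    family: str
    n_repeats: int
    pearson_r_mean: float
    pearson_r_sd: float
    mae_mean: float
    mae_sd: float
    rmse_mean: float
    rmse_sd: float
    sign_accuracy_mean: float
    sign_accuracy_sd: float
    repeat_metrics: list[MetricReport] = field(default_factory=list)


def run_cv(
    dataset: PropertyDataset,
    configs: Sequence[ModelConfig],
    plan: FoldPlan,
    include_self_pairs: bool = True,
    predictions_out: dict | None = None,
) -> list[MetricReport]:
    """Leak-free repeated k-fold CV for each config; one report per fold.

    For each (config, repeat, fold): train on the training-molecule pairs
    (delta families) or training molecules (traditional families), predict
    the exhaustive test pairs, and score. Folds with fewer than 2 test
    molecules are skipped with a warning. When ``predictions_out`` (a dict)
    is supplied, pooled (true, pred) arrays are accumulated under
    (dataset, family, repeat) keys so summaries can score each repeat over
    its pooled test-pair predictions rather than averaging fold metrics.
    """
    records = dataset.records
    reports: list[MetricReport] = []
    for config in configs:
        for rep in range(plan.n_repeats):
            for fold in range(plan.n_folds):
                train_pairs, test_pairs = pairs_for_fold(
                    plan, rep, fold, records, include_self_pairs
                )
                n_test_mols = len(test_pairs.molecule_ids)
                if n_test_mols < 2:
                    warnings.warn(f"fold {fold} of repeat {rep} has {n_test_mols} test molecules; skipped")
                    continue
                amap = plan.assignment[rep]
                train_records = [r for r in records if amap[r.mol_id] != fold]
                model = train_model(config, train_records, train_pairs)
                model.register_molecules(records)
                preds = predict_delta(model, test_pairs)
                reports.append(
                    compute_metrics(
                        test_pairs.true_deltas, preds,
                        dataset=dataset.name, family=config.family, repeat=rep, fold=fold,
                    )
                )
                if predictions_out is not None:
                    key = (dataset.name, config.family, rep)
                    t_acc, p_acc = predictions_out.setdefault(key, ([], []))
                    t_acc.append(test_pairs.true_deltas)
                    p_acc.append(preds)
    return reports


def _repeat_metrics_from_predictions(
    dataset: str, family: str, predictions: dict
) -> list[MetricReport]:
    out = []
    for (ds, fam, rep) in sorted(k for k in predictions if k[0] == dataset and k[1] == family):
        t_acc, p_acc = predictions[(ds, fam, rep)]
        t = np.concatenate(t_acc)
        p = np.concatenate(p_acc)
        out.append(compute_metrics(t, p, dataset=ds, family=fam, repeat=rep))
    return out


def _pool_by_repeat(fold_reports: list[MetricReport]) -> list[MetricReport]:
    """Fallback repeat-level pooling from fold summaries alone.

    Pair-count weighting is exact for MAE and (via mean squares) RMSE but
    only approximate for Pearson r and sign accuracy; prefer pooled
    predictions when available.
    """
    out = []
    for rep in sorted({r.repeat for r in fold_reports}):
        reps = [r for r in fold_reports if r.repeat == rep]
        w = np.array([r.n_pairs for r in reps], dtype=float)
        w /= w.sum()
        out.append(
            MetricReport(
                pearson_r=float(np.nansum(w * np.array([r.pearson_r for r in reps]))),
                mae=float(np.sum(w * np.array([r.mae for r in reps]))),
                rmse=float(np.sqrt(np.sum(w * np.array([r.rmse for r in reps]) ** 2))),
                sign_accuracy=float(np.nansum(w * np.array([r.sign_accuracy for r in reps]))),
                n_pairs=int(sum(r.n_pairs for r in reps)),
                dataset=reps[0].dataset,
                family=reps[0].family,
                repeat=rep,
            )
        )
    return out


def summarize_cv(
    fold_reports: list[MetricReport], predictions: dict | None = None
) -> list[CVSummary]:
    """Aggregate to per-(dataset, family) mean +/- SD over repeats.

    With ``predictions`` (from ``run_cv(..., predictions_out=...)``) each
    repeat is scored over its pooled test-pair predictions — the comparison
    unit for paired tests. Without it, repeat metrics fall back to
    pair-count-weighted averages of fold metrics (exact for MAE/RMSE,
    approximate for r and sign accuracy).
    """
    summaries = []
    keys = sorted({(r.dataset, r.family) for r in fold_reports})
    for dataset, family in keys:
        group = [r for r in fold_reports if (r.dataset, r.family) == (dataset, family)]
        if predictions is not None:
            per_rep = _repeat_metrics_from_predictions(dataset, family, predictions)
        else:
            per_rep = _pool_by_repeat(group)
        def ms(attr):
            vals = np.array([getattr(r, attr) for r in per_rep])
            return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        r_m, r_s = ms("pearson_r")
        mae_m, mae_s = ms("mae")
        rmse_m, rmse_s = ms("rmse")
        sa_m, sa_s = ms("sign_accuracy")
        summaries.append(
            CVSummary(
                dataset=dataset, family=family, n_repeats=len(per_rep),
                pearson_r_mean=r_m, pearson_r_sd=r_s,
                mae_mean=mae_m, mae_sd=mae_s,
                rmse_mean=rmse_m, rmse_sd=rmse_s,
                sign_accuracy_mean=sa_m, sign_accuracy_sd=sa_s,
                repeat_metrics=per_rep,
            )
        )
    return summaries


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_partition(
    pairs: PairSet, smiles_by_id: dict[str, str]
) -> dict[str, list[int]]:
    """Split pair indices into same- vs different-scaffold groups.

    Scaffolds compare by string equality; two acyclic molecules (both empty
    scaffolds) count as 'same'. The two groups partition the pair set.
    """
    scaffolds = {m: murcko_scaffold(s) for m, s in smiles_by_id.items()}
    groups: dict[str, list[int]] = {"same_scaffold": [], "different_scaffold": []}
    for i, p in enumerate(pairs.pairs):
        key = "same_scaffold" if scaffolds[p.first] == scaffolds[p.second] else "different_scaffold"
        groups[key].append(i)
    return groups


def magnitude_analysis(
    true_deltas: Sequence[float],
    pred_deltas: Sequence[float],
    decile: float = 0.1,
) -> dict:
    """Error structure across the difference-magnitude distribution.

    Reports the Pearson correlation between |error| and |true delta|, and
    the MAE within the top and bottom ``decile`` of |true delta| (stable
    sort by (|delta|, index) so group sizes are exactly floor(decile * n)).
    """
    t = np.asarray(true_deltas, dtype=float)
    p = np.asarray(pred_deltas, dtype=float)
    if len(t) < 10:
        raise ValueError("need >= 10 pairs for a decile analysis")
    abs_err = np.abs(p - t)
    abs_t = np.abs(t)
    if np.ptp(abs_t) == 0:
        warnings.warn("all |true delta| equal; deciles degenerate")
    if np.ptp(abs_err) == 0 or np.ptp(abs_t) == 0:
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(abs_t, abs_err).statistic)
    k = int(np.floor(decile * len(t)))
    order = np.lexsort((np.arange(len(t)), abs_t))  # stable: magnitude then index
    bottom, top = order[:k], order[len(t) - k :]
    return {
        "error_vs_delta_r": corr,
        "top_decile_mae": float(np.mean(abs_err[top])),
        "bottom_decile_mae": float(np.mean(abs_err[bottom])),
        "n_per_decile": k,
    }


def similarity_analysis(
    pairs: PairSet,
    pred_deltas: Sequence[float],
    smiles_by_id: dict[str, str],
) -> pd.DataFrame:
    """Per-pair table (tanimoto, |error|, true_delta) for similarity plots.

    The frame's ``attrs`` carry the Pearson correlations of similarity with
    |error| and with |true delta| (NaN when a column is constant).
    """
    p = np.asarray(pred_deltas, dtype=float)
    if len(p) != len(pairs):
        raise ValueError("prediction length != pair count")
    fps = {m: morgan_fingerprint(s) for m, s in smiles_by_id.items()}
    sims = np.array([tanimoto(fps[q.first], fps[q.second]) for q in pairs.pairs])
    t = pairs.true_deltas
    df = pd.DataFrame({"tanimoto": sims, "abs_error": np.abs(p - t), "true_delta": t})
    for name, col in (("sim_vs_error_r", "abs_error"), ("sim_vs_delta_r", "true_delta")):
        y = np.abs(df[col].to_numpy())
        if np.ptp(sims) == 0 or np.ptp(y) == 0:
            warnings.warn(f"constant column; {name} undefined")
            df.attrs[name] = float("nan")
        else:
            df.attrs[name] = float(stats.pearsonr(sims, y).statistic)
    return df


def compare_repeat_metrics(
    a: Sequence[float], b: Sequence[float]
) -> dict[str, float]:
    """Paired comparison of two model families over repeat-level metrics.

    Returns the paired t-test p-value, the Wilcoxon signed-rank p-value
    (nonparametric alternative) and a Kolmogorov-Smirnov normality p-value
    for the paired differences. No automatic selection between tests.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 repeat metrics")
    d = a - b
    t_p = float(stats.ttest_rel(a, b).pvalue)
    try:
        w_p = float(stats.wilcoxon(a, b).pvalue)
    except ValueError:  # all differences zero
        w_p = 1.0
    sd = np.std(d, ddof=1)
    norm_p = float(stats.kstest((d - np.mean(d)) / sd, "norm").pvalue) if sd > 0 else 1.0
    return {"t_test_p": t_p, "wilcoxon_p": w_p, "normality_p": norm_p}
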