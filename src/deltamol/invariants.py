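"""Unsupervised consistency diagnostics for pair-difference models.

A perfect difference predictor f obeys three identities:

    f(x, x) = 0                      (zero self-difference)
    f(x, y) = -f(y, x)               (swap antisymmetry)
    f(x, y) + f(y, z) = f(x, z)      (triplet additivity)

Predict-then-subtract models satisfy all three exactly because subtraction
telescopes. Direct delta models satisfy them only to the extent training
recovered them, so the residuals — self-pair MAE, swap correlation, triplet
additivity MAE — quantify internal consistency *without labels*, and
correlate with supervised cross-validation performance across datasets.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .chemdata import MoleculeRecord
from .models import TrainedModel, predict_delta
from .pairing import OrderedPair, PairSet

__all__ = [
    "InvariantReport",
    "self_difference_mae",
    "swap_correlation",
    "additivity_mae",
    "evaluate_invariants",
    "anticipate_performance",
]


@dataclass(frozen=True)
class InvariantReport:
    """Residuals of the three pair identities for one trained model."""

    self_mae: float
    swap_r: float
    additivity_mae: float
    n_molecules: int
    n_triplets_used: int
    triplet_sampling_seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _self_pairs(molecules: Sequence[MoleculeRecord]) -> PairSet:
    return PairSet(
        [OrderedPair(r.mol_id, r.mol_id, 0.0) for r in molecules], include_self_pairs=True
    )


def self_difference_mae(model: TrainedModel, molecules: Sequence[MoleculeRecord]) -> float:
    """Mean |f(x, x)| over the molecules; zero for an ideal model."""
    if not molecules:
        raise ValueError("need at least one molecule")
    model.register_molecules(molecules)
    preds = predict_delta(model, _self_pairs(molecules))
    return float(np.mean(np.abs(preds)))


def swap_correlation(model: TrainedModel, pairs: PairSet) -> float:
    """Pearson r between f(a, b) and f(b, a) over unordered pairs.

    Self-pairs carry no swap information and are excluded. An ideal model
    gives exactly -1. Constant predictions leave the correlation undefined;
    NaN is returned with a warning.
    """
    unordered = sorted({tuple(sorted((p.first, p.second))) for p in pairs.pairs if p.first != p.second})
    if len(unordered) < 2:
        raise ValueError("need >= 2 distinct unordered non-self pairs")
    fwd = PairSet([OrderedPair(a, b, 0.0) for a, b in unordered])
    bwd = PairSet([OrderedPair(b, a, 0.0) for a, b in unordered])
    p_fwd = predict_delta(model, fwd)
    p_bwd = predict_delta(model, bwd)
    if np.ptp(p_fwd) == 0 or np.ptp(p_bwd) == 0:
        warnings.warn("constant predictions; swap correlation undefined")
        return float("nan")
    return float(stats.pearsonr(p_fwd, p_bwd).statistic)


def additivity_mae(
    model: TrainedModel,
    molecules: Sequence[MoleculeRecord],
    max_triplets: int = 100_000,
    seed: int = 0,
) -> tuple[float, int]:
    """Mean |f(x,y) + f(y,z) - f(x,z)| over ordered distinct triplets.

    Enumerates all n(n-1)(n-2) ordered triplets when that count is at most
    ``max_triplets``, otherwise draws a uniform seeded sample of
    ``max_triplets`` triplets. Returns (mae, n_triplets_used).
    """
    n = len(molecules)
    if n < 3:
        raise ValueError("need >= 3 molecules for triplets")
    model.register_molecules(molecules)
    ids = [r.mol_id for r in molecules]
    total = n * (n - 1) * (n - 2)
    if total <= max_triplets:
        triplets = list(itertools.permutations(range(n), 3))
    else:
        rng = np.random.default_rng(seed)
        picked = set()
        triplets = []
        while len(triplets) < max_triplets:
            i, j, k = rng.integers(0, n, size=3)
            if i == j or j == k or i == k:
                continue
            key = (int(i), int(j), int(k))
            if key in picked:
                continue
            picked.add(key)
            triplets.append(key)
    xy = PairSet([OrderedPair(ids[i], ids[j], 0.0) for i, j, _ in triplets])
    yz = PairSet([OrderedPair(ids[j], ids[k], 0.0) for _, j, k in triplets])
    xz = PairSet([OrderedPair(ids[i], ids[k], 0.0) for i, _, k in triplets])
    resid = predict_delta(model, xy) + predict_delta(model, yz) - predict_delta(model, xz)
    return float(np.mean(np.abs(resid))), len(triplets)


def evaluate_invariants(
    model: TrainedModel,
    molecules: Sequence[MoleculeRecord],
    max_triplets: int = 100_000,
    seed: int = 0,
) -> InvariantReport:
    """All three diagnostics in one report (swap over all non-self pairs)."""
    from .pairing import cross_merge

    model.register_molecules(molecules)
    pairs = cross_merge(molecules, include_self_pairs=False)
    add_mae, n_trip = additivity_mae(model, molecules, max_triplets, seed)
    return InvariantReport(
        self_mae=self_difference_mae(model, molecules),
        swap_r=swap_correlation(model, pairs),
        additivity_mae=add_mae,
        n_molecules=len(molecules),
        n_triplets_used=n_trip,
        triplet_sampling_seed=seed,
    )


def anticipate_performance(rows: Sequence[tuple[float, float]]) -> float:
    """Pearson r across datasets between an invariant residual and a CV metric.

    Each row is (invariant metric, cross-validation metric) for one dataset;
    a strong correlation means the label-free diagnostic anticipates how
    well the model will do on that dataset.
    """
    if len(rows) < 3:
        raise ValueError("need >= 3 datasets to correlate")
    x = np.array([r[0] for r in rows], dtype=float)
    y = np.array([r[1] for r in rows], dtype=float)
    return float(stats.pearsonr(x, y).statistic)
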