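"""Ordered molecule pairs and leak-free cross-validation folds.

The central hazard of pairwise difference learning is leakage: if a molecule
contributes pairs to both the training and the test side of a split, test
performance is inflated because half of every test pair was seen in
training. The firewall is to split *molecules* into folds first and
cross-merge into exhaustive ordered pairs only afterwards, so the molecule
sets underlying train and test pairs are disjoint by construction.

Sign convention: ``true_delta = value(second) - value(first)`` throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .chemdata import MoleculeRecord

__all__ = [
    "OrderedPair",
    "PairSet",
    "FoldPlan",
    "cross_merge",
    "make_fold_plan",
    "pairs_for_fold",
    "leakage_check",
    "pairset_to_frame",
    "write_pairset_csv",
]


@dataclass(frozen=True)
class OrderedPair:
    """Directed pair; ``true_delta`` is value(second) minus value(first)."""

    first: str
    second: str
    true_delta: float


@dataclass
class PairSet:
    pairs: list[OrderedPair]
    include_self_pairs: bool = True
    origin: Literal["train", "test", "external"] = "train"

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def molecule_ids(self) -> set[str]:
        ids = {p.first for p in self.pairs}
        ids.update(p.second for p in self.pairs)
        return ids

    @property
    def true_deltas(self) -> np.ndarray:
        return np.array([p.true_delta for p in self.pairs], dtype=float)


def cross_merge(
    records: Sequence[MoleculeRecord],
    include_self_pairs: bool = True,
    origin: Literal["train", "test", "external"] = "train",
) -> PairSet:
    """Exhaustively pair all molecules in both orders.

    Order matters: (a, b) and (b, a) are distinct pairs carrying deltas of
    opposite sign. Self-pairs (a, a) carry delta 0 and give delta models an
    explicit zero anchor; with them the set has n^2 pairs, without n(n-1).
    Pair order is deterministic (lexicographic by mol_id).
    """
    ids = [r.mol_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("records must have distinct mol_ids")
    if not include_self_pairs and len(records) < 2:
        raise ValueError("need >= 2 molecules to form non-self pairs")
    by_id = sorted(records, key=lambda r: r.mol_id)
    pairs = [
        OrderedPair(a.mol_id, b.mol_id, b.value - a.value)
        for a in by_id
        for b in by_id
        if include_self_pairs or a.mol_id != b.mol_id
    ]
    return PairSet(pairs=pairs, include_self_pairs=include_self_pairs, origin=origin)


@dataclass
class FoldPlan:
    """Molecule-level assignment to repeats x folds.

    ``assignment[repeat][mol_id]`` is the fold index of that molecule in
    that repeat. Each repeat's folds partition the molecule set with sizes
    differing by at most one. Per-repeat shuffles use seeds derived from the
    master seed as ``SeedSequence([seed, repeat])`` so any repeat is
    reconstructible in isolation.
    """

    n_repeats: int
    n_folds: int
    assignment: list[dict[str, int]]
    seed: int

    def fold_members(self, repeat: int, fold: int) -> list[str]:
        amap = self.assignment[repeat]
        return [m for m, f in amap.items() if f == fold]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "assignment": self.assignment,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            n_repeats=d["n_repeats"],
            n_folds=d["n_folds"],
            assignment=[{m: int(f) for m, f in amap.items()} for amap in d["assignment"]],
            seed=d["seed"],
        )


def make_fold_plan(
    records: Sequence[MoleculeRecord],
    n_folds: int = 10,
    n_repeats: int = 5,
    seed: int = 1,
) -> FoldPlan:
    """Random molecule-level partition per repeat, reproducible from ``seed``."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(records):
        raise ValueError(f"n_folds={n_folds} exceeds molecule count {len(records)}")
    ids = sorted(r.mol_id for r in records)
    assignment: list[dict[str, int]] = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        order = rng.permutation(len(ids))
        amap: dict[str, int] = {}
        for pos, idx in enumerate(order):
            amap[ids[idx]] = pos % n_folds
        assignment.append(amap)
    return FoldPlan(n_repeats=n_repeats, n_folds=n_folds, assignment=assignment, seed=seed)


def pairs_for_fold(
    plan: FoldPlan,
    repeat: int,
    fold: int,
    records: Sequence[MoleculeRecord],
    include_self_pairs: bool = True,
) -> tuple[PairSet, PairSet]:
    """Cross-merge train (outside fold) and test (inside fold) molecules separately."""
    if not 0 <= repeat < plan.n_repeats:
        raise IndexError(f"repeat {repeat} out of range")
    if not 0 <= fold < plan.n_folds:
        raise IndexError(f"fold {fold} out of range")
    amap = plan.assignment[repeat]
    train_recs = [r for r in records if amap[r.mol_id] != fold]
    test_recs = [r for r in records if amap[r.mol_id] == fold]
    train = cross_merge(train_recs, include_self_pairs, origin="train")
    test = cross_merge(test_recs, include_self_pairs, origin="test")
    return train, test


def leakage_check(train: PairSet, test: PairSet) -> bool:
    """True iff no molecule appears in both pair sets."""
    return not (train.molecule_ids & test.molecule_ids)


def pairset_to_frame(
    pairs: PairSet, smiles_by_id: dict[str, str] | None = None
) -> pd.DataFrame:
    """Pair table with columns smiles_1, smiles_2, delta (mol_ids if no map given)."""
    s1 = [p.first for p in pairs.pairs]
    s2 = [p.second for p in pairs.pairs]
    if smiles_by_id is not None:
        s1 = [smiles_by_id[m] for m in s1]
        s2 = [smiles_by_id[m] for m in s2]
    return pd.DataFrame({"smiles_1": s1, "smiles_2": s2, "delta": [p.true_delta for p in pairs.pairs]})


def write_pairset_csv(
    pairs: PairSet, path: str | Path, smiles_by_id: dict[str, str] | None = None
) -> None:
    pairset_to_frame(pairs, smiles_by_id).to_csv(path, index=False)
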