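"""Model families for property-difference prediction.

Two philosophies are implemented behind one prediction contract:

* *traditional* (predict-then-subtract): a single-molecule regressor is
  fitted on (fingerprint or graph latent -> absolute value); the difference
  prediction for an ordered pair is the subtraction of the two absolute
  predictions. Because subtraction telescopes, these models satisfy the
  zero-self-difference, swap-antisymmetry and triplet-additivity identities
  *exactly*, by construction.
* *delta*: a regressor is fitted directly on ordered pairs with the
  difference as target — concatenated Morgan fingerprints into a gradient
  boosting machine, or two D-MPNN encoders whose latents are concatenated
  and passed through a feed-forward head. Nothing in the architecture
  enforces the pair identities; how well a trained model recovers them is an
  unsupervised diagnostic of its quality.

Every trained model exposes ``predict_delta(pairs)``; traditional models
additionally expose ``predict_value(mol_ids)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, replace, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from lightgbm import LGBMRegressor
from sklearn.ensemble import RandomForestRegressor

from .chemdata import MoleculeRecord
from .features import fingerprint_matrix, pair_feature_matrix
from .graph import Adam, FeedForwardHead, MPNNEncoder, MolecularGraph, mol_to_graph
from .pairing import OrderedPair, PairSet

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "TraditionalTabularModel",
    "GraphTraditionalModel",
    "DeltaTabularModel",
    "GraphDeltaModel",
    "DeltaOracle",
    "train_traditional",
    "train_delta_tabular",
    "train_delta_graph",
    "train_model",
    "predict_delta",
    "predict_delta_by_subtraction",
    "save_model",
    "load_model",
]

Family = Literal[
    "forest_traditional",
    "gbm_traditional",
    "gbm_delta",
    "graph_traditional",
    "graph_delta",
    "oracle",
]

TRADITIONAL_FAMILIES = {"forest_traditional", "gbm_traditional", "graph_traditional"}
DELTA_FAMILIES = {"gbm_delta", "graph_delta"}

# datasets below this molecule count get the small-data LightGBM leaf setting
SMALL_DATASET_CUTOFF = 300
SMALL_MIN_CHILD_SAMPLES = 5


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one model family.

    Defaults follow the benchmark setup: 500-tree random forest; gradient
    boosting with 10% row subsampling per iteration; graph models trained
    for 5 epochs (delta) or 50 epochs (traditional) with sum aggregation.
    ``hidden_size``/``depth``/``ffn_hidden_size``/``learning_rate``/
    ``batch_size`` only affect the graph families and are desk-scale
    choices exposed for tuning.
    """

    family: Family = "gbm_delta"
    n_trees: int = 500
    subsample_freq: float = 0.1
    epochs: int | None = None
    hidden_size: int = 64
    depth: int = 3
    ffn_hidden_size: int = 64
    aggregation: Literal["sum", "mean"] = "sum"
    encoder_sharing: bool = False
    learning_rate: float = 5e-3
    batch_size: int = 256
    fp_radius: int = 2
    fp_bits: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.epochs is not None and self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def resolved_epochs(self) -> int:
        if self.epochs is not None:
            return self.epochs
        return 5 if self.family == "graph_delta" else 50

    @property
    def mode(self) -> str:
        return "traditional" if self.family in TRADITIONAL_FAMILIES else "delta"


class TrainedModel:
    """Common surface: ``predict_delta`` on ordered pairs."""

    config: ModelConfig
    mode: str

    def predict_delta(self, pairs: PairSet) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def register_molecules(self, records: Sequence[MoleculeRecord]) -> None:
        """Make (possibly unseen) molecules resolvable at prediction time.

        Models predict from structure, so prediction on held-out pairs only
        needs the mol_id -> SMILES mapping, never the held-out values.
        """
        mapping = getattr(self, "smiles_by_id", None)
        if mapping is not None:
            mapping.update({r.mol_id: r.canonical_smiles for r in records})


def _quiet_predict(estimator, X) -> np.ndarray:
    # sklearn warns about feature names when mixing array/CSR inputs; the
    # columns are positional fingerprint bits, so the warning is noise here
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        return estimator.predict(X)


def _warn_if_constant(y: np.ndarray, what: str) -> None:
    if len(y) and np.ptp(y) == 0:
        warnings.warn(f"{what} target is constant; fitted model will predict a constant")


def _gbm_params(config: ModelConfig, n_molecules: int, n_rows: int) -> dict:
    params = dict(
        n_estimators=100,
        subsample=config.subsample_freq,
        subsample_freq=1,
        random_state=config.seed,
        n_jobs=1,
        verbose=-1,
    )
    if n_molecules < SMALL_DATASET_CUTOFF:
        params["min_child_samples"] = SMALL_MIN_CHILD_SAMPLES
    # bagging a handful of rows leaves nothing to split on; fall back to
    # full-data boosting when the bagged sample would be degenerate
    if n_rows * config.subsample_freq < 20:
        params["subsample"] = 1.0
        params["subsample_freq"] = 0
    if n_rows < 100:
        params["min_data_in_bin"] = 1
    return params


class TraditionalTabularModel(TrainedModel):
    """Fingerprint -> absolute value regressor (random forest or GBM)."""

    mode = "traditional"

    def __init__(self, config: ModelConfig, estimator, smiles_by_id: dict[str, str]):
        self.config = config
        self.estimator = estimator
        self.smiles_by_id = dict(smiles_by_id)

    def predict_value(self, mol_ids: Sequence[str]) -> np.ndarray:
        X = fingerprint_matrix(
            [self.smiles_by_id[m] for m in mol_ids], self.config.fp_radius, self.config.fp_bits
        )
        return _quiet_predict(self.estimator, X)

    def predict_delta(self, pairs: PairSet) -> np.ndarray:
        return predict_delta_by_subtraction(self, pairs)


class GraphTraditionalModel(TrainedModel):
    """Single D-MPNN encoder + head predicting absolute values."""

    mode = "traditional"

    def __init__(self, config: ModelConfig, encoder: MPNNEncoder, head: FeedForwardHead,
                 smiles_by_id: dict[str, str], y_mean: float, y_scale: float):
        self.config = config
        self.encoder = encoder
        self.head = head
        self.smiles_by_id = dict(smiles_by_id)
        self.y_mean = y_mean
        self.y_scale = y_scale
        self._graph_cache: dict[str, MolecularGraph] = {}

    def _graph(self, mol_id: str) -> MolecularGraph:
        if mol_id not in self._graph_cache:
            self._graph_cache[mol_id] = mol_to_graph(self.smiles_by_id[mol_id])
        return self._graph_cache[mol_id]

    def predict_value(self, mol_ids: Sequence[str]) -> np.ndarray:
        uniq = sorted(set(mol_ids))
        z = np.stack([self.encoder.forward(self._graph(m))[0] for m in uniq])
        raw, _ = self.head.forward(z)
        by_id = {m: v for m, v in zip(uniq, raw)}
        return np.array([by_id[m] * self.y_scale + self.y_mean for m in mol_ids])

    def predict_delta(self, pairs: PairSet) -> np.ndarray:
        return predict_delta_by_subtraction(self, pairs)


class DeltaTabularModel(TrainedModel):
    """Concatenated pair fingerprints -> difference, via gradient boosting."""

    mode = "delta"

    def __init__(self, config: ModelConfig, estimator, smiles_by_id: dict[str, str]):
        self.config = config
        self.estimator = estimator
        self.smiles_by_id = dict(smiles_by_id)

    def predict_delta(self, pairs: PairSet) -> np.ndarray:
        X = pair_feature_matrix(pairs, self.smiles_by_id, self.config.fp_radius, self.config.fp_bits)
        return _quiet_predict(self.estimator, X)


class GraphDeltaModel(TrainedModel):
    """Two D-MPNN encoders (first/second position) + feed-forward head on
    the concatenated latents, trained directly on pair differences."""

    mode = "delta"

    def __init__(self, config: ModelConfig, encoder_first: MPNNEncoder,
                 encoder_second: MPNNEncoder, head: FeedForwardHead,
                 smiles_by_id: dict[str, str], y_scale: float):
        self.config = config
        self.encoder_first = encoder_first
        self.encoder_second = encoder_second
        self.head = head
        self.smiles_by_id = dict(smiles_by_id)
        self.y_scale = y_scale
        self._graph_cache: dict[str, MolecularGraph] = {}

    def _graph(self, mol_id: str) -> MolecularGraph:
        if mol_id not in self._graph_cache:
            self._graph_cache[mol_id] = mol_to_graph(self.smiles_by_id[mol_id])
        return self._graph_cache[mol_id]

    def predict_delta(self, pairs: PairSet) -> np.ndarray:
        ids = sorted({m for p in pairs.pairs for m in (p.first, p.second)})
        z1 = {m: self.encoder_first.forward(self._graph(m))[0] for m in ids}
        z2 = {m: self.encoder_second.forward(self._graph(m))[0] for m in ids}
        u = np.stack([np.concatenate([z1[p.first], z2[p.second]]) for p in pairs.pairs])
        raw, _ = self.head.forward(u)
        return raw * self.y_scale


class DeltaOracle(TrainedModel):
    """Ground-truth oracle: returns the true difference from a value table.

    Not a model — a plumbing probe. Injected into the evaluation loop it
    must score perfectly, which validates pairing/metric code independent of
    any learning.
    """

    mode = "delta"

    def __init__(self, values_by_id: dict[str, float]):
        self.config = ModelConfig(family="oracle")
        self.values_by_id = dict(values_by_id)

    def register_molecules(self, records: Sequence[MoleculeRecord]) -> None:
        self.values_by_id.update({r.mol_id: r.value for r in records})

    def predict_delta(self, pairs: PairSet) -> np.ndarray:
        v = self.values_by_id
        return np.array([v[p.second] - v[p.first] for p in pairs.pairs])


def predict_delta_by_subtraction(model: TrainedModel, pairs: PairSet) -> np.ndarray:
    """Difference as subtraction of two absolute predictions (telescoping)."""
    if model.mode != "traditional":
        raise ValueError("subtraction path requires a traditional model")
    ids = sorted({m for p in pairs.pairs for m in (p.first, p.second)})
    vals = dict(zip(ids, model.predict_value(ids)))
    return np.array([vals[p.second] - vals[p.first] for p in pairs.pairs])


def predict_delta(model: TrainedModel, pairs: PairSet) -> np.ndarray:
    """Single dispatch: every model answers for ordered pairs, order-preserving."""
    out = np.asarray(model.predict_delta(pairs), dtype=float)
    if out.shape != (len(pairs),):
        raise ValueError(f"prediction length {out.shape} != pair count {len(pairs)}")
    return out


def train_traditional(
    train_records: Sequence[MoleculeRecord], config: ModelConfig
) -> TrainedModel:
    """Fit a single-molecule regressor on (features -> value)."""
    if config.family not in TRADITIONAL_FAMILIES:
        raise ValueError(f"{config.family!r} is not a traditional family")
    if len(train_records) < 2:
        raise ValueError("need >= 2 training molecules")
    smiles_by_id = {r.mol_id: r.canonical_smiles for r in train_records}
    y = np.array([r.value for r in train_records])
    _warn_if_constant(y, "absolute-value")
    if config.family == "graph_traditional":
        return _train_graph_traditional(train_records, config, smiles_by_id, y)
    X = fingerprint_matrix(
        [r.canonical_smiles for r in train_records], config.fp_radius, config.fp_bits
    )
    if config.family == "forest_traditional":
        est = RandomForestRegressor(
            n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
        )
    else:
        est = LGBMRegressor(**_gbm_params(config, len(train_records), len(train_records)))
    est.fit(X, y)
    return TraditionalTabularModel(config, est, smiles_by_id)


def train_delta_tabular(train_pairs: PairSet, smiles_by_id: dict[str, str],
                        config: ModelConfig) -> DeltaTabularModel:
    """Fit gradient boosting on (concatenated pair fingerprints -> delta)."""
    if config.family != "gbm_delta":
        raise ValueError("train_delta_tabular requires family='gbm_delta'")
    if not len(train_pairs):
        raise ValueError("empty pair set")
    X = pair_feature_matrix(train_pairs, smiles_by_id, config.fp_radius, config.fp_bits)
    y = train_pairs.true_deltas
    _warn_if_constant(y, "pair-difference")
    n_molecules = len(train_pairs.molecule_ids)
    est = LGBMRegressor(**_gbm_params(config, n_molecules, len(train_pairs)))
    est.fit(X, y)
    return DeltaTabularModel(config, est, smiles_by_id)


def _train_graph_traditional(records, config, smiles_by_id, y) -> GraphTraditionalModel:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    encoder = MPNNEncoder(config.hidden_size, config.depth, config.aggregation, rng)
    head = FeedForwardHead(config.hidden_size, config.ffn_hidden_size, rng)
    y_mean = float(np.mean(y))
    y_scale = float(np.std(y)) or 1.0
    yn = (y - y_mean) / y_scale
    graphs = [mol_to_graph(smiles_by_id[r.mol_id]) for r in records]
    params = encoder.params + head.params
    opt = Adam(params, lr=config.learning_rate)
    n = len(records)
    bs = min(config.batch_size, n)
    for _ in range(config.resolved_epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            batch = order[start : start + bs]
            zs, caches = [], []
            for i in batch:
                z, c = encoder.forward(graphs[i], need_cache=True)
                zs.append(z)
                caches.append(c)
            Z = np.stack(zs)
            pred, hcache = head.forward(Z, need_cache=True)
            d_out = 2.0 * (pred - yn[batch]) / len(batch)
            eg = encoder.zero_grads()
            hg = head.zero_grads()
            dZ = head.backward(hcache, d_out, hg)
            for c, dz in zip(caches, dZ):
                encoder.backward(c, dz, eg)
            opt.step(eg + hg)
    return GraphTraditionalModel(config, encoder, head, smiles_by_id, y_mean, y_scale)


def train_delta_graph(train_pairs: PairSet, smiles_by_id: dict[str, str],
                      config: ModelConfig) -> GraphDeltaModel:
    """Fit the two-encoder graph delta model by minibatch Adam on MSE.

    Each batch encodes every distinct molecule it touches once per encoder
    position, reuses the latents across all pairs in the batch, and
    backpropagates the summed per-molecule upstream gradients — pair counts
    are quadratic in molecules, so this amortization is what makes
    exhaustive pair training tractable.
    """
    if config.family != "graph_delta":
        raise ValueError("train_delta_graph requires family='graph_delta'")
    if not len(train_pairs):
        raise ValueError("empty pair set")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    enc1 = MPNNEncoder(config.hidden_size, config.depth, config.aggregation, rng)
    enc2 = enc1 if config.encoder_sharing else MPNNEncoder(
        config.hidden_size, config.depth, config.aggregation, rng
    )
    head = FeedForwardHead(2 * config.hidden_size, config.ffn_hidden_size, rng)
    ids = sorted({m for p in train_pairs.pairs for m in (p.first, p.second)})
    idx = {m: i for i, m in enumerate(ids)}
    graphs = [mol_to_graph(smiles_by_id[m]) for m in ids]
    firsts = np.array([idx[p.first] for p in train_pairs.pairs])
    seconds = np.array([idx[p.second] for p in train_pairs.pairs])
    y = train_pairs.true_deltas
    _warn_if_constant(y, "pair-difference")
    y_scale = float(np.std(y)) or 1.0
    yn = y / y_scale
    H = config.hidden_size
    if config.encoder_sharing:
        params = enc1.params + head.params
    else:
        params = enc1.params + enc2.params + head.params
    opt = Adam(params, lr=config.learning_rate)
    n_pairs = len(train_pairs)
    bs = min(config.batch_size, n_pairs)
    for _ in range(config.resolved_epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, bs):
            batch = order[start : start + bs]
            bf, bsnd = firsts[batch], seconds[batch]
            u1, inv1 = np.unique(bf, return_inverse=True)
            u2, inv2 = np.unique(bsnd, return_inverse=True)
            z1s, c1s = zip(*(enc1.forward(graphs[i], need_cache=True) for i in u1))
            z2s, c2s = zip(*(enc2.forward(graphs[i], need_cache=True) for i in u2))
            Z1, Z2 = np.stack(z1s), np.stack(z2s)
            U = np.concatenate([Z1[inv1], Z2[inv2]], axis=1)
            pred, hcache = head.forward(U, need_cache=True)
            d_out = 2.0 * (pred - yn[batch]) / len(batch)
            g1 = enc1.zero_grads()
            g2 = g1 if config.encoder_sharing else enc2.zero_grads()
            hg = head.zero_grads()
            dU = head.backward(hcache, d_out, hg)
            dZ1 = np.zeros_like(Z1)
            dZ2 = np.zeros_like(Z2)
            np.add.at(dZ1, inv1, dU[:, :H])
            np.add.at(dZ2, inv2, dU[:, H:])
            for c, dz in zip(c1s, dZ1):
                enc1.backward(c, dz, g1)
            for c, dz in zip(c2s, dZ2):
                enc2.backward(c, dz, g2)
            if config.encoder_sharing:
                opt.step(g1 + hg)
            else:
                opt.step(g1 + g2 + hg)
    return GraphDeltaModel(config, enc1, enc2, head, smiles_by_id, y_scale)


def train_model(
    config: ModelConfig,
    train_records: Sequence[MoleculeRecord],
    train_pairs: PairSet | None = None,
) -> TrainedModel:
    """Route a config to the right trainer; delta families need train_pairs."""
    if config.family == "oracle":
        return DeltaOracle({r.mol_id: r.value for r in train_records})
    if config.family in TRADITIONAL_FAMILIES:
        return train_traditional(train_records, config)
    if train_pairs is None:
        raise ValueError(f"family {config.family!r} requires train_pairs")
    smiles_by_id = {r.mol_id: r.canonical_smiles for r in train_records}
    if config.family == "gbm_delta":
        return train_delta_tabular(train_pairs, smiles_by_id, config)
    if config.family == "graph_delta":
        return train_delta_graph(train_pairs, smiles_by_id, config)
    raise ValueError(f"unknown family {config.family!r}")


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Persist a model bundle: config JSON + family-specific state."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(model.config), "class": type(model).__name__}
    (directory / "config.json").write_text(json.dumps(meta, indent=2) + "\n")
    (directory / "smiles.json").write_text(
        json.dumps(getattr(model, "smiles_by_id", getattr(model, "values_by_id", {}))) + "\n"
    )
    if isinstance(model, (TraditionalTabularModel, DeltaTabularModel)):
        import pickle

        (directory / "estimator.pkl").write_bytes(pickle.dumps(model.estimator))
    elif isinstance(model, GraphTraditionalModel):
        np.savez(
            directory / "weights.npz",
            *model.encoder.params,
            *model.head.params,
            scale=np.array([model.y_mean, model.y_scale]),
        )
    elif isinstance(model, GraphDeltaModel):
        np.savez(
            directory / "weights.npz",
            *model.encoder_first.params,
            *model.encoder_second.params,
            *model.head.params,
            scale=np.array([model.y_scale]),
        )


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    cls = meta["class"]
    mapping = json.loads((directory / "smiles.json").read_text())
    if cls == "DeltaOracle":
        return DeltaOracle({k: float(v) for k, v in mapping.items()})
    config = ModelConfig(**meta["config"])
    if cls in ("TraditionalTabularModel", "DeltaTabularModel"):
        import pickle

        est = pickle.loads((directory / "estimator.pkl").read_bytes())
        klass = TraditionalTabularModel if cls == "TraditionalTabularModel" else DeltaTabularModel
        return klass(config, est, mapping)
    data = np.load(directory / "weights.npz")
    keys = sorted(
        (k for k in data.files if k != "scale"), key=lambda k: int(k.split("_")[1])
    )
    arrays = [data[k] for k in keys]
    rng = np.random.default_rng(0)
    if cls == "GraphTraditionalModel":
        enc = MPNNEncoder(config.hidden_size, config.depth, config.aggregation, rng)
        head = FeedForwardHead(config.hidden_size, config.ffn_hidden_size, rng)
        for p, a in zip(enc.params + head.params, arrays):
            p[...] = a
        y_mean, y_scale = data["scale"]
        return GraphTraditionalModel(config, enc, head, mapping, float(y_mean), float(y_scale))
    if cls == "GraphDeltaModel":
        enc1 = MPNNEncoder(config.hidden_size, config.depth, config.aggregation, rng)
        enc2 = MPNNEncoder(config.hidden_size, config.depth, config.aggregation, rng)
        head = FeedForwardHead(2 * config.hidden_size, config.ffn_hidden_size, rng)
        for p, a in zip(enc1.params + enc2.params + head.params, arrays):
            p[...] = a
        (y_scale,) = data["scale"]
        return GraphDeltaModel(config, enc1, enc2, head, mapping, float(y_scale))
    raise ValueError(f"unknown model class {cls!r}")
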