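"""Directed message passing neural network (D-MPNN) molecule encoder in NumPy.

The encoder passes messages along *directed* bonds for a fixed number of
steps, then aggregates bond states into atom states and atom states into a
fixed-length molecule latent (sum or mean readout). A feed-forward head maps
one latent (single-molecule regression) or the concatenation of two latents
(pair difference regression) to a scalar. Forward, backward and an Adam
optimizer are implemented explicitly on NumPy arrays, which keeps training
fully deterministic for a given seed on one CPU.

Message scheme, per directed bond b = (u -> v) with reverse bond rev(b):

    h0_b  = relu([x_u ; e_b] W_i)
    h_b^t = relu(h0_b + (sum_{w->u, w != v} h_{w->u}^{t-1}) W_h)
    a_v   = sum_{u->v} h_{u->v}^{T-1}
    z_v   = relu([x_v ; a_v] W_o)
    mol   = sum_v z_v            (aggregation='sum'; 'mean' divides by n_atoms)

Atoms with no bonds (e.g. methane) skip message passing: a_v = 0 and the
readout acts on atom features alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from rdkit import Chem

from .chemdata import CurationError

__all__ = ["MolecularGraph", "mol_to_graph", "MPNNEncoder", "FeedForwardHead", "Adam"]

_ELEMENTS = ["C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

ATOM_FDIM = len(_ELEMENTS) + 1 + 6 + 4 + 1 + len(_HYBRIDIZATIONS) + 1  # 25
BOND_FDIM = len(_BOND_TYPES) + 2  # 6


def _one_hot(value, choices: list) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    feats = _one_hot(atom.GetSymbol(), _ELEMENTS)
    feats += _one_hot(min(atom.GetDegree(), 5), [0, 1, 2, 3, 4])
    feats += _one_hot(atom.GetFormalCharge(), [-1, 0, 1])
    feats.append(1.0 if atom.GetIsAromatic() else 0.0)
    feats += _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
    return feats


def _bond_features(bond: Chem.Bond) -> list[float]:
    feats = _one_hot(bond.GetBondType(), _BOND_TYPES)[:-1]
    # 'other' bond types fold into the aromatic slot being all-zero; explicit
    # flags below carry conjugation and ring membership
    feats.append(1.0 if bond.GetIsConjugated() else 0.0)
    feats.append(1.0 if bond.IsInRing() else 0.0)
    return feats


@dataclass(frozen=True)
class MolecularGraph:
    """Featurized molecule: atom matrix plus directed-bond incidence arrays.

    Every undirected bond yields two directed bonds; ``rev[b]`` is the index
    of the bond opposite to ``b`` (an involution). ``src``/``dst`` give the
    source and destination atom of each directed bond.
    """

    atom_features: np.ndarray  # (n_atoms, ATOM_FDIM)
    bond_features: np.ndarray  # (n_dirbonds, BOND_FDIM)
    src: np.ndarray  # (n_dirbonds,) int
    dst: np.ndarray  # (n_dirbonds,) int
    rev: np.ndarray  # (n_dirbonds,) int

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_directed_bonds(self) -> int:
        return self.bond_features.shape[0]


def mol_to_graph(smiles: str) -> MolecularGraph:
    """Build the directed molecular graph for one SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CurationError(f"SMILES does not parse: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise CurationError(f"empty molecule: {smiles!r}")
    x = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.float64)
    e, src, dst, rev = [], [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        k = len(e)
        e.extend([bf, bf])
        src.extend([u, v])
        dst.extend([v, u])
        rev.extend([k + 1, k])
    return MolecularGraph(
        atom_features=x,
        bond_features=np.array(e, dtype=np.float64).reshape(-1, BOND_FDIM),
        src=np.array(src, dtype=np.intp),
        dst=np.array(dst, dtype=np.intp),
        rev=np.array(rev, dtype=np.intp),
    )


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


class MPNNEncoder:
    """D-MPNN encoder with explicit forward/backward passes."""

    def __init__(
        self,
        hidden_size: int = 64,
        depth: int = 3,
        aggregation: Literal["sum", "mean"] = "sum",
        rng: np.random.Generator | None = None,
    ):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.hidden_size = hidden_size
        self.depth = depth
        self.aggregation = aggregation
        rng = rng or np.random.default_rng(0)
        h = hidden_size

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_in, n_out))

        self.W_i = glorot(ATOM_FDIM + BOND_FDIM, h)
        self.b_i = np.zeros(h)
        self.W_h = glorot(h, h)
        self.b_h = np.zeros(h)
        self.W_o = glorot(ATOM_FDIM + h, h)
        self.b_o = np.zeros(h)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W_i, self.b_i, self.W_h, self.b_h, self.W_o, self.b_o]

    def zero_grads(self) -> list[np.ndarray]:
        return [np.zeros_like(p) for p in self.params]

    def forward(self, g: MolecularGraph, need_cache: bool = False):
        """Encode one molecule; returns (latent, cache-or-None)."""
        x, e, src, dst, rev = g.atom_features, g.bond_features, g.src, g.dst, g.rev
        n_atoms = g.n_atoms
        if g.n_directed_bonds:
            inp0 = np.concatenate([x[src], e], axis=1)
            z0 = inp0 @ self.W_i + self.b_i
            h = h0 = _relu(z0)
            steps = []  # (m_t, mask_t) per message step
            for _ in range(1, self.depth):
                a = np.zeros((n_atoms, self.hidden_size))
                np.add.at(a, dst, h)
                m = a[src] - h[rev]
                z = h0 + m @ self.W_h + self.b_h
                steps.append((m, z > 0))
                h = _relu(z)
            a_final = np.zeros((n_atoms, self.hidden_size))
            np.add.at(a_final, dst, h)
        else:
            inp0 = np.zeros((0, ATOM_FDIM + BOND_FDIM))
            z0 = np.zeros((0, self.hidden_size))
            steps = []
            a_final = np.zeros((n_atoms, self.hidden_size))
        inp_o = np.concatenate([x, a_final], axis=1)
        zo = inp_o @ self.W_o + self.b_o
        h_atom = _relu(zo)
        latent = h_atom.sum(axis=0)
        if self.aggregation == "mean":
            latent = latent / n_atoms
        cache = (g, inp0, z0, steps, inp_o, zo) if need_cache else None
        return latent, cache

    def backward(self, cache, d_latent: np.ndarray, grads: list[np.ndarray]) -> None:
        """Accumulate parameter gradients for one molecule into ``grads``."""
        g, inp0, z0, steps, inp_o, zo = cache
        gW_i, gb_i, gW_h, gb_h, gW_o, gb_o = grads
        n_atoms = g.n_atoms
        scale = 1.0 / n_atoms if self.aggregation == "mean" else 1.0
        d_h_atom = np.broadcast_to(d_latent * scale, zo.shape)
        d_zo = np.where(zo > 0, d_h_atom, 0.0)
        gW_o += inp_o.T @ d_zo
        gb_o += d_zo.sum(axis=0)
        if not g.n_directed_bonds:
            return
        d_inp_o = d_zo @ self.W_o.T
        d_a = d_inp_o[:, ATOM_FDIM:]
        dh = d_a[g.dst]  # grad wrt final bond states through the atom sum
        d_h0_skip = np.zeros_like(dh)
        for m, mask in reversed(steps):
            dz = np.where(mask, dh, 0.0)
            d_h0_skip += dz
            gW_h += m.T @ dz
            gb_h += dz.sum(axis=0)
            dm = dz @ self.W_h.T
            da = np.zeros((n_atoms, self.hidden_size))
            np.add.at(da, g.src, dm)
            dh = da[g.dst] - dm[g.rev]
        d_z0 = np.where(z0 > 0, dh + d_h0_skip, 0.0)
        gW_i += inp0.T @ d_z0
        gb_i += d_z0.sum(axis=0)


class FeedForwardHead:
    """One-hidden-layer regression head on (batched) latent vectors."""

    def __init__(self, in_size: int, hidden_size: int = 64, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        s1 = np.sqrt(6.0 / (in_size + hidden_size))
        self.W1 = rng.uniform(-s1, s1, size=(in_size, hidden_size))
        self.b1 = np.zeros(hidden_size)
        s2 = np.sqrt(6.0 / (hidden_size + 1))
        self.W2 = rng.uniform(-s2, s2, size=(hidden_size, 1))
        self.b2 = np.zeros(1)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def zero_grads(self) -> list[np.ndarray]:
        return [np.zeros_like(p) for p in self.params]

    def forward(self, u: np.ndarray, need_cache: bool = False):
        z1 = u @ self.W1 + self.b1
        a1 = _relu(z1)
        out = (a1 @ self.W2 + self.b2)[:, 0]
        cache = (u, z1, a1) if need_cache else None
        return out, cache

    def backward(self, cache, d_out: np.ndarray, grads: list[np.ndarray]) -> np.ndarray:
        """Accumulate gradients; returns gradient wrt the input batch."""
        u, z1, a1 = cache
        gW1, gb1, gW2, gb2 = grads
        d_out = d_out[:, None]
        gW2 += a1.T @ d_out
        gb2 += d_out.sum(axis=0)
        d_a1 = d_out @ self.W2.T
        d_z1 = np.where(z1 > 0, d_a1, 0.0)
        gW1 += u.T @ d_z1
        gb1 += d_z1.sum(axis=0)
        return d_z1 @ self.W1.T


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 5e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
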