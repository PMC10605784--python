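"""Morgan fingerprints, pair concatenation, and Tanimoto similarity."""

from __future__ import annotations

import warnings
from functools import lru_cache
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chemdata import CurationError
from .pairing import PairSet

__all__ = [
    "morgan_fingerprint",
    "concat_pair",
    "tanimoto",
    "fingerprint_matrix",
    "pair_feature_matrix",
]

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


@lru_cache(maxsize=200_000)
def _fingerprint_cached(canonical_smiles: str, radius: int, n_bits: int) -> bytes:
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise CurationError(f"SMILES does not parse: {canonical_smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8).tobytes()


def morgan_fingerprint(
    canonical_smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> np.ndarray:
    """Binary Morgan circular fingerprint (default radius 2, 2048 bits).

    A deterministic function of the molecule: any SMILES notation of the
    same structure yields identical bits. Cached per (smiles, radius, bits).
    """
    return np.frombuffer(_fingerprint_cached(canonical_smiles, radius, n_bits), dtype=np.uint8).copy()


def concat_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Concatenate two equal-length fingerprints into one ordered pair feature."""
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    return np.concatenate([a, b])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|A n B| / |A u B| on bit sets; symmetric, in [0, 1].

    Two all-zero (featureless) fingerprints are defined as similarity 1.0
    with a warning rather than an error.
    """
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("both fingerprints are all-zero; defining similarity as 1.0")
        return 1.0
    return np.count_nonzero(a & b) / union


def fingerprint_matrix(
    smiles: Sequence[str],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> np.ndarray:
    """Stack fingerprints row-wise into an (n, n_bits) uint8 array."""
    return np.stack([morgan_fingerprint(s, radius, n_bits) for s in smiles])


def pair_feature_matrix(
    pairs: PairSet,
    smiles_by_id: dict[str, str],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> sp.csr_matrix:
    """Sparse (n_pairs, 2*n_bits) matrix of concatenated pair fingerprints.

    Fingerprints are computed once per distinct molecule; rows are assembled
    sparse because Morgan bit density is low and pair counts are quadratic.
    """
    ids = sorted({m for p in pairs.pairs for m in (p.first, p.second)})
    idx = {m: i for i, m in enumerate(ids)}
    fps = sp.csr_matrix(
        fingerprint_matrix([smiles_by_id[m] for m in ids], radius, n_bits).astype(np.float32)
    )
    rows_first = np.array([idx[p.first] for p in pairs.pairs])
    rows_second = np.array([idx[p.second] for p in pairs.pairs])
    return sp.hstack([fps[rows_first], fps[rows_second]], format="csr")
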