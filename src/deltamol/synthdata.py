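"""Synthetic molecule libraries with a controllable additive ground truth.

Molecules are built by decorating ring cores (benzene, pyridine,
cyclohexane, furan, thiophene, naphthalene) with up to three substituents
drawn from a small medicinal-chemistry grammar (halogens, alkyls, hydroxy,
amino, nitro, methoxy, carboxyl, nitrile). The noiseless property of a
molecule is the scaffold's base value plus the sum of its substituents'
contributions — an additive structure-property landscape on a log-like
scale, mimicking the size (hundreds to ~1,300 molecules) and value scale of
typical ADMET benchmark tables. Observed values add Gaussian noise and an
optional constant assay offset; the offset shifts every absolute value but
cancels in every pairwise difference, which is exactly the systematic-error
cancellation pairing buys.

Everything is deterministic per seed, and every emitted SMILES is valid by
construction (each decorated template is parsed and canonicalized through
RDKit before acceptance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chemdata import MoleculeRecord, PropertyDataset, TransformSpec, canonicalize

__all__ = [
    "ScaffoldCore",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_library",
    "make_benchmark_suite",
    "DEFAULT_CORES",
    "DEFAULT_SUBSTITUENTS",
]


@dataclass(frozen=True)
class ScaffoldCore:
    """A ring core as a format template with `{0}`-style substituent slots."""

    name: str
    template: str
    n_slots: int
    base_value: float


# Slots hold either '' (hydrogen) or a parenthesized branch like '(F)'.
DEFAULT_CORES: tuple[ScaffoldCore, ...] = (
    ScaffoldCore("benzene", "c1cc{0}cc{1}c1{2}", 3, 1.0),
    ScaffoldCore("pyridine", "c1cc{0}nc{1}c1{2}", 3, 0.4),
    ScaffoldCore("cyclohexane", "C1CC{0}CC{1}C1{2}", 3, 1.6),
    ScaffoldCore("furan", "c1cc{0}oc1{1}", 2, 0.2),
    ScaffoldCore("thiophene", "c1cc{0}sc1{1}", 2, 0.8),
    ScaffoldCore("naphthalene", "c1ccc2cc{0}c{1}cc2c1{2}", 3, 2.2),
)

# substituent SMILES fragment -> additive contribution to the property
DEFAULT_SUBSTITUENTS: dict[str, float] = {
    "": 0.0,  # hydrogen (slot left empty)
    "F": 0.30,
    "Cl": 0.55,
    "Br": 0.70,
    "C": 0.25,
    "CC": 0.45,
    "O": -0.40,
    "N": -0.55,
    "[N+](=O)[O-]": -0.80,
    "OC": -0.15,
    "C(=O)O": -1.00,
    "C#N": -0.60,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Controls for one synthetic dataset.

    ``noise_sd`` is the SD of Gaussian noise added to the noiseless value
    (on the property's log-like scale); ``assay_offset`` is a constant added
    to every observed value, invisible to pair differences.
    """

    n_molecules: int = 300
    cores: tuple[ScaffoldCore, ...] = DEFAULT_CORES
    substituents: tuple[tuple[str, float], ...] = tuple(DEFAULT_SUBSTITUENTS.items())
    noise_sd: float = 0.1
    assay_offset: float = 0.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_molecules < 2:
            raise ValueError("n_molecules must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.cores or not self.substituents:
            raise ValueError("core and substituent libraries must be nonempty")


@dataclass
class SyntheticDataset:
    """A PropertyDataset plus its latent noiseless truth."""

    dataset: PropertyDataset
    noiseless: dict[str, float]
    config: GeneratorConfig

    @property
    def records(self) -> list[MoleculeRecord]:
        return self.dataset.records


_GRID = 2.0**20


def _quantize(v: float) -> float:
    """Snap a value to a 2^-20 grid (~1e-6, far below assay noise).

    With values and the assay offset on a common dyadic grid, every sum and
    difference is exactly representable in float64, so a constant offset
    cancels *bit-exactly* in every pair difference instead of merely to
    rounding error.
    """
    return round(v * _GRID) / _GRID


def _combinatorial_space(config: GeneratorConfig) -> int:
    k = len(config.substituents)
    return sum(k**core.n_slots for core in config.cores)


def generate_library(config: GeneratorConfig) -> SyntheticDataset:
    """Sample ``n_molecules`` distinct decorated structures.

    Noiseless value = core base + sum of substituent contributions; observed
    value = noiseless + N(0, noise_sd) + assay_offset. Duplicate structures
    (distinct decorations can canonicalize to the same molecule by symmetry)
    are rejected, so values are a function of the structure alone.
    """
    space = _combinatorial_space(config)
    if space < config.n_molecules * 2:
        raise ValueError(
            f"combinatorial space {space} too small for {config.n_molecules} distinct "
            f"molecules (need >= {config.n_molecules * 2} candidates); extend the libraries"
        )
    rng = np.random.default_rng(config.seed)
    frags = [f for f, _ in config.substituents]
    contrib = dict(config.substituents)
    seen: dict[str, float] = {}
    order: list[str] = []
    attempts = 0
    max_attempts = 200 * config.n_molecules
    while len(order) < config.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could only realize {len(order)} of {config.n_molecules} distinct "
                f"molecules after {max_attempts} draws; extend the libraries"
            )
        core = config.cores[rng.integers(len(config.cores))]
        picks = [frags[rng.integers(len(frags))] for _ in range(core.n_slots)]
        smiles = core.template.format(*(f"({p})" if p else "" for p in picks))
        canon = canonicalize(smiles)  # validates; raises on a bad template
        if canon in seen:
            continue
        value = core.base_value + sum(contrib[p] for p in picks)
        seen[canon] = value
        order.append(canon)
    noise = rng.normal(0.0, config.noise_sd, size=len(order)) if config.noise_sd else np.zeros(len(order))
    width = max(4, len(str(len(order))))
    records = []
    noiseless = {}
    offset = _quantize(config.assay_offset)
    for i, smi in enumerate(order):
        mol_id = f"{config.name}:{i:0{width}d}"
        noiseless[mol_id] = _quantize(seen[smi])
        records.append(
            MoleculeRecord(mol_id, smi, _quantize(seen[smi] + float(noise[i])) + offset)
        )
    dataset = PropertyDataset(
        name=config.name,
        records=records,
        transform=TransformSpec("identity", 0.0),
        provenance_log=[("generated", len(records))],
    )
    return SyntheticDataset(dataset=dataset, noiseless=noiseless, config=config)


def make_benchmark_suite(
    sizes: Sequence[int],
    noise_levels: Sequence[float],
    seed: int = 0,
    assay_offset: float = 0.0,
) -> list[SyntheticDataset]:
    """One dataset per (size, noise) combination with derived seeds."""
    if not sizes or not noise_levels:
        raise ValueError("sizes and noise_levels must be nonempty")
    out = []
    for i, size in enumerate(sizes):
        for j, noise in enumerate(noise_levels):
            sub_seed = int(
                np.random.SeedSequence([seed, i, j]).generate_state(1, np.uint32)[0] % (2**31)
            )
            cfg = GeneratorConfig(
                n_molecules=size,
                noise_sd=noise,
                assay_offset=assay_offset,
                seed=sub_seed,
                name=f"synthetic_n{size}_sd{noise:g}",
            )
            out.append(generate_library(cfg))
    return out
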