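"""Curation of molecule/property tables.

Raw tables (one SMILES column, one numeric property column) are filtered,
canonicalized, deduplicated and value-transformed into a
:class:`PropertyDataset`, the input container for pairing and modelling.
Every removal is counted per rule in a provenance log so curation is fully
auditable and byte-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

import math

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RawRecord",
    "MoleculeRecord",
    "TransformSpec",
    "PropertyDataset",
    "CurationError",
    "canonicalize",
    "parse_table",
    "parse_value",
    "apply_transform",
    "curate",
    "read_table",
    "dedup_against",
    "write_dataset_csv",
    "write_provenance_json",
]


class CurationError(ValueError):
    """Raised when curation cannot produce a usable dataset."""


@dataclass(frozen=True)
class RawRecord:
    """One row of an uncurated table; ``value_text`` may carry a '<'/'>' qualifier."""

    smiles_text: str
    value_text: str
    source_row: int


@dataclass(frozen=True)
class MoleculeRecord:
    """A curated molecule: canonical SMILES plus its (transformed) property value."""

    mol_id: str
    canonical_smiles: str
    value: float


@dataclass(frozen=True)
class TransformSpec:
    """Value transform applied at curation time.

    kind='log10' maps v -> log10(v + pre_offset); kind='identity' leaves
    values untouched (used when negative values prohibit the log, as for
    hydration free energies). ``pre_offset`` shifts values before the log so
    that zero-valued assay readouts (e.g. renal clearance) stay finite.
    """

    kind: Literal["log10", "identity"] = "log10"
    pre_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("log10", "identity"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.pre_offset < 0:
            raise ValueError("pre_offset must be >= 0")
        if self.kind == "identity" and self.pre_offset != 0:
            raise ValueError("identity transform requires pre_offset = 0")


@dataclass
class PropertyDataset:
    """A curated, deduplicated set of molecules with one value each."""

    name: str
    records: list[MoleculeRecord]
    transform: TransformSpec = field(default_factory=TransformSpec)
    provenance_log: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        smiles = [r.canonical_smiles for r in self.records]
        if len(set(smiles)) != len(smiles):
            raise CurationError(f"dataset {self.name!r} contains duplicate structures")
        if len(self.records) < 2:
            raise CurationError(
                f"dataset {self.name!r} has {len(self.records)} molecules; need >= 2"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def values(self) -> dict[str, float]:
        return {r.mol_id: r.value for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mol_id": [r.mol_id for r in self.records],
                "smiles": [r.canonical_smiles for r in self.records],
                "value": [r.value for r in self.records],
            }
        )


def canonicalize(smiles_text: str) -> str:
    """Return RDKit's canonical SMILES; idempotent by construction.

    Raises ``CurationError`` naming the offending string on parse failure.
    """
    mol = Chem.MolFromSmiles(smiles_text)
    if mol is None:
        raise CurationError(f"SMILES does not parse: {smiles_text!r}")
    return Chem.MolToSmiles(mol)


def parse_value(value_text: str) -> float:
    """Parse a numeric value; decimal and scientific notation, locale-independent."""
    return float(str(value_text).strip())


def parse_table(
    rows: Sequence[RawRecord],
) -> tuple[list[RawRecord], list[tuple[str, int]]]:
    """Filter raw rows, returning survivors and a per-rule removal log.

    Rules applied, in order, per row:
      * ``qualifier``      — value annotated '<' or '>' instead of an exact number
      * ``invalid_value``  — value text is not numeric
      * ``invalid_smiles`` — structure does not parse

    Raises ``CurationError`` if nothing survives.
    """
    if not rows:
        raise CurationError("empty input table")
    kept: list[RawRecord] = []
    counts = {"qualifier": 0, "invalid_value": 0, "invalid_smiles": 0}
    for row in rows:
        vt = str(row.value_text).strip()
        if vt.startswith("<") or vt.startswith(">"):
            counts["qualifier"] += 1
            continue
        try:
            v = parse_value(vt)
        except ValueError:
            counts["invalid_value"] += 1
            continue
        if not math.isfinite(v):
            counts["invalid_value"] += 1
            continue
        if Chem.MolFromSmiles(row.smiles_text) is None:
            counts["invalid_smiles"] += 1
            continue
        kept.append(row)
    if not kept:
        raise CurationError("no rows survived filtering; dataset unusable")
    return kept, [(rule, n) for rule, n in counts.items()]


def apply_transform(values: Sequence[float], spec: TransformSpec) -> list[float]:
    """Apply the dataset value transform elementwise.

    For log10, every ``value + pre_offset`` must be strictly positive; the
    error lists the offending positions.
    """
    if spec.kind == "identity":
        return [float(v) for v in values]
    bad = [i for i, v in enumerate(values) if v + spec.pre_offset <= 0]
    if bad:
        raise CurationError(
            f"log10 transform undefined for rows {bad}: value + {spec.pre_offset} <= 0"
        )
    return [math.log10(v + spec.pre_offset) for v in values]


def curate(
    rows: Sequence[RawRecord],
    name: str,
    transform: TransformSpec | None = None,
    substitutions: Mapping[str, str] | None = None,
    id_prefix: str | None = None,
) -> PropertyDataset:
    """Full curation pipeline: filter, canonicalize, dedup-within, transform.

    ``substitutions`` is an optional user-supplied SMILES correction table
    (raw text -> replacement), applied before parsing; it stands in for
    manual fixes of mis-annotated structures.

    Duplicate canonical structures keep the first occurrence; the count of
    dropped duplicates is logged under rule ``duplicate_structure``.
    """
    transform = transform or TransformSpec()
    if substitutions:
        rows = [
            RawRecord(substitutions.get(r.smiles_text, r.smiles_text), r.value_text, r.source_row)
            for r in rows
        ]
    kept, log = parse_table(rows)
    seen: dict[str, int] = {}
    uniq: list[tuple[str, float]] = []
    n_dup = 0
    for row in kept:
        smi = canonicalize(row.smiles_text)
        if smi in seen:
            n_dup += 1
            continue
        seen[smi] = len(uniq)
        uniq.append((smi, parse_value(row.value_text)))
    log.append(("duplicate_structure", n_dup))
    values = apply_transform([v for _, v in uniq], transform)
    prefix = id_prefix if id_prefix is not None else name
    width = max(4, len(str(len(uniq))))
    records = [
        MoleculeRecord(f"{prefix}:{i:0{width}d}", smi, val)
        for i, ((smi, _), val) in enumerate(zip(uniq, values))
    ]
    return PropertyDataset(name=name, records=records, transform=transform, provenance_log=log)


def read_table(
    path: str | Path,
    smiles_col: str = "smiles",
    value_col: str = "value",
) -> list[RawRecord]:
    """Read a CSV with header into raw records; column names configurable."""
    df = pd.read_csv(path, dtype=str)
    for col in (smiles_col, value_col):
        if col not in df.columns:
            raise CurationError(f"column {col!r} missing from {path} (have {list(df.columns)})")
    return [
        RawRecord(str(s), str(v), i)
        for i, (s, v) in enumerate(zip(df[smiles_col], df[value_col]))
    ]


def dedup_against(
    candidates: PropertyDataset,
    reference: PropertyDataset,
    threshold: float = 1.0,
) -> PropertyDataset:
    """Drop candidate molecules too similar to any reference molecule.

    Similarity is Tanimoto on Morgan fingerprints (radius 2, 2048 bits); a
    candidate is removed when its maximum similarity to the reference set is
    >= ``threshold``. Used to keep external test sets disjoint from training
    data (threshold 1.0 removes exact structural matches).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    from .features import morgan_fingerprint, tanimoto

    ref_fps = [morgan_fingerprint(r.canonical_smiles) for r in reference.records]
    kept = []
    n_removed = 0
    for rec in candidates.records:
        fp = morgan_fingerprint(rec.canonical_smiles)
        if ref_fps and max(tanimoto(fp, rf) for rf in ref_fps) >= threshold:
            n_removed += 1
        else:
            kept.append(rec)
    if len(kept) < 2:
        raise CurationError(
            f"dedup against {reference.name!r} left {len(kept)} molecules; dataset unusable"
        )
    log = list(candidates.provenance_log) + [("external_duplicate", n_removed)]
    return PropertyDataset(
        name=candidates.name,
        records=kept,
        transform=candidates.transform,
        provenance_log=log,
    )


def write_dataset_csv(dataset: PropertyDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def write_provenance_json(dataset: PropertyDataset, path: str | Path) -> None:
    payload = {
        "dataset": dataset.name,
        "n_molecules": len(dataset),
        "transform": {"kind": dataset.transform.kind, "pre_offset": dataset.transform.pre_offset},
        "removals": {rule: n for rule, n in dataset.provenance_log},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
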