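"""Molecule dataset I/O, structure standardization and curation.

Datasets are ordered collections of :class:`MoleculeRecord`, each carrying a
SMILES structure and (optionally) an experimental intrinsic aqueous
solubility, ``logS0``, in log10 molar units.  Curation follows the usual
QSPR bookkeeping: structures are canonicalized so chemically identical
inputs share one key, raw solubilities in heterogeneous units are converted
to log molar, replicate measurements are aggregated by their median, and
training sets are purged of compounds that occur in a held-out set.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from statistics import median
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import SchemaError, SmilesParseError, UnitConversionError

RDLogger.DisableLog("rdApp.*")  # RDKit parse warnings are surfaced as exceptions


class Role(str, Enum):
    """Dataset role of a compound."""

    TRAIN = "train"
    VALIDATION = "validation"
    TEST = "test"
    UNASSIGNED = "unassigned"


class SolubilityUnit(str, Enum):
    MOLAR = "molar"
    MG_PER_ML = "mg_per_mL"
    UG_PER_ML = "ug_per_mL"
    LOG_MOLAR = "log_molar"


@dataclass
class MoleculeRecord:
    """One compound: identifier, structure and optional experimental logS0."""

    id: str
    smiles: str
    name: Optional[str] = None
    logS0_exp: Optional[float] = None
    role: Role = Role.UNASSIGNED
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("record id must be non-empty")
        if isinstance(self.role, str) and not isinstance(self.role, Role):
            self.role = Role(self.role)
        if self.logS0_exp is not None and not math.isfinite(self.logS0_exp):
            raise SchemaError(f"logS0 for {self.id!r} is not finite")


@dataclass
class RawSolubilityEntry:
    """A raw solubility measurement in one of the supported units."""

    compound_id: str
    value: float
    unit: SolubilityUnit
    molecular_weight: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.unit, str) and not isinstance(self.unit, SolubilityUnit):
            self.unit = SolubilityUnit(self.unit)
        if self.unit is not SolubilityUnit.LOG_MOLAR and self.value <= 0:
            raise UnitConversionError(
                f"{self.compound_id}: solubility must be positive in unit {self.unit.value}"
            )
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise UnitConversionError(
                f"{self.compound_id}: molecular weight must be positive"
            )


@dataclass
class Dataset:
    """Ordered collection of molecule records."""

    records: list[MoleculeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def validate_unique_ids(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise SchemaError(f"duplicate record id: {r.id!r}")
            seen.add(r.id)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def standardize_structure(smiles: str, keep_largest_fragment: bool = False) -> str:
    """Canonicalize a SMILES under one aromaticity/nitro convention.

    RDKit sanitization perceives aromaticity (so Kekulé and aromatic inputs
    converge) and rewrites hypervalent nitro groups to the charge-separated
    ``[N+](=O)[O-]`` dialect.  Multi-fragment inputs (salts, mixtures) are
    rejected unless ``keep_largest_fragment`` is set, in which case the
    fragment with the most heavy atoms (carbon-containing fragments
    preferred) is retained.

    The returned canonical SMILES is the dataset's structure key: chemically
    identical inputs map to identical strings and the function is idempotent.
    """
    mol = _mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        if not keep_largest_fragment:
            raise SmilesParseError(
                smiles, "multi-fragment structure (pass keep_largest_fragment=True)"
            )
        def frag_key(m: Chem.Mol) -> tuple:
            has_c = any(a.GetSymbol() == "C" for a in m.GetAtoms())
            return (has_c, m.GetNumHeavyAtoms(), Chem.MolToSmiles(m))
        mol = max(frags, key=frag_key)
    return Chem.MolToSmiles(mol)


def structure_key(record: MoleculeRecord, **kw) -> str:
    """Canonical structure key of a record (standardized canonical SMILES)."""
    return standardize_structure(record.smiles, **kw)


def to_log_molar(entry: RawSolubilityEntry) -> float:
    """Convert a raw solubility entry to log10 molar.

    Mass-based units require the molecular weight (g/mol); log-molar values
    pass through unchanged.
    """
    unit = entry.unit
    if unit is SolubilityUnit.LOG_MOLAR:
        return float(entry.value)
    if unit is SolubilityUnit.MOLAR:
        return math.log10(entry.value)
    # mass-based units: mg/mL == g/L; µg/mL == mg/L
    if entry.molecular_weight is None:
        raise UnitConversionError(
            f"{entry.compound_id}: unit {unit.value} requires a molecular weight"
        )
    grams_per_litre = entry.value if unit is SolubilityUnit.MG_PER_ML else entry.value * 1e-3
    return math.log10(grams_per_litre / entry.molecular_weight)


def from_log_molar(logS0: float, unit: SolubilityUnit, molecular_weight: float | None = None) -> float:
    """Inverse of :func:`to_log_molar` (used for round-trip checks and fixtures)."""
    if unit is SolubilityUnit.LOG_MOLAR:
        return logS0
    molar = 10.0 ** logS0
    if unit is SolubilityUnit.MOLAR:
        return molar
    if molecular_weight is None:
        raise UnitConversionError(f"unit {unit.value} requires a molecular weight")
    grams_per_litre = molar * molecular_weight
    return grams_per_litre if unit is SolubilityUnit.MG_PER_ML else grams_per_litre * 1e3


def aggregate_duplicates(dataset: Dataset, keep_largest_fragment: bool = False) -> Dataset:
    """Merge records that share a canonical structure key.

    The merged record keeps the first id/name/role seen for the key, the
    standardized SMILES as structure, the union of provenance sources, and
    the median of the contributing experimental logS0 values (even-sized
    groups take the midpoint of the two central values).
    """
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in dataset:
        key = standardize_structure(rec.smiles, keep_largest_fragment=keep_largest_fragment)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    merged: list[MoleculeRecord] = []
    for key in order:
        members = groups[key]
        first = members[0]
        values = [m.logS0_exp for m in members if m.logS0_exp is not None]
        sources: list[str] = []
        for m in members:
            for s in m.sources or (m.id,):
                if s not in sources:
                    sources.append(s)
        merged.append(
            replace(
                first,
                smiles=key,
                logS0_exp=float(median(values)) if values else None,
                sources=tuple(sources),
            )
        )
    return Dataset(merged)


def remove_overlap(
    training: Dataset, held_out: Dataset, keep_largest_fragment: bool = False
) -> tuple[Dataset, Dataset]:
    """Remove from ``training`` every compound whose structure occurs in ``held_out``.

    Returns ``(kept, removed)``; removed compounds are typically routed to a
    validation set since the held-out reference values differ from the
    training-source values.
    """
    kw = {"keep_largest_fragment": keep_largest_fragment}
    held_keys = {standardize_structure(r.smiles, **kw) for r in held_out}
    kept, removed = [], []
    for rec in training:
        if standardize_structure(rec.smiles, **kw) in held_keys:
            removed.append(rec)
        else:
            kept.append(rec)
    return Dataset(kept), Dataset(removed)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

DATASET_COLUMNS = ("id", "smiles", "name", "logS0", "role")
_MANDATORY = ("id", "smiles")


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_dataset(path: str | Path, delimiter: str | None = None) -> Dataset:
    """Read a molecule table (CSV/TSV with header ``id,smiles,name,logS0,role``)."""
    path = Path(path)
    delimiter = delimiter or _delimiter_for(path)
    records: list[MoleculeRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _MANDATORY if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")
        for row in reader:
            logs0 = row.get("logS0", "")
            records.append(
                MoleculeRecord(
                    id=row["id"],
                    smiles=row["smiles"],
                    name=(row.get("name") or None),
                    logS0_exp=float(logs0) if logs0 not in (None, "") else None,
                    role=Role(row.get("role") or "unassigned"),
                    sources=tuple(filter(None, (row.get("source"),))),
                )
            )
    ds = Dataset(records)
    ds.validate_unique_ids()
    return ds


def write_dataset(dataset: Dataset, path: str | Path, delimiter: str | None = None) -> None:
    """Write a molecule table; missing logS0 values become empty cells."""
    path = Path(path)
    delimiter = delimiter or _delimiter_for(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(DATASET_COLUMNS)
        for r in dataset:
            writer.writerow(
                [
                    r.id,
                    r.smiles,
                    r.name or "",
                    "" if r.logS0_exp is None else repr(r.logS0_exp),
                    r.role.value,
                ]
            )


def read_smiles_file(path: str | Path) -> Dataset:
    """Read a one-SMILES-per-line file (optional tab-separated id)."""
    path = Path(path)
    records = []
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            rec_id = parts[1] if len(parts) > 1 and parts[1] else f"mol{i}"
            records.append(MoleculeRecord(id=rec_id, smiles=smiles))
    ds = Dataset(records)
    ds.validate_unique_ids()
    return ds


def write_smiles_file(dataset: Dataset, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in dataset:
            fh.write(f"{r.smiles}\t{r.id}\n")
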