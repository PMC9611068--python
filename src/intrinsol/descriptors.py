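"""The six model descriptors and descriptor-matrix assembly/prefiltering.

Three descriptors are implemented from first principles because their exact
dialect matters to the published model coefficients:

* ``SM04_EA_bo`` — natural log of the fourth spectral moment of the
  bond-order-weighted edge adjacency matrix (Estrada's convention: bond
  orders on the diagonal, 1 for incident bond pairs off-diagonal).
* ``SpMax1_Bhp`` — largest absolute eigenvalue of a Burden-type matrix over
  heavy atoms with relative atomic polarizabilities (carbon ≡ 1) on the
  diagonal, 0.1 × bond order for bonded pairs and 0.001 otherwise.
* ``SHBd`` — sum of Kier–Hall electrotopological states over hydrogen-bond
  donor atoms (N/O bearing at least one hydrogen).

``TPSA`` (Ertl group contributions) and ``MolLogP`` (Wildman–Crippen atom
contributions) delegate to RDKit.  ``ALOGP2`` squares a pluggable
atom-contribution logP provider (default: Wildman–Crippen).  ``XlogS`` is a
pluggable input column: the group-contribution solubility estimate is
supplied per compound, never computed here.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors as RDDescriptors

from .chemio import standardize_structure
from .errors import (
    DescriptorUndefinedError,
    EmptyMatrixError,
    SmilesParseError,
)

# ---------------------------------------------------------------------------
# Atom parameter tables
# ---------------------------------------------------------------------------

#: Static atomic dipole polarizabilities, Å³ (CRC Handbook values).
ATOMIC_POLARIZABILITY = {
    "H": 0.667,
    "B": 3.03,
    "C": 1.76,
    "N": 1.10,
    "O": 0.802,
    "F": 0.557,
    "Si": 5.38,
    "P": 3.63,
    "S": 2.90,
    "Cl": 2.18,
    "As": 4.31,
    "Se": 3.77,
    "Br": 3.05,
    "I": 5.35,
}

#: Polarizabilities relative to carbon (carbon entry exactly 1.0).
RELATIVE_POLARIZABILITY = {
    el: (1.0 if el == "C" else round(val / ATOMIC_POLARIZABILITY["C"], 6))
    for el, val in ATOMIC_POLARIZABILITY.items()
}


def principal_quantum_number(atomic_number: int) -> int:
    """Period (principal quantum number of the valence shell) of an element."""
    for n, upper in enumerate((2, 10, 18, 36, 54, 86, 118), start=1):
        if atomic_number <= upper:
            return n
    raise DescriptorUndefinedError("SHBd", f"no period for Z={atomic_number}")


@dataclass(frozen=True)
class AtomParams:
    """Per-atom parameters entering the graph-theoretical descriptors."""

    relative_polarizability: Mapping[str, float] = field(
        default_factory=lambda: dict(RELATIVE_POLARIZABILITY)
    )


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def conventional_bond_order(bond: Chem.Bond) -> float:
    """Conventional bond order: 1/2/3 and 1.5 for aromatic bonds."""
    if bond.GetIsAromatic():
        return 1.5
    try:
        return _BOND_ORDER[bond.GetBondType()]
    except KeyError:
        raise DescriptorUndefinedError(
            "bond_order", f"unsupported bond type {bond.GetBondType()}"
        ) from None


def as_mol(molecule: str | Chem.Mol) -> Chem.Mol:
    """Accept a SMILES or an RDKit Mol; SMILES are standardized first."""
    if isinstance(molecule, Chem.Mol):
        return molecule
    mol = Chem.MolFromSmiles(standardize_structure(molecule))
    if mol is None:  # pragma: no cover - standardize already validates
        raise SmilesParseError(str(molecule))
    return mol


# ---------------------------------------------------------------------------
# Descriptor implementations
# ---------------------------------------------------------------------------

def edge_adjacency_matrix(mol: Chem.Mol) -> np.ndarray:
    """Bond-order-weighted edge adjacency matrix.

    ``B[i, i]`` is the conventional order of bond *i*; ``B[i, j] = 1`` when
    bonds *i* and *j* share an atom, 0 otherwise.
    """
    bonds = list(mol.GetBonds())
    m = len(bonds)
    B = np.zeros((m, m))
    ends = [
        {b.GetBeginAtomIdx(), b.GetEndAtomIdx()} for b in bonds
    ]
    for i, b in enumerate(bonds):
        B[i, i] = conventional_bond_order(b)
        for j in range(i + 1, m):
            if ends[i] & ends[j]:
                B[i, j] = B[j, i] = 1.0
    return B


def calc_sm04_ea_bo(molecule: str | Chem.Mol) -> float:
    """Spectral moment of order 4 of the edge adjacency matrix, log scale.

    Returns ``ln(trace(B⁴))``.  Undefined for molecules without bonds.
    """
    mol = as_mol(molecule)
    if mol.GetNumBonds() == 0:
        raise DescriptorUndefinedError("SM04_EA_bo", "molecule has no bonds")
    B = edge_adjacency_matrix(mol)
    trace = float(np.trace(np.linalg.matrix_power(B, 4)))
    return math.log(trace)


def wildman_crippen_logp(molecule: str | Chem.Mol) -> float:
    """Wildman–Crippen atom-contribution octanol/water logP (RDKit)."""
    return float(Crippen.MolLogP(as_mol(molecule)))


def calc_mollogp(molecule: str | Chem.Mol) -> float:
    """Octanol/water partition coefficient, Wildman–Crippen atom contributions."""
    return wildman_crippen_logp(molecule)


def calc_alogp2(
    molecule: str | Chem.Mol,
    logp_provider: Callable[[Chem.Mol], float] | None = None,
) -> float:
    """Squared atom-contribution logP.

    ``logp_provider`` abstracts the atom-contribution scheme (Ghose–Crippen
    in the original descriptor; Wildman–Crippen by default here — the two
    schemes differ only in their atom-type tables).
    """
    provider = logp_provider or wildman_crippen_logp
    try:
        logp = float(provider(as_mol(molecule)))
    except DescriptorUndefinedError:
        raise
    except Exception as exc:  # provider failures carry the descriptor name
        raise DescriptorUndefinedError("ALOGP2", f"logP provider failed: {exc}") from exc
    return logp * logp


def atom_contribution_provider(contributions: Mapping[str, float]) -> Callable[[Chem.Mol], float]:
    """Build a logP provider summing per-element contributions.

    ``contributions`` maps element symbols (and optionally ``"H"``, applied
    per attached hydrogen) to additive increments.  Intended for plugging in
    published group-contribution tables or synthetic test tables.
    """

    def provider(mol: Chem.Mol) -> float:
        total = 0.0
        h_contrib = contributions.get("H")
        for atom in mol.GetAtoms():
            sym = atom.GetSymbol()
            if sym not in contributions:
                raise DescriptorUndefinedError(
                    "ALOGP2", f"no contribution for element {sym}"
                )
            total += contributions[sym]
            if h_contrib is not None:
                total += h_contrib * atom.GetTotalNumHs()
        return total

    return provider


def calc_tpsa(molecule: str | Chem.Mol) -> float:
    """Topological polar surface area (Ertl group contributions), Å²."""
    return float(RDDescriptors.TPSA(as_mol(molecule)))


def burden_matrix(mol: Chem.Mol, params: AtomParams | None = None) -> np.ndarray:
    """Burden-type matrix over heavy atoms, polarizability-weighted diagonal.

    Diagonal: relative polarizability of the atom (carbon ≡ 1).  Bonded
    off-diagonal: 0.1 × conventional bond order.  Non-bonded: 0.001.
    """
    params = params or AtomParams()
    atoms = list(mol.GetAtoms())
    n = len(atoms)
    M = np.full((n, n), 0.001)
    for i, atom in enumerate(atoms):
        sym = atom.GetSymbol()
        if sym not in params.relative_polarizability:
            raise DescriptorUndefinedError(
                "SpMax1_Bhp", f"element {sym} missing from polarizability table"
            )
        M[i, i] = params.relative_polarizability[sym]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        M[i, j] = M[j, i] = 0.1 * conventional_bond_order(bond)
    return M


def calc_spmax1_bhp(molecule: str | Chem.Mol, params: AtomParams | None = None) -> float:
    """Largest absolute eigenvalue of the polarizability-weighted Burden matrix."""
    mol = as_mol(molecule)
    if mol.GetNumAtoms() == 0:
        raise DescriptorUndefinedError("SpMax1_Bhp", "no heavy atoms")
    M = burden_matrix(mol, params)
    eigenvalues = np.linalg.eigvalsh(M)
    return float(np.max(np.abs(eigenvalues)))


def estate_indices(mol: Chem.Mol) -> np.ndarray:
    """Kier–Hall electrotopological state S_i of every heavy atom.

    Intrinsic state ``I = ((2/N)² δv + 1) / δ`` with N the principal quantum
    number, δv the valence connectivity (valence electrons minus attached
    hydrogens) and δ the heavy-atom connectivity; each atom's intrinsic
    state is perturbed by every other atom, weighted by the inverse squared
    (graph distance + 1).
    """
    pt = Chem.GetPeriodicTable()
    atoms = list(mol.GetAtoms())
    n = len(atoms)
    intrinsic = np.empty(n)
    for i, atom in enumerate(atoms):
        degree = atom.GetDegree()
        if degree == 0:
            raise DescriptorUndefinedError(
                "EState", f"isolated heavy atom {atom.GetSymbol()} (index {i})"
            )
        zv = pt.GetNOuterElecs(atom.GetAtomicNum())
        delta_v = zv - atom.GetTotalNumHs()
        period = principal_quantum_number(atom.GetAtomicNum())
        intrinsic[i] = ((2.0 / period) ** 2 * delta_v + 1.0) / degree
    dist = Chem.GetDistanceMatrix(mol)
    perturbation = (intrinsic[:, None] - intrinsic[None, :]) / (dist + 1.0) ** 2
    return intrinsic + perturbation.sum(axis=1)


def hbd_atom_indices(mol: Chem.Mol, include_sh: bool = False) -> list[int]:
    """Indices of hydrogen-bond donor atoms (N/O with ≥1 H; optionally S-H)."""
    donors = {"N", "O"} | ({"S"} if include_sh else set())
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() in donors and a.GetTotalNumHs() >= 1
    ]


def calc_shbd(molecule: str | Chem.Mol, include_sh: bool = False) -> float:
    """Sum of E-states over hydrogen-bond donor atoms (0 when no donors)."""
    mol = as_mol(molecule)
    donors = hbd_atom_indices(mol, include_sh=include_sh)
    if not donors:
        return 0.0
    states = estate_indices(mol)
    return float(states[donors].sum())


# ---------------------------------------------------------------------------
# Descriptor registry
# ---------------------------------------------------------------------------

class Provider(str, Enum):
    BUILTIN = "builtin"
    TOOLKIT = "toolkit"
    PLUGGABLE = "pluggable"


@dataclass(frozen=True)
class DescriptorSpec:
    name: str
    provider: Provider
    func: Optional[Callable[[Chem.Mol], float]] = None
    doc: str = ""


DESCRIPTOR_REGISTRY: dict[str, DescriptorSpec] = {
    "SM04_EA_bo": DescriptorSpec(
        "SM04_EA_bo", Provider.BUILTIN, calc_sm04_ea_bo,
        "ln spectral moment 4, bond-order-weighted edge adjacency"),
    "ALOGP2": DescriptorSpec(
        "ALOGP2", Provider.BUILTIN, calc_alogp2,
        "squared atom-contribution logP"),
    "TPSA": DescriptorSpec(
        "TPSA", Provider.TOOLKIT, calc_tpsa,
        "Ertl topological polar surface area, Å²"),
    "MolLogP": DescriptorSpec(
        "MolLogP", Provider.TOOLKIT, calc_mollogp,
        "Wildman–Crippen octanol/water logP"),
    "SpMax1_Bhp": DescriptorSpec(
        "SpMax1_Bhp", Provider.BUILTIN, calc_spmax1_bhp,
        "max |eigenvalue| of polarizability-weighted Burden matrix"),
    "SHBd": DescriptorSpec(
        "SHBd", Provider.BUILTIN, calc_shbd,
        "sum of E-states over H-bond donor atoms"),
    "XlogS": DescriptorSpec(
        "XlogS", Provider.PLUGGABLE, None,
        "group-contribution solubility estimate, supplied as input"),
}

MODEL_DESCRIPTORS = tuple(DESCRIPTOR_REGISTRY)


def list_descriptors() -> list[DescriptorSpec]:
    return list(DESCRIPTOR_REGISTRY.values())


# ---------------------------------------------------------------------------
# Descriptor matrix
# ---------------------------------------------------------------------------

@dataclass
class DescriptorMatrix:
    """Compounds × named descriptors; NaN entries are the missing mask."""

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = self.frame.astype(float)
        self.frame.index = self.frame.index.astype(str)
        self.frame.index.name = "id"

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def missing(self) -> pd.DataFrame:
        return self.frame.isna()

    def values_for(self, compound_id: str) -> dict[str, float]:
        row = self.frame.loc[compound_id]
        return {k: float(v) for k, v in row.items() if not pd.isna(v)}

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, na_rep="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        frame = pd.read_csv(path, index_col="id")
        frame.index = frame.index.astype(str)
        return cls(frame)


def compute_descriptors(
    molecules: Iterable,
    names: Sequence[str] = ("SM04_EA_bo", "ALOGP2", "TPSA", "MolLogP", "SpMax1_Bhp", "SHBd"),
    xlogs_table: Mapping[str, float] | None = None,
    logp_provider: Callable[[Chem.Mol], float] | None = None,
) -> tuple[DescriptorMatrix, list[tuple[str, str, str]]]:
    """Compute a descriptor matrix for molecule records (or (id, smiles) pairs).

    Failures are recorded as NaN (the missing mask) and returned in a
    failure log of ``(compound_id, descriptor, reason)``.  ``XlogS`` values,
    when requested, are taken from ``xlogs_table``.
    """
    rows: dict[str, dict[str, float]] = {}
    failures: list[tuple[str, str, str]] = []
    for item in molecules:
        if hasattr(item, "id"):
            cid, smiles = item.id, item.smiles
        else:
            cid, smiles = item
        mol = as_mol(smiles)
        row: dict[str, float] = {}
        for name in names:
            if name == "XlogS":
                table = xlogs_table or {}
                if cid in table:
                    row[name] = float(table[cid])
                else:
                    row[name] = math.nan
                    failures.append((cid, name, "no XlogS value supplied"))
                continue
            spec = DESCRIPTOR_REGISTRY.get(name)
            if spec is None or spec.func is None:
                raise KeyError(f"unknown descriptor {name!r}")
            try:
                if name == "ALOGP2":
                    row[name] = calc_alogp2(mol, logp_provider)
                else:
                    row[name] = float(spec.func(mol))
            except DescriptorUndefinedError as exc:
                row[name] = math.nan
                failures.append((cid, name, exc.reason))
        rows[cid] = row
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
    return DescriptorMatrix(frame), failures


def xlogs_provider(table: Mapping[str, float]) -> Mapping[str, float]:
    """Validate and pass through an XlogS input table (id → value)."""
    clean = {str(k): float(v) for k, v in table.items()}
    for k, v in clean.items():
        if not math.isfinite(v):
            raise DescriptorUndefinedError("XlogS", f"non-finite value for {k!r}")
    return clean


# ---------------------------------------------------------------------------
# Prefiltering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrefilterConfig:
    correlation_threshold: float = 0.9
    drop_missing: bool = True
    drop_zero_variance: bool = True
    name_blacklist: tuple[str, ...] = ()


def prefilter(
    matrix: DescriptorMatrix, config: PrefilterConfig | None = None
) -> tuple[DescriptorMatrix, list[tuple[str, str]]]:
    """Drop missing-value, zero-variance, blacklisted and collinear columns.

    For every pair with |Pearson R| above the threshold the later column (in
    stable column order) is dropped.  Returns the filtered matrix and a
    removal log of ``(column, reason)``.
    """
    config = config or PrefilterConfig()
    frame = matrix.frame
    removed: list[tuple[str, str]] = []
    keep: list[str] = []
    for col in frame.columns:
        series = frame[col]
        if config.drop_missing and series.isna().any():
            removed.append((col, "missing values"))
        elif config.drop_zero_variance and float(series.var(ddof=0)) == 0.0:
            removed.append((col, "zero variance"))
        elif col in config.name_blacklist:
            removed.append((col, "blacklisted name"))
        else:
            keep.append(col)

    # pairwise collinearity on the survivors, stable order
    dropped_corr: set[str] = set()
    if len(keep) > 1:
        corr = frame[keep].corr().to_numpy()
        for i, ci in enumerate(keep):
            if ci in dropped_corr:
                continue
            for j in range(i + 1, len(keep)):
                cj = keep[j]
                if cj in dropped_corr:
                    continue
                if abs(corr[i, j]) > config.correlation_threshold:
                    dropped_corr.add(cj)
                    removed.append((cj, f"|R| > {config.correlation_threshold} with {ci}"))
    keep = [c for c in keep if c not in dropped_corr]
    if not keep:
        raise EmptyMatrixError("prefilter removed every descriptor column")
    return DescriptorMatrix(frame[keep].copy(), dict(matrix.provenance)), removed
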