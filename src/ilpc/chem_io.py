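"""Structure parsing and tabular/model I/O.

Ions are handled one at a time: an ionic liquid is a *pair* of independent
molecular graphs (cation, anion), never a merged salt.  The parser is a thin
wrapper over RDKit that freezes the perceived graph — element, formal charge,
implicit hydrogen count per atom; order, aromaticity and ring membership per
bond — into a plain :class:`MolecularGraph` so every descriptor downstream is
a pure function of that record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

BUNDLE_SCHEMA_VERSION = "ilpc-bundle-v1"

#: bond order encoding used throughout: 1, 2, 3 or the string "aromatic"
BondOrder = Union[int, str]


class StructureParseError(ValueError):
    """SMILES/SDF input that does not describe a single valid ion."""


class SchemaError(ValueError):
    """A tabular or JSON input whose layout does not match the contract."""


class ValidationError(ValueError):
    """Chemically parsed input that violates an IL-record invariant."""


@dataclass(frozen=True)
class MolecularGraph:
    """One ion: atoms (element, formal charge, implicit H) and bonds.

    Invariants are enforced at construction: bond indices valid and distinct,
    no duplicate bonds, the graph connected, and ``net_charge`` equal to the
    sum of formal charges.
    """

    atoms: tuple[tuple[str, int, int], ...]
    bonds: tuple[tuple[int, int, BondOrder, bool], ...]
    net_charge: int

    def __post_init__(self):
        n = len(self.atoms)
        if n == 0:
            raise StructureParseError("graph has no atoms")
        seen = set()
        for i, j, order, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise StructureParseError(f"bond ({i},{j}) references a missing atom")
            if i == j:
                raise StructureParseError(f"self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise StructureParseError(f"duplicate bond {key}")
            seen.add(key)
            if order not in (1, 2, 3, "aromatic"):
                raise StructureParseError(f"unknown bond order {order!r}")
        if self.net_charge != sum(q for _, q, _ in self.atoms):
            raise ValidationError("net_charge does not equal the sum of formal charges")
        if not self._connected():
            raise StructureParseError("not a single ion: graph is disconnected")

    def _connected(self) -> bool:
        n = len(self.atoms)
        if n == 1:
            return True
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j, _, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for k in adj[stack.pop()]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        return len(seen) == n

    def heavy_degree(self, idx: int) -> int:
        """Number of bonds from atom ``idx`` to other heavy atoms."""
        return sum(1 for i, j, _, _ in self.bonds if idx in (i, j))


@dataclass(frozen=True)
class ILRecord:
    """An ionic liquid: identifier plus its cation and anion graphs."""

    il_id: str
    cation: MolecularGraph
    anion: MolecularGraph
    family: str | None = None

    def __post_init__(self):
        if self.cation.net_charge < 1:
            raise ValidationError(
                f"{self.il_id}: cation net charge must be >= +1, got {self.cation.net_charge}")
        if self.anion.net_charge > -1:
            raise ValidationError(
                f"{self.il_id}: anion net charge must be <= -1, got {self.anion.net_charge}")


_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "aromatic",
}


def _graph_from_mol(mol: Chem.Mol, source: str) -> MolecularGraph:
    if mol is None:
        raise StructureParseError(f"could not parse structure: {source!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StructureParseError(f"not a single ion (multiple fragments): {source!r}")
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    )
    bonds = []
    for b in mol.GetBonds():
        order = _ORDER_FROM_RDKIT.get(b.GetBondType())
        if order is None:
            raise StructureParseError(
                f"unsupported bond type {b.GetBondType()} in {source!r}")
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, b.IsInRing()))
    return MolecularGraph(atoms=atoms, bonds=tuple(bonds),
                          net_charge=Chem.GetFormalCharge(mol))


def parse_structure(smiles: str) -> MolecularGraph:
    """Parse a single-ion SMILES into a :class:`MolecularGraph`.

    Aromaticity, ring membership and implicit hydrogens are perceived by
    RDKit; impossible valences are rejected, never silently repaired.
    Deterministic: equal input text gives an equal graph.
    """
    if not smiles or not smiles.strip():
        raise StructureParseError("empty structure text")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"could not parse SMILES: {smiles!r}")
    return _graph_from_mol(mol, smiles)


def read_sdf(path: str | Path) -> list[MolecularGraph]:
    """Read V2000 SDF records into graphs under the same contract as SMILES."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    graphs = []
    for k, mol in enumerate(supplier):
        if mol is None:
            raise StructureParseError(f"unparsable SDF record {k} in {path}")
        graphs.append(_graph_from_mol(mol, f"{path}#{k}"))
    return graphs


_REQUIRED_COLUMNS = ("il_id", "cation_smiles", "anion_smiles")


def read_il_table(path: str | Path) -> list[ILRecord]:
    """Read a CSV of ionic liquids (il_id, cation_smiles, anion_smiles[, family]).

    All rows are validated; failures are aggregated into a single error that
    reports each offending row number and identifier.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records: list[ILRecord] = []
    failures: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        il_id = str(row.il_id)
        try:
            records.append(ILRecord(
                il_id=il_id,
                cation=parse_structure(str(row.cation_smiles)),
                anion=parse_structure(str(row.anion_smiles)),
                family=(str(row.family) if "family" in df.columns
                        and pd.notna(getattr(row, "family", None)) else None),
            ))
        except (StructureParseError, ValidationError) as exc:
            failures.append(f"row {row_no} ({il_id}): {exc}")
    if failures:
        raise ValidationError(f"{path}: {len(failures)} invalid row(s):\n  "
                              + "\n  ".join(failures))
    return records


def write_il_table(records: Iterable[ILRecord], path: str | Path) -> None:
    rows = [{"il_id": r.il_id,
             "cation_smiles": graph_to_smiles(r.cation),
             "anion_smiles": graph_to_smiles(r.anion),
             "family": r.family or ""} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


_ORDER_TO_RDKIT = {v: k for k, v in _ORDER_FROM_RDKIT.items()}


def graph_to_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES for a stored graph (round-trip helper)."""
    mol = Chem.RWMol()
    for sym, charge, n_h in g.atoms:
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(charge)
        atom.SetNumExplicitHs(n_h)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    for i, j, order, _ in g.bonds:
        mol.AddBond(i, j, _ORDER_TO_RDKIT[order])
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def save_bundle(bundle, path: str | Path) -> None:
    """Serialize a fitted model bundle to a single JSON document."""
    doc = bundle.to_dict()
    doc["schema_version"] = BUNDLE_SCHEMA_VERSION
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_bundle(path: str | Path):
    """Load a bundle saved by :func:`save_bundle`; numeric fields round-trip
    bit-exactly (JSON repr of Python floats is shortest-exact)."""
    from .pipeline import ModelBundle  # noqa: PLC0415 — avoid import cycle

    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise SchemaError(f"cannot read bundle {path}: {exc}") from exc
    version = doc.pop("schema_version", None)
    if version != BUNDLE_SCHEMA_VERSION:
        raise SchemaError(
            f"bundle schema version mismatch: file has {version!r}, "
            f"this build reads {BUNDLE_SCHEMA_VERSION!r}")
    return ModelBundle.from_dict(doc)
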