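"""Molecule I/O: SMILES parsing, canonicalization, heavy-atom graphs, tables.

Molecules are represented as heavy-atom graphs: hydrogens are not nodes,
their counts live on the heavy atoms they are attached to. Atom indices are
0-based and contiguous. Multi-component inputs (salts, mixtures) can be
reduced to their largest component before featurization, which avoids
unreachable atom pairs in shortest-path calculations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("herbsig")

#: Molecules heavier than this (Da) are outside the stated applicability
#: domain and trigger a warning, never an error.
APPLICABILITY_MW_DA = 2000.0

AROMATIC_BOND_ORDER = 1.5

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: AROMATIC_BOND_ORDER,
}


class ParseError(ValueError):
    """Malformed SMILES. ``position`` is the 0-based offending token offset."""

    def __init__(self, message: str, position: int = 0):
        super().__init__(f"{message} (position {position})")
        self.position = position


class DatasetError(ValueError):
    """A dataset-level problem (empty, single-class, inconsistent)."""


class ContractError(ValueError):
    """An argument violates a documented precondition."""


class Atom(NamedTuple):
    index: int
    element: str
    formal_charge: int
    n_hydrogens: int
    aromatic: bool


class Bond(NamedTuple):
    i: int
    j: int
    order: float  # 1, 1.5 (aromatic), 2, 3


@dataclass
class MolecularGraph:
    """Undirected heavy-atom graph of a molecule.

    No self-loops, no duplicate edges; ``component_ids`` gives each atom's
    connected-component index (components numbered in order of first
    appearance). The underlying RDKit molecule is retained for descriptor
    and SMARTS work downstream.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    component_ids: list[int]
    rdkit_mol: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_components(self) -> int:
        return max(self.component_ids) + 1 if self.component_ids else 0

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj


@dataclass
class MoleculeRecord:
    """One molecule with an optional binary label or continuous endpoint."""

    id: str
    smiles: str
    label: Optional[int] = None
    value: Optional[float] = None
    endpoint_name: Optional[str] = None


class MoleculeTable(list):
    """A list of :class:`MoleculeRecord` that remembers skipped input lines."""

    skipped: int = 0


def _scan_smiles_syntax(smiles: str) -> None:
    """Cheap syntax scan so parse errors can point at the offending token.

    Catches unbalanced branches ``()``, unbalanced brackets ``[]`` and
    unclosed ring-bond digits; anything subtler is left to RDKit.
    """
    paren_stack: list[int] = []
    bracket_open: Optional[int] = None
    ring_open: dict[str, int] = {}
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if bracket_open is not None:
            if ch == "]":
                bracket_open = None
            i += 1
            continue
        if ch == "[":
            bracket_open = i
        elif ch == "]":
            raise ParseError("unmatched ']'", i)
        elif ch == "(":
            paren_stack.append(i)
        elif ch == ")":
            if not paren_stack:
                raise ParseError("unmatched ')'", i)
            paren_stack.pop()
        elif ch == "%":
            if i + 2 >= len(smiles) or not smiles[i + 1 : i + 3].isdigit():
                raise ParseError("bad %-ring-closure", i)
            key = smiles[i + 1 : i + 3]
            if key in ring_open:
                del ring_open[key]
            else:
                ring_open[key] = i
            i += 3
            continue
        elif ch.isdigit():
            if ch in ring_open:
                del ring_open[ch]
            else:
                ring_open[ch] = i
        i += 1
    if bracket_open is not None:
        raise ParseError("unclosed '['", bracket_open)
    if paren_stack:
        raise ParseError("unclosed '('", paren_stack[0])
    if ring_open:
        pos = min(ring_open.values())
        raise ParseError("unclosed ring bond", pos)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES to a sanitized RDKit molecule or raise :class:`ParseError`."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError("empty SMILES", 0)
    smiles = smiles.strip()
    _scan_smiles_syntax(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError("RDKit could not parse SMILES", 0)
    if mol.GetNumAtoms() == 0:
        raise ParseError("SMILES has no heavy atoms", 0)
    return mol


def graph_from_mol(mol: Chem.Mol) -> MolecularGraph:
    """Build the heavy-atom graph (aromaticity perceived, H collapsed)."""
    atoms = [
        Atom(
            a.GetIdx(),
            a.GetSymbol(),
            a.GetFormalCharge(),
            a.GetTotalNumHs(),
            a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bonds.append(Bond(i, j, _BOND_ORDER.get(b.GetBondType(), 1.0)))
    # connected components by BFS over the bond list, numbered by first visit
    comp = [-1] * len(atoms)
    adj: list[list[int]] = [[] for _ in atoms]
    for b in bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    c = 0
    for start in range(len(atoms)):
        if comp[start] != -1:
            continue
        stack = [start]
        comp[start] = c
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp[v] == -1:
                    comp[v] = c
                    stack.append(v)
        c += 1
    return MolecularGraph(atoms=atoms, bonds=bonds, component_ids=comp, rdkit_mol=mol)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`."""
    return graph_from_mol(mol_from_smiles(smiles))


def canonicalize(smiles: str) -> str:
    """Canonical SMILES; identical for any rendering of the same molecule."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def largest_component(mol: Chem.Mol) -> Chem.Mol:
    """Strip a multi-component molecule to its largest fragment by atom count.

    Ties break toward the first-listed fragment. Single-component molecules
    are returned unchanged.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    best = max(frags, key=lambda m: m.GetNumAtoms())
    logger.info(
        "multi-component molecule reduced to largest component "
        "(%d of %d atoms kept)",
        best.GetNumAtoms(),
        mol.GetNumAtoms(),
    )
    Chem.SanitizeMol(best)
    return best


def prepare_mol(smiles: str, strip_salts: bool = True) -> Chem.Mol:
    """Parse and (by default) keep only the largest component.

    Warns when the molecule exceeds the 2 kDa applicability bound.
    """
    mol = mol_from_smiles(smiles)
    if strip_salts:
        mol = largest_component(mol)
    if Descriptors.MolWt(mol) > APPLICABILITY_MW_DA:
        logger.warning(
            "molecule above %g Da applicability bound: %s",
            APPLICABILITY_MW_DA,
            Chem.MolToSmiles(mol),
        )
    return mol


_TRUE_LABELS = {"1", "active", "true", "yes", "pos", "positive"}
_FALSE_LABELS = {"0", "inactive", "false", "no", "neg", "negative"}


def _parse_label(token: str) -> int:
    t = token.strip().lower()
    if t in _TRUE_LABELS:
        return 1
    if t in _FALSE_LABELS:
        return 0
    raise ValueError(f"unrecognised class label {token!r}")


def read_smiles_file(
    path,
    label_column: Optional[str] = None,
    endpoint_name: Optional[str] = None,
) -> MoleculeTable:
    """Read a whitespace-delimited SMILES file.

    Each non-blank, non-``#`` line is ``SMILES [id] [label-or-value]``.
    ``label_column`` selects the role of the third column: ``"class"`` for
    binary labels (1/0, active/inactive), ``"value"`` for continuous
    endpoints, ``None`` to ignore it. Unparseable lines are skipped with a
    warning; the returned table carries the skip count as ``.skipped``.
    """
    if label_column not in (None, "class", "value"):
        raise ContractError(f"label_column must be None, 'class' or 'value', got {label_column!r}")
    records = MoleculeTable()
    skipped = 0
    seen_ids: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            smiles = tokens[0]
            try:
                mol_from_smiles(smiles)
                rec_id = tokens[1] if len(tokens) > 1 else f"mol{lineno}"
                label = value = None
                if label_column and len(tokens) > 2:
                    if label_column == "class":
                        label = _parse_label(tokens[2])
                    else:
                        value = float(tokens[2])
                if rec_id in seen_ids:
                    raise ValueError(f"duplicate id {rec_id!r}")
                seen_ids.add(rec_id)
            except (ParseError, ValueError) as exc:
                logger.warning("skipping line %d of %s: %s", lineno, path, exc)
                skipped += 1
                continue
            records.append(
                MoleculeRecord(
                    id=rec_id,
                    smiles=smiles,
                    label=label,
                    value=value,
                    endpoint_name=endpoint_name if label_column else None,
                )
            )
    if not records:
        raise DatasetError(f"no parseable molecules in {path} ({skipped} lines skipped)")
    records.skipped = skipped
    return records


def write_prediction_table(
    records: Sequence[MoleculeRecord],
    predictions: Sequence[dict],
    path,
) -> pd.DataFrame:
    """Write a CSV prediction table (id, smiles, one column per endpoint).

    ``predictions`` holds one dict per record mapping endpoint column name
    to value; missing endpoints are written as empty fields. The assembled
    frame is returned as well as written.
    """
    if len(records) != len(predictions):
        raise ContractError(
            f"{len(records)} records but {len(predictions)} prediction rows"
        )
    columns: list[str] = []
    for row in predictions:
        for key in row:
            if key not in columns:
                columns.append(key)
    data = {
        "id": [r.id for r in records],
        "smiles": [r.smiles for r in records],
    }
    for col in columns:
        data[col] = [row.get(col) for row in predictions]
    frame = pd.DataFrame(data)
    frame.to_csv(path, index=False)
    return frame
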