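"""Graph-based molecular signatures (cutoff scanning matrix) and descriptors.

A molecule's signature is the cumulative distribution of pharmacophore-
categorised atom-pair graph distances: for every unordered label pair (28
pairs over the 7-label vocabulary) and every distance cutoff (default 1..10
bond steps), the entry counts unordered heavy-atom pairs whose shortest-path
distance is at most the cutoff and which realise that label pair. The
signature is concatenated with a 10-descriptor physicochemical block.

Distances are bond-step BFS distances on the unweighted heavy-atom graph;
pairs in different components are unreachable and contribute to no bin.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, fields
from itertools import combinations_with_replacement
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .chem import (
    ContractError,
    DatasetError,
    MolecularGraph,
    MoleculeRecord,
    ParseError,
    graph_from_mol,
    prepare_mol,
)
from .pharmacophore import LABELS, PharmacophoreLabeling, TypingRule, assign_labels

logger = logging.getLogger("herbsig")

#: Sentinel for unreachable atom pairs in the distance matrix.
UNREACHABLE = -1

DEFAULT_CUTOFFS: tuple[int, ...] = tuple(range(1, 11))

#: Unordered label pairs in fixed vocabulary order: 7 + C(7,2) = 28.
LABEL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    combinations_with_replacement(LABELS, 2)
)
_PAIR_INDEX = {p: k for k, p in enumerate(LABEL_PAIRS)}
_LABEL_RANK = {label: k for k, label in enumerate(LABELS)}


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path lengths in bond steps; UNREACHABLE sentinel."""

    matrix: np.ndarray  # (n, n) int array

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def census(self) -> dict[int, int]:
        """Count unordered reachable pairs at each distance d >= 1."""
        out: dict[int, int] = {}
        n = self.n
        for i in range(n):
            for j in range(i + 1, n):
                d = int(self.matrix[i, j])
                if d != UNREACHABLE:
                    out[d] = out.get(d, 0) + 1
        return out


def all_pairs_distances(graph: MolecularGraph) -> DistanceMatrix:
    """BFS all-pairs shortest paths on the unweighted heavy-atom graph."""
    n = graph.n_atoms
    adj = graph.adjacency()
    dist = np.full((n, n), UNREACHABLE, dtype=np.int64)
    for src in range(n):
        dist[src, src] = 0
        queue = deque([src])
        while queue:
            u = queue.popleft()
            du = dist[src, u]
            for v in adj[u]:
                if dist[src, v] == UNREACHABLE:
                    dist[src, v] = du + 1
                    queue.append(v)
    return DistanceMatrix(dist)


@dataclass
class DescriptorBlock:
    """Complementary physicochemical descriptors (fixed 10-column block)."""

    molecular_weight: float  # Da
    logp: float
    h_bond_acceptors: int
    h_bond_donors: int
    rotatable_bonds: int
    rings: int
    aromatic_rings: int
    heavy_atoms: int
    tpsa: float  # topological polar surface area, A^2
    fraction_csp3: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


DESCRIPTOR_NAMES: tuple[str, ...] = tuple(f.name for f in fields(DescriptorBlock))


def compute_descriptors(graph: MolecularGraph) -> DescriptorBlock:
    """Physicochemical descriptor block via RDKit on the heavy-atom molecule."""
    mol = graph.rdkit_mol
    if mol is None:
        raise ContractError("graph does not carry an RDKit molecule")
    # renumber to canonical atom order first: descriptor sums are floating-
    # point and must not depend on the input rendering's atom order
    from rdkit import Chem

    ranks = list(Chem.CanonicalRankAtoms(mol, includeChirality=False))
    order = sorted(range(len(ranks)), key=ranks.__getitem__)
    mol = Chem.RenumberAtoms(mol, order)
    return DescriptorBlock(
        molecular_weight=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        h_bond_acceptors=Lipinski.NumHAcceptors(mol),
        h_bond_donors=Lipinski.NumHDonors(mol),
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
        rings=rdMolDescriptors.CalcNumRings(mol),
        aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        fraction_csp3=rdMolDescriptors.CalcFractionCSP3(mol),
    )


@dataclass
class SignatureVector:
    """Cumulative pair-label distance counts plus the descriptor block."""

    pair_block: np.ndarray  # (28, n_cutoffs), row = label pair, col = cutoff
    descriptor_block: Optional[DescriptorBlock]
    cutoffs: tuple[int, ...]

    def as_array(self) -> np.ndarray:
        flat = self.pair_block.reshape(-1).astype(float)
        if self.descriptor_block is None:
            return flat
        return np.concatenate([flat, self.descriptor_block.as_array()])


def signature_column_names(
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS, with_descriptors: bool = True
) -> list[str]:
    names = [f"{a}:{b}:d{c}" for (a, b) in LABEL_PAIRS for c in cutoffs]
    if with_descriptors:
        names.extend(DESCRIPTOR_NAMES)
    return names


def compute_signature(
    graph: MolecularGraph,
    labeling: PharmacophoreLabeling,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    normalise: bool = False,
) -> SignatureVector:
    """Cumulative pair-label distance counts (pair block only).

    Entry (pair (a, b), cutoff c) counts unordered atom pairs (i, j) with
    d(i, j) <= c realising the unordered label pair (a, b); a multi-label
    atom pair contributes once per distinct unordered label pair it
    realises. ``normalise`` divides counts by the heavy-atom count.
    """
    cutoffs = tuple(int(c) for c in cutoffs)
    if not cutoffs or any(c <= 0 for c in cutoffs) or list(cutoffs) != sorted(set(cutoffs)):
        raise ContractError("cutoffs must be strictly increasing positive integers")
    if labeling.n_atoms != graph.n_atoms:
        raise ContractError(
            f"labeling covers {labeling.n_atoms} atoms, graph has {graph.n_atoms}"
        )
    dmat = all_pairs_distances(graph).matrix
    max_cut = cutoffs[-1]
    # raw per-distance counts, then cumulate over the cutoff grid
    per_dist = np.zeros((len(LABEL_PAIRS), max_cut + 1), dtype=np.int64)
    n = graph.n_atoms
    for i in range(n):
        li = labeling[i]
        for j in range(i + 1, n):
            d = int(dmat[i, j])
            if d == UNREACHABLE or d > max_cut:
                continue
            pairs = {
                (a, b) if _LABEL_RANK[a] <= _LABEL_RANK[b] else (b, a)
                for a in li
                for b in labeling[j]
            }
            for p in pairs:
                per_dist[_PAIR_INDEX[p], d] += 1
    cum = np.cumsum(per_dist, axis=1)
    block = cum[:, list(cutoffs)].astype(float)
    if normalise and n > 0:
        block = block / n
    return SignatureVector(pair_block=block, descriptor_block=None, cutoffs=cutoffs)


# --- herbicide-likeness windows -------------------------------------------

@dataclass(frozen=True)
class LikenessBounds:
    """Property window enclosing a given fraction of active herbicides.

    ``*_strict`` flags record whether the bound is an open ("fewer than")
    or closed ("up to") comparison; the logP interval is closed.
    """

    tier: str
    mw_max: float
    mw_strict: bool
    acceptor_max: int
    donor_max: int
    rotatable_max: int
    rotatable_strict: bool
    logp_min: float
    logp_max: float


#: 90% of active herbicides: < 517 Da, <= 9 acceptors, <= 4 donors,
#: fewer than 9 rotatable bonds, logP in [-1.7, 6.1].
TIER_90 = LikenessBounds("90%", 517.0, True, 9, 4, 9, True, -1.7, 6.1)
#: 95% of active herbicides: < 700 Da, <= 11 acceptors, <= 6 donors,
#: <= 11 rotatable bonds, logP in [-3.0, 6.1].
TIER_95 = LikenessBounds("95%", 700.0, True, 11, 6, 11, False, -3.0, 6.1)

TIERS = (TIER_90, TIER_95)


def _violations(desc: DescriptorBlock, b: LikenessBounds) -> list[str]:
    out = []
    mw_ok = desc.molecular_weight < b.mw_max if b.mw_strict else desc.molecular_weight <= b.mw_max
    if not mw_ok:
        out.append(f"MW {desc.molecular_weight:.1f} not < {b.mw_max:g} Da")
    if desc.h_bond_acceptors > b.acceptor_max:
        out.append(f"{desc.h_bond_acceptors} acceptors > {b.acceptor_max}")
    if desc.h_bond_donors > b.donor_max:
        out.append(f"{desc.h_bond_donors} donors > {b.donor_max}")
    rot_ok = (
        desc.rotatable_bonds < b.rotatable_max
        if b.rotatable_strict
        else desc.rotatable_bonds <= b.rotatable_max
    )
    if not rot_ok:
        cmp = "<" if b.rotatable_strict else "<="
        out.append(f"{desc.rotatable_bonds} rotatable bonds not {cmp} {b.rotatable_max}")
    if not (b.logp_min <= desc.logp <= b.logp_max):
        out.append(f"logP {desc.logp:.2f} outside [{b.logp_min:g}, {b.logp_max:g}]")
    return out


def herbicide_likeness(desc: DescriptorBlock) -> dict[str, dict]:
    """Check a descriptor block against the 90% and 95% likeness windows.

    Returns, per tier, whether the molecule passes and the list of violated
    bounds (human-readable strings).
    """
    return {
        b.tier: {"passes": not (v := _violations(desc, b)), "violations": v}
        for b in TIERS
    }


# --- dataset featurization -------------------------------------------------

def featurize_graph(
    graph: MolecularGraph,
    rule_table: Optional[list[TypingRule]] = None,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    normalise: bool = False,
) -> np.ndarray:
    labeling = assign_labels(graph, rule_table)
    sig = compute_signature(graph, labeling, cutoffs, normalise=normalise)
    sig.descriptor_block = compute_descriptors(graph)
    return sig.as_array()


def featurize_smiles(
    smiles: str,
    rule_table: Optional[list[TypingRule]] = None,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    normalise: bool = False,
    strip_salts: bool = True,
) -> np.ndarray:
    graph = graph_from_mol(prepare_mol(smiles, strip_salts=strip_salts))
    return featurize_graph(graph, rule_table, cutoffs, normalise)


def featurize_dataset(
    records: Sequence[MoleculeRecord],
    rule_table: Optional[list[TypingRule]] = None,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    normalise: bool = False,
    strip_salts: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Featurize a dataset into a (records x features) frame.

    Row order follows the input; molecules that fail to parse are dropped
    with their ids logged and returned. An all-failed dataset is an error.
    """
    rows, index, failed = [], [], []
    for rec in records:
        try:
            rows.append(
                featurize_smiles(
                    rec.smiles, rule_table, cutoffs, normalise, strip_salts
                )
            )
            index.append(rec.id)
        except ParseError as exc:
            logger.warning("dropping molecule %s: %s", rec.id, exc)
            failed.append(rec.id)
    if not rows:
        raise DatasetError("no featurizable molecules in dataset")
    frame = pd.DataFrame(
        np.vstack(rows), index=index, columns=signature_column_names(cutoffs)
    )
    return frame, failed
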