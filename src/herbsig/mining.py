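"""Enriched-substructure mining between active and inactive compound classes.

Connected fragments (node-induced subgraphs of the heavy-atom graph) are
enumerated exhaustively up to a size limit, deduplicated by canonical form,
and scored by class support: the fraction of molecules in a class containing
at least one embedding. Fragments frequent in the active class and rare in
the inactive class are reported ranked by fold-change.

Presence is molecule-level (a molecule counts once no matter how many
embeddings) and matching respects element, aromatic flag and bond order;
formal charge is ignored by default. Embeddings are node-induced, matching
the enumeration semantics, which keeps support anti-monotone along the
fragment lattice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
from networkx.algorithms.isomorphism import GraphMatcher
from rdkit import Chem

from .chem import (
    ContractError,
    MolecularGraph,
    MoleculeRecord,
    parse_smiles,
)

logger = logging.getLogger("herbsig")

DEFAULT_MAX_ATOMS = 8

#: The four support regimes screened when contrasting classes, crossed with
#: a 5x or 10x fold-change requirement.
PRESETS: dict[str, dict[str, float]] = {
    "s1": {"min_support_pos": 0.01, "max_support_neg": 1.0},
    "s5": {"min_support_pos": 0.05, "max_support_neg": 1.0},
    "s1-10": {"min_support_pos": 0.01, "max_support_neg": 0.10},
    "s2-10": {"min_support_pos": 0.02, "max_support_neg": 0.10},
}

MoleculeLike = Union[str, MoleculeRecord, MolecularGraph]


def _as_graph(m: MoleculeLike) -> MolecularGraph:
    if isinstance(m, MolecularGraph):
        return m
    if isinstance(m, MoleculeRecord):
        return parse_smiles(m.smiles)
    return parse_smiles(m)


@dataclass
class EnrichedFragment:
    fragment: str  # canonical SMILES of the connected subgraph
    size: int  # atom count
    support_pos: float
    support_neg: float
    fold_change: float


# --- canonical fragment forms ---------------------------------------------

def _fragment_smiles(mol: Chem.Mol, atom_indices: Iterable[int]) -> str:
    """Canonical SMILES of the node-induced subgraph on ``atom_indices``.

    Rebuilt as a bare molecule (element, aromatic flag, bond order; charges
    dropped) so the same fragment gets the same string whatever molecule it
    was cut from. Partial aromatic systems are written with lowercase atoms
    without kekulisation.
    """
    def build(atom_info, bond_info):
        rw = Chem.RWMol()
        for num, aromatic, isotope in atom_info:
            na = Chem.Atom(num)
            na.SetIsAromatic(aromatic)
            na.SetNoImplicit(True)
            na.SetIsotope(isotope)
            rw.AddAtom(na)
        for i, j, btype in bond_info:
            rw.AddBond(i, j, btype)
        out = rw.GetMol()
        out.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(out)
        return out

    subset = sorted(atom_indices)
    remap = {i: k for k, i in enumerate(subset)}
    # isotope temporarily encodes the aromatic flag: RDKit's canonical
    # ranking ignores aromaticity itself, and without this a C-c pair can
    # canonicalize differently depending on the parent's atom order
    atoms = [
        (
            mol.GetAtomWithIdx(i).GetAtomicNum(),
            mol.GetAtomWithIdx(i).GetIsAromatic(),
            1 if mol.GetAtomWithIdx(i).GetIsAromatic() else 0,
        )
        for i in subset
    ]
    bonds = sorted(
        (
            min(remap[b.GetBeginAtomIdx()], remap[b.GetEndAtomIdx()]),
            max(remap[b.GetBeginAtomIdx()], remap[b.GetEndAtomIdx()]),
            b.GetBondType(),
        )
        for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in remap and b.GetEndAtomIdx() in remap
    )
    probe = build(atoms, bonds)
    ranks = list(Chem.CanonicalRankAtoms(probe, breakTies=True))
    order = sorted(range(len(ranks)), key=ranks.__getitem__)
    inv = {old: new for new, old in enumerate(order)}
    # rebuild in canonical order, isotopes cleared, and let the final
    # canonical writer see a parent-independent molecule
    atoms2 = [(atoms[o][0], atoms[o][1], 0) for o in order]
    bonds2 = sorted((min(inv[i], inv[j]), max(inv[i], inv[j]), t) for i, j, t in bonds)
    return Chem.MolToSmiles(build(atoms2, bonds2))


def _connected_subsets(adj: list[list[int]], max_size: int):
    """Enumerate every connected vertex subset of size <= max_size once (ESU)."""
    n = len(adj)
    neigh = [set(a) for a in adj]

    def extend(sub: list[int], ext: set[int], root: int):
        yield frozenset(sub)
        if len(sub) == max_size:
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            sub_neigh = set().union(*(neigh[u] for u in sub))
            new_ext = ext | {
                u for u in neigh[w] if u > root and u not in sub and u not in sub_neigh
            }
            yield from extend(sub + [w], new_ext, root)

    for v in range(n):
        yield from extend([v], {u for u in neigh[v] if u > v}, v)


def enumerate_fragments(
    graph: MolecularGraph, max_atoms: int = DEFAULT_MAX_ATOMS
) -> dict[str, int]:
    """All connected induced subgraphs up to ``max_atoms`` atoms.

    Returns canonical fragment SMILES mapped to atom count; each fragment
    appears once per molecule however many embeddings it has.
    """
    if max_atoms < 1:
        raise ContractError("max_atoms must be >= 1")
    mol = graph.rdkit_mol
    out: dict[str, int] = {}
    for subset in _connected_subsets(graph.adjacency(), max_atoms):
        smi = _fragment_smiles(mol, subset)
        if smi not in out:
            out[smi] = len(subset)
    return out


# --- embedding search (independent matching route) -------------------------

def _bond_order_key(bond: Chem.Bond) -> float:
    t = bond.GetBondType()
    if t == Chem.BondType.AROMATIC:
        return 1.5
    return {Chem.BondType.SINGLE: 1.0, Chem.BondType.DOUBLE: 2.0,
            Chem.BondType.TRIPLE: 3.0}.get(t, 1.0)


def _mol_to_nx(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for a in mol.GetAtoms():
        g.add_node(a.GetIdx(), element=a.GetAtomicNum(), aromatic=a.GetIsAromatic())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order=_bond_order_key(b))
    return g


def _parse_fragment(fragment: str) -> Chem.Mol:
    """Parse a fragment SMILES, tolerating partial aromatic systems."""
    mol = Chem.MolFromSmiles(fragment)
    if mol is None:
        mol = Chem.MolFromSmiles(fragment, sanitize=False)
        if mol is None:
            raise ContractError(f"cannot parse fragment {fragment!r}")
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
    return mol


def _node_match(a: dict, b: dict) -> bool:
    return a["element"] == b["element"] and a["aromatic"] == b["aromatic"]


def _edge_match(a: dict, b: dict) -> bool:
    return a["order"] == b["order"]


def contains_fragment(molecule: MoleculeLike, fragment: str) -> bool:
    """True iff the molecule has a node-induced embedding of the fragment."""
    target = _mol_to_nx(_as_graph(molecule).rdkit_mol)
    query = _mol_to_nx(_parse_fragment(fragment))
    return _has_embedding(target, query)


def _has_embedding(target: nx.Graph, query: nx.Graph) -> bool:
    gm = GraphMatcher(target, query, node_match=_node_match, edge_match=_edge_match)
    return gm.subgraph_is_isomorphic()


def support(fragment: str, dataset: Sequence[MoleculeLike]) -> float:
    """Fraction of molecules containing >= 1 embedding of ``fragment``.

    Uses a VF2 subgraph-isomorphism search, independent of the enumeration
    used by :func:`mine_enriched`.
    """
    if len(dataset) == 0:
        raise ContractError("support over an empty dataset is undefined")
    query = _mol_to_nx(_parse_fragment(fragment))
    hits = sum(
        1 for m in dataset if _has_embedding(_mol_to_nx(_as_graph(m).rdkit_mol), query)
    )
    return hits / len(dataset)


# --- enrichment mining ----------------------------------------------------

def _class_supports(
    molecules: Sequence[MoleculeLike], max_atoms: int
) -> tuple[dict[str, int], dict[str, int], int]:
    counts: dict[str, int] = {}
    sizes: dict[str, int] = {}
    for m in molecules:
        frags = enumerate_fragments(_as_graph(m), max_atoms)
        for smi, size in frags.items():
            counts[smi] = counts.get(smi, 0) + 1
            sizes.setdefault(smi, size)
    return counts, sizes, len(molecules)


def _fragment_contained_in(inner: str, outer: str) -> bool:
    gi = _mol_to_nx(_parse_fragment(inner))
    go = _mol_to_nx(_parse_fragment(outer))
    return _has_embedding(go, gi)


def mine_enriched(
    pos: Sequence[MoleculeLike],
    neg: Sequence[MoleculeLike],
    min_support_pos: float = 0.05,
    max_support_neg: float = 0.10,
    min_fold: float = 10.0,
    max_atoms: int = DEFAULT_MAX_ATOMS,
    maximal_only: bool = True,
    epsilon: Optional[float] = None,
) -> list[EnrichedFragment]:
    """Fragments enriched in ``pos`` and depleted in ``neg``.

    Keeps fragments with support_pos >= min_support_pos, support_neg <=
    max_support_neg and fold_change >= min_fold, where fold_change =
    support_pos / max(support_neg, epsilon) and epsilon defaults to
    1/(2*|neg|). Ranked by fold-change, then positive support, then size
    (larger, more specific fragments first). ``maximal_only`` collapses a
    fragment into any equally-supported superfragment that contains it.
    An empty result is a valid outcome.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ContractError("both classes must be non-empty")
    if not 0 < min_support_pos <= 1:
        raise ContractError("min_support_pos must be in (0, 1]")
    if min_fold < 1:
        raise ContractError("min_fold must be >= 1")
    eps = epsilon if epsilon is not None else 1.0 / (2 * len(neg))
    pos_counts, sizes, n_pos = _class_supports(pos, max_atoms)
    neg_counts, neg_sizes, n_neg = _class_supports(neg, max_atoms)
    sizes.update(neg_sizes)
    hits: list[EnrichedFragment] = []
    for smi, c in pos_counts.items():
        sp = c / n_pos
        sn = neg_counts.get(smi, 0) / n_neg
        if sp < min_support_pos or sn > max_support_neg:
            continue
        fold = sp / max(sn, eps)
        if fold < min_fold:
            continue
        hits.append(EnrichedFragment(smi, sizes[smi], sp, sn, fold))
    if maximal_only and hits:
        by_support: dict[tuple[float, float], list[EnrichedFragment]] = {}
        for h in hits:
            by_support.setdefault((h.support_pos, h.support_neg), []).append(h)
        keep: list[EnrichedFragment] = []
        for group in by_support.values():
            group.sort(key=lambda h: -h.size)
            maximal: list[EnrichedFragment] = []
            for h in group:
                if any(
                    g.size > h.size and _fragment_contained_in(h.fragment, g.fragment)
                    for g in maximal
                ):
                    continue
                maximal.append(h)
            keep.extend(maximal)
        hits = keep
    hits.sort(
        key=lambda h: (-h.fold_change, -h.support_pos, -h.size, h.fragment)
    )
    return hits
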