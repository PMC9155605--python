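"""Pharmacophore atom typing.

Each heavy atom is assigned a subset of a fixed, ordered 7-label vocabulary
(hydrophobic, aromatic, H-bond donor/acceptor, positively/negatively
ionizable, neutral) describing its physicochemical role. The label pairs
categorise atom-pair distances in the signature engine, so the vocabulary
order is part of the feature-vector layout and must stay fixed.

Typing rules are SMARTS patterns read from a plain-text table; the shipped
default table encodes standard pharmacophore families and is fully
replaceable by the user (the exact published definitions are not public, so
the default is a documented stand-in).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Optional

from rdkit import Chem

from .chem import ContractError, MolecularGraph

#: Fixed, ordered label vocabulary. Downstream feature layout depends on it.
LABELS = (
    "Hydrophobic",
    "Aromatic",
    "Donor",
    "Acceptor",
    "PosIonizable",
    "NegIonizable",
    "Neutral",
)

NEUTRAL = "Neutral"


class ConfigurationError(ValueError):
    """Invalid typing rule table."""


class TypingRule(NamedTuple):
    smarts: str
    pattern: Chem.Mol
    label: str


@dataclass
class PharmacophoreLabeling:
    """Per-atom pharmacophore label sets for one molecule."""

    labels: dict[int, frozenset[str]]

    def __getitem__(self, atom_index: int) -> frozenset[str]:
        return self.labels[atom_index]

    @property
    def n_atoms(self) -> int:
        return len(self.labels)


def parse_rule_table(text: str) -> list[TypingRule]:
    """Parse a rule table: one ``SMARTS  Label`` pair per non-comment line."""
    rules = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ConfigurationError(
                f"line {lineno}: expected 'SMARTS LABEL', got {line!r}"
            )
        smarts, label = parts
        if label not in LABELS or label == NEUTRAL:
            raise ConfigurationError(
                f"line {lineno}: unknown label {label!r} "
                f"(must be one of {', '.join(l for l in LABELS if l != NEUTRAL)})"
            )
        pattern = Chem.MolFromSmarts(smarts)
        if pattern is None:
            raise ConfigurationError(f"line {lineno}: invalid SMARTS {smarts!r}")
        rules.append(TypingRule(smarts, pattern, label))
    if not rules:
        raise ConfigurationError("rule table contains no rules")
    return rules


def load_rule_table(path) -> list[TypingRule]:
    with open(path, "rt", encoding="utf-8") as fh:
        return parse_rule_table(fh.read())


def default_rule_table() -> list[TypingRule]:
    """The rule table shipped with the package."""
    text = (
        resources.files("herbsig").joinpath("data/pharmacophore_rules.txt").read_text()
    )
    return parse_rule_table(text)


def assign_labels(
    graph: MolecularGraph, rule_table: Optional[list[TypingRule]] = None
) -> PharmacophoreLabeling:
    """Label every atom of ``graph``; unmatched atoms become Neutral.

    A rule labels the first atom of each SMARTS match; an atom's label set
    is the union over all matching rules, so rule order is irrelevant.
    """
    if rule_table is None:
        rule_table = default_rule_table()
    mol = graph.rdkit_mol
    if mol is None or mol.GetNumAtoms() != graph.n_atoms:
        raise ContractError("graph does not carry a matching RDKit molecule")
    sets: dict[int, set[str]] = {a.index: set() for a in graph.atoms}
    for rule in rule_table:
        for match in mol.GetSubstructMatches(rule.pattern, uniquify=True):
            sets[match[0]].add(rule.label)
    return PharmacophoreLabeling(
        labels={
            i: frozenset(s) if s else frozenset({NEUTRAL}) for i, s in sets.items()
        }
    )
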