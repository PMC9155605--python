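"""Synthetic structure–activity datasets with planted, known ground truth.

Molecules are assembled from a small scaffold/decorator grammar (rings and
chains decorated with halogens, alkyl and polar groups), which guarantees
chemically well-formed SMILES and makes planted substructures exact. Labels
come from a planted rule — presence of a specific fragment, a descriptor
window, or both — optionally corrupted by label-flip noise, emulating the
statistical shape of herbicidal screening sets (binary labels at roughly
22% prevalence) and of continuous toxicity endpoints (LC50/LD50-style
values as a linear function of true descriptors plus Gaussian noise).

These sets exercise every pipeline stage without external data; they do not
attempt to mimic the chemical space of any real screening library.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord, MoleculeTable, parse_smiles
from .mining import contains_fragment
from .pharmacophore import ConfigurationError
from .signatures import compute_descriptors

logger = logging.getLogger("herbsig")

#: Positive prevalence of the emulated herbicidal screening sets.
DEFAULT_PREVALENCE = 0.22
#: Default planted substructure: a chlorinated benzene ring (chlorine on
#: aromatic carbon is a recurring motif of active herbicides).
DEFAULT_FRAGMENT = "Clc1ccccc1"


def _load_grammar() -> dict:
    text = resources.files("herbsig").joinpath("data/grammar.json").read_text()
    return json.loads(text)


@dataclass
class PlantedRule:
    """Ground-truth labelling rule for a synthetic binary SAR set."""

    mode: str = "fragment"  # "fragment" | "descriptor" | "mixed"
    active_fragment: str = DEFAULT_FRAGMENT
    descriptor_window: Optional[dict] = None  # {"molecular_weight": [lo, hi], ...}
    prevalence: float = DEFAULT_PREVALENCE
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("fragment", "descriptor", "mixed"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not 0 < self.prevalence < 1:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ConfigurationError("label_noise must be in [0, 0.5)")

    def to_config(self) -> str:
        return "\n".join(f"{k} = {json.dumps(v)}" for k, v in asdict(self).items())

    @classmethod
    def from_config(cls, text: str) -> "PlantedRule":
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = json.loads(value.strip())
        return cls(**kwargs)


class MoleculeAssembler:
    """Random scaffold + decorator assembly, deterministic under its rng."""

    def __init__(self, rng: np.random.Generator, grammar: Optional[dict] = None):
        self.rng = rng
        g = grammar or _load_grammar()
        self.scaffolds = [Chem.MolFromSmiles(s) for s in g["scaffolds"]]
        self.decorators = list(g["decorators"])
        if any(m is None for m in self.scaffolds):
            raise ConfigurationError("grammar scaffold does not parse")

    def _free_sites(self, mol: Chem.Mol) -> list[int]:
        return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]

    def _attach(self, mol: Chem.Mol, decorator: str) -> Optional[Chem.Mol]:
        sites = self._free_sites(mol)
        if not sites:
            return None
        site = int(self.rng.choice(sites))
        dec = Chem.MolFromSmiles(decorator)
        if dec is None:
            raise ConfigurationError(f"decorator {decorator!r} does not parse")
        combo = Chem.RWMol(Chem.CombineMols(mol, dec))
        combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        out = combo.GetMol()
        try:
            Chem.SanitizeMol(out)
        except Exception:
            return None
        return out

    def assemble(
        self,
        force_scaffold: Optional[str] = None,
        force_decorators: tuple[str, ...] = (),
        n_extra: Optional[int] = None,
    ) -> str:
        """One random molecule; forced pieces are applied before random ones."""
        if force_scaffold is not None:
            mol = Chem.MolFromSmiles(force_scaffold)
        else:
            mol = self.scaffolds[int(self.rng.integers(len(self.scaffolds)))]
        mol = Chem.Mol(mol)
        for dec in force_decorators:
            nxt = self._attach(mol, dec)
            if nxt is None:
                raise ConfigurationError(f"cannot attach forced decorator {dec!r}")
            mol = nxt
        k = int(self.rng.integers(0, 4)) if n_extra is None else n_extra
        for _ in range(k):
            dec = self.decorators[int(self.rng.integers(len(self.decorators)))]
            nxt = self._attach(mol, dec)
            if nxt is not None:
                mol = nxt
        return Chem.MolToSmiles(mol)


def _window_ok(smiles: str, window: Optional[dict]) -> bool:
    if not window:
        return True
    desc = compute_descriptors(parse_smiles(smiles))
    for key, (lo, hi) in window.items():
        v = getattr(desc, key)
        if not (lo <= v <= hi):
            return False
    return True


def generate_dataset(n: int, rule: PlantedRule) -> MoleculeTable:
    """Generate ``n`` labelled molecules under a planted rule.

    Fragment and mixed modes plant the active fragment in the positive
    class by construction (a chlorinated-benzene positive is built on a
    benzene scaffold with a forced chlorine) and rejection-sample negatives
    until they lack it, so at zero label noise every positive contains the
    fragment and no negative does. Descriptor mode labels by the window, or
    by the upper molecular-weight quantile matching the target prevalence
    when no window is given. Labels are then flipped with probability
    ``label_noise``. Deterministic under ``rule.seed``.
    """
    if n < 20:
        raise ConfigurationError("n must be >= 20")
    rng = np.random.default_rng(rule.seed)
    asm = MoleculeAssembler(rng)
    if rule.mode in ("fragment", "mixed"):
        frag_mol = Chem.MolFromSmiles(rule.active_fragment)
        if frag_mol is None:
            raise ConfigurationError(
                f"active fragment {rule.active_fragment!r} does not parse"
            )
        # fragment must be constructible: benzene scaffold + chlorine covers
        # the default; other fragments must appear within grammar reach
        probe = asm.assemble(force_scaffold="c1ccccc1", force_decorators=("Cl",), n_extra=0)
        if rule.active_fragment != DEFAULT_FRAGMENT and not any(
            contains_fragment(asm.assemble(), rule.active_fragment) for _ in range(200)
        ):
            raise ConfigurationError(
                f"fragment {rule.active_fragment!r} not reachable from the grammar"
            )
        del probe
    records = MoleculeTable()
    smiles_list: list[str] = []
    truth: list[int] = []
    for i in range(n):
        want_positive = bool(rng.random() < rule.prevalence)
        if rule.mode in ("fragment", "mixed"):
            smi = _sample_fragment_conditioned(asm, rule, want_positive)
            label = want_positive
            if rule.mode == "mixed":
                label = want_positive and _window_ok(smi, rule.descriptor_window)
        else:
            smi = asm.assemble()
            label = None  # assigned below
        smiles_list.append(smi)
        truth.append(label)
    if rule.mode == "descriptor":
        mws = np.array(
            [compute_descriptors(parse_smiles(s)).molecular_weight for s in smiles_list]
        )
        if rule.descriptor_window:
            truth = [_window_ok(s, rule.descriptor_window) for s in smiles_list]
        else:
            cut = np.quantile(mws, 1 - rule.prevalence)
            truth = [bool(m > cut) for m in mws]
    for i, (smi, t) in enumerate(zip(smiles_list, truth)):
        label = int(t)
        if rule.label_noise > 0 and rng.random() < rule.label_noise:
            label = 1 - label
        records.append(MoleculeRecord(id=f"m{i:04d}", smiles=smi, label=label))
    return records


def _sample_fragment_conditioned(
    asm: MoleculeAssembler, rule: PlantedRule, positive: bool
) -> str:
    for _ in range(200):
        if positive:
            smi = asm.assemble(force_scaffold="c1ccccc1", force_decorators=("Cl",))
            if contains_fragment(smi, rule.active_fragment):
                return smi
        else:
            smi = asm.assemble()
            if not contains_fragment(smi, rule.active_fragment):
                return smi
    raise ConfigurationError(
        f"could not sample a {'positive' if positive else 'negative'} molecule "
        f"for fragment {rule.active_fragment!r}"
    )


DEFAULT_COEFFICIENTS = {"logp": 0.8, "molecular_weight": 0.01, "h_bond_donors": -0.4}


def generate_regression_dataset(
    n: int,
    coefficients: Optional[dict] = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    intercept: float = 1.0,
    endpoint_name: str = "synthetic_lc50",
) -> MoleculeTable:
    """Continuous-endpoint records: a linear function of true descriptors.

    value = intercept + sum(coef * descriptor) + N(0, noise_sd), emulating
    log-scale LC50/LD50-style endpoints. Deterministic under ``seed``.
    """
    if n < 20:
        raise ConfigurationError("n must be >= 20")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    coefficients = coefficients if coefficients is not None else DEFAULT_COEFFICIENTS
    rng = np.random.default_rng(seed)
    asm = MoleculeAssembler(rng)
    records = MoleculeTable()
    for i in range(n):
        smi = asm.assemble()
        desc = compute_descriptors(parse_smiles(smi))
        value = intercept + sum(
            coef * getattr(desc, key) for key, coef in coefficients.items()
        )
        value += float(rng.normal(0, noise_sd)) if noise_sd > 0 else 0.0
        records.append(
            MoleculeRecord(
                id=f"m{i:04d}", smiles=smi, value=value, endpoint_name=endpoint_name
            )
        )
    return records


def write_smiles_file(records, path, rule: Optional[PlantedRule] = None) -> None:
    """Write records as a whitespace-delimited SMILES file.

    The planted rule, when given, is serialised next to the file as
    ``<path>.rule.txt`` so ground truth travels with the data.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for rec in records:
            extra = ""
            if rec.label is not None:
                extra = f" {rec.label}"
            elif rec.value is not None:
                extra = f" {rec.value:.6g}"
            fh.write(f"{rec.smiles} {rec.id}{extra}\n")
    if rule is not None:
        with open(f"{path}.rule.txt", "wt", encoding="utf-8") as fh:
            fh.write(rule.to_config() + "\n")
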