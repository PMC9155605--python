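"""Shared fixtures: synthetic datasets and their featurizations.

The planted-rule dataset (n=500, 22% target prevalence, no label noise,
fixed seed) is built once per session and shared by the model-recovery and
mining-recovery tests.
"""

import numpy as np
import pytest

import herbsig as hs
from herbsig.synthetic import MoleculeAssembler

RULE_SEED = 7
N_MOLECULES = 500


@pytest.fixture(scope="session")
def planted_rule():
    return hs.PlantedRule(mode="fragment", prevalence=0.22, label_noise=0.0, seed=RULE_SEED)


@pytest.fixture(scope="session")
def sar_dataset(planted_rule):
    return hs.generate_dataset(N_MOLECULES, planted_rule)


@pytest.fixture(scope="session")
def sar_features(sar_dataset):
    X, failed = hs.featurize_dataset(sar_dataset)
    assert not failed
    y = np.array([r.label for r in sar_dataset])
    return X, y


@pytest.fixture(scope="session")
def sar_cv_report(sar_features):
    X, y = sar_features
    spec = hs.ModelSpec(task="classification", seed=1)
    return hs.cross_validate(X, y, spec, k=10, seed=1)


@pytest.fixture(scope="session")
def mining_hits(sar_dataset):
    pos = [r for r in sar_dataset if r.label == 1]
    neg = [r for r in sar_dataset if r.label == 0]
    return hs.mine_enriched(
        pos, neg, min_support_pos=0.05, max_support_neg=0.10, min_fold=10.0
    )


@pytest.fixture(scope="session")
def random_smiles():
    """200 random grammar molecules (deterministic)."""
    asm = MoleculeAssembler(np.random.default_rng(123))
    return [asm.assemble() for _ in range(200)]


@pytest.fixture(scope="session")
def small_graphs(random_smiles):
    """Heavy-atom graphs of the random molecules with <= 12 atoms."""
    graphs = [hs.parse_smiles(s) for s in random_smiles]
    return [g for g in graphs if g.n_atoms <= 12]
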