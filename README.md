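# herbsig

Graph-based molecular signatures for herbicide discovery: featurization,
herbicide-likeness profiling, QSAR modelling of herbicidal activity and
toxicity endpoints, and enriched-substructure mining.

## The problem

Designing new herbicides means balancing potency against environmental and
human safety, and very little computational tooling exists for that
trade-off compared with pharmaceutical pipelines. `herbsig` is a toolkit
for researchers building structure–activity models from screening data:
given molecules as SMILES with binary activity labels (active/inactive) or
continuous endpoints (LC50/LD50-style values), it turns each molecule into
a fixed-length signature, trains and validates predictive models, profiles
whether candidates sit inside the property windows that enclose most known
active herbicides, and mines the substructures that distinguish actives
from inactives.

## The signature

A molecule is modelled as an unweighted, undirected heavy-atom graph
(nodes = atoms, edges = covalent bonds, hydrogens collapsed onto their
heavy atoms). Each atom receives a set of pharmacophore labels from a
fixed 7-label vocabulary — Hydrophobic, Aromatic, Donor, Acceptor,
PosIonizable, NegIonizable, Neutral — via a configurable SMARTS rule
table. All-pairs shortest-path distances d(i, j) in bond steps are
computed by BFS, and the signature entry for label pair (a, b) at cutoff c
counts the unordered atom pairs with d(i, j) ≤ c realising that label
pair:

    sig[(a,b), c] = |{ {i,j} : d(i,j) ≤ c, (a,b) ∈ labels(i) × labels(j) }|

Rows are cumulative distance distributions, non-decreasing in c. With the
default cutoff grid 1..10 this gives 28 × 10 = 280 counts, concatenated
with a 10-descriptor physicochemical block (MW, logP, H-bond acceptors and
donors, rotatable bonds, rings, aromatic rings, heavy atoms, TPSA,
fraction C sp³) for a 290-long feature vector.

On top of the signatures the toolkit provides:

- **Models** — random forests (300 trees by default) and other
  scikit-learn algorithms, evaluated by stratified 10-fold cross-validation
  with pooled out-of-fold metrics (accuracy, MCC, ROC-AUC, PR-AUC,
  sensitivity, specificity; Pearson r, RMSE and a 10 %-trimmed r for
  regression), random 10 % blind splits, greedy forward feature selection,
  and Fisher r-to-z comparison of correlations.
- **Herbicide-likeness windows** — two property windows enclosing 90 %
  (MW < 517 Da, ≤ 9 acceptors, ≤ 4 donors, < 9 rotatable bonds, logP in
  [−1.7, 6.1]) and 95 % (MW < 700 Da, ≤ 11 acceptors, ≤ 6 donors, ≤ 11
  rotatable bonds, logP in [−3.0, 6.1]) of known active herbicides.
- **Substructure mining** — exhaustive enumeration of connected fragments
  up to 8 atoms, scored by per-class support (fraction of molecules
  containing the fragment) and ranked by fold-change between classes.
- **Synthetic SAR data** — a grammar-based generator that plants a known
  fragment or descriptor rule at a target prevalence, so every pipeline
  stage can be verified against ground truth.

## Worked example

```python
import herbsig as hs

for name, smi in [("atrazine", "CCNc1nc(Cl)nc(NC(C)C)n1"),
                  ("glyphosate", "C(C(=O)O)NCP(=O)(O)O"),
                  ("oleic acid", "CCCCCCCC/C=C\\CCCCCCCC(=O)O")]:
    desc = hs.compute_descriptors(hs.parse_smiles(smi))
    like = hs.herbicide_likeness(desc)
    print(name, f"MW={desc.molecular_weight:.1f} logP={desc.logp:.2f}",
          "90%:", "pass" if like["90%"]["passes"] else like["90%"]["violations"])
```

prints

```
atrazine MW=215.7 logP=1.78 90%: pass
glyphosate MW=169.1 logP=-1.20 90%: pass
oleic acid MW=282.5 logP=6.11 90%: ['15 rotatable bonds not < 9; logP 6.11 outside [-1.7, 6.1]']
```

— the two commercial herbicides sit inside the 90 % likeness window, while
the natural fatty acid violates the rotatable-bond and logP bounds of both
tiers. `hs.featurize_smiles("CCNc1nc(Cl)nc(NC(C)C)n1")` returns the full
290-long signature + descriptor vector used by the models.

The same workflow is available from the shell:

```bash
herbsig --seed 7 simulate -n 500 -o sar.smi        # planted-rule dataset
herbsig crossval sar.smi -k 10                     # pooled 10-fold CV report
herbsig train sar.smi -o herb.joblib               # persist a 300-tree forest
herbsig predict --smiles "Clc1ccccc1CC" --models herbicide=herb.joblib -o pred.csv
herbsig profile sar.smi -o likeness.csv
herbsig mine pos.smi neg.smi --preset s2-10 --fold 10 -o fragments.csv
```

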