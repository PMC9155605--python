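# Methods

## Molecular graphs

Molecules are heavy-atom graphs: nodes carry element, formal charge,
attached-hydrogen count and an aromaticity flag; edges carry bond order
(aromatic bonds as a distinct order). Hydrogens are never nodes — the
signature is computed over heavy atoms, which makes it stable to how
hydrogens are rendered, and the H counts that matter (donor typing, donor
counts) live on the heavy atoms. Atom indices are 0-based and contiguous.
SMILES parsing, sanitisation and canonicalization are delegated to RDKit;
a lightweight pre-scan reports the offending token position for the common
syntax errors (unclosed rings, branches, brackets) before RDKit sees the
string.

Multi-component inputs (salts, mixtures) are reduced to their largest
component by heavy-atom count before featurization, with a logged notice.
This removes unreachable atom pairs from the distance matrix, which would
otherwise fall outside every cutoff bin and make the signature depend on
counter-ion bookkeeping. Stereochemistry is parsed but ignored by all
downstream operations: the signature is a topological object. Molecules
above 2000 Da — the stated applicability bound of the approach — trigger a
warning, never an error.

## Pharmacophore typing

Atoms are labelled from the ordered vocabulary (Hydrophobic, Aromatic,
Donor, Acceptor, PosIonizable, NegIonizable, Neutral). The vocabulary
order is fixed because it defines the feature-vector layout. Rules are
SMARTS patterns in a plain-text table; a rule labels the first atom of
each match, and an atom's label set is the union over all matching rules,
so rule order is irrelevant by construction and no tie-breaking is needed.
Neutral is never assignable by rule: it is the fallback for atoms no rule
matches, so every atom carries at least one label.

The shipped default table encodes the standard pharmacophore families:
aromatic-perceived atoms; N/O bearing hydrogens as donors; N/O with a lone
pair and non-positive formal charge as acceptors (pyrrole-type aromatic NH
excluded — its lone pair is part of the ring system); uncharged C/S/halogen
not bonded to a charged atom as hydrophobic; formal positive charge or
aliphatic amines as positively ionizable; formal negative charge or
carboxylic/sulfonic/phosphonic acid OH as negatively ionizable. The exact
published label definitions behind signature-based ADMET tools are not
public, so this table is a documented, fully replaceable stand-in — the
engine treats it as configuration, not as chemistry baked into code.

## Signatures

All-pairs shortest-path distances are computed by per-source BFS on the
unweighted graph (verified in the tests against a dense Floyd–Warshall
oracle); unreachable pairs hold an explicit sentinel and contribute to no
bin. For each unordered label pair (28 over 7 labels) and each cutoff in
the grid (default 1..10 bond steps), the signature counts unordered atom
pairs at distance ≤ cutoff realising that label pair. A multi-label atom
pair contributes once per distinct unordered label pair it realises —
(a, b) and (b, a) are the same pair and are never double-counted. Rows are
cumulative, hence non-decreasing in the cutoff, which is asserted for
every featurized molecule.

The cutoff grid defaults to 1..10 because 10 bond steps covers the
diameter of most molecules under ~500 Da; it is configurable. Counts are
raw, not divided by atom count: molecular size is itself predictive of
herbicidal activity (see the likeness windows), and normalising it away
discards that signal. A `normalise` switch divides by heavy-atom count for
users who want size-free signatures.

The descriptor block is computed by RDKit (MolWt, Crippen logP, Lipinski
H-bond acceptor/donor counts, rotatable bonds, ring and aromatic-ring
counts, heavy atoms, TPSA, fraction C sp³). Ten descriptors is a choice,
not a published list: it covers every property the likeness analysis uses
plus the standard size/polarity/flexibility axes. Descriptors are computed
after renumbering atoms into canonical order, because RDKit's descriptor
sums are floating-point reductions over atoms and would otherwise differ
in the last bits between renderings of the same molecule; with the
renumbering, featurization is bit-identical across SMILES renderings,
which the tests assert exactly.

## Herbicide-likeness windows

Two tiers of property bounds enclose 90 % and 95 % of known active
herbicides: 90 % — MW < 517 Da, acceptors ≤ 9, donors ≤ 4, rotatable
bonds < 9, logP ∈ [−1.7, 6.1]; 95 % — MW < 700 Da, acceptors ≤ 11,
donors ≤ 6, rotatable bonds ≤ 11, logP ∈ [−3.0, 6.1]. Boundary semantics
are read literally from how the windows are stated: "< 517 Da" and "fewer
than 9 rotatable bonds" are strict, "up to 9 acceptors" is inclusive, and
the logP interval is closed. The 95 % tier's counts are stated
elliptically in the source analysis; they are taken as inclusive bounds
(≤ 11 rotatable bonds), the reading under which the tier is uniformly at
least as permissive as the 90 % tier — an invariant the code asserts. The
profiler reports pass/fail per tier plus the violated bounds.

## Models and validation

The model layer wraps scikit-learn estimators behind a serialisable
`ModelSpec`; the default is a random forest with 300 trees, the
configuration found to perform best for herbicidal activity. The headline
evaluation protocol is stratified 10-fold cross-validation with **pooled**
out-of-fold metrics: every sample is predicted exactly once by a model
that never saw it, and each metric is computed once on the pooled
prediction vector (per-fold values are reported alongside). Pooling rather
than averaging folds is a choice — it matches the convention of reporting
a single accuracy/AUC/MCC triple per dataset and behaves better when folds
contain few positives. Blind tests hold out a simple random 10 % (a
stratified variant is available). Threshold metrics use 0.5 by default,
configurable; MCC, accuracy, sensitivity and specificity are computed
directly from the confusion matrix (tested against scikit-learn and
against an exhaustive concordant-pair AUC oracle).

Greedy forward selection starts from the empty set and adds, at each
step, the feature maximising the cross-validated pooled metric (ROC-AUC
for classification, Pearson r for regression), breaking ties toward the
lower column index, and stops when the best improvement does not exceed
the tolerance. When enabled inside cross-validation it runs within each
training fold, never on the fold being predicted, so selection cannot leak
test information into the reported metrics.

Regression reports Pearson r and RMSE on all points plus a trimmed r
computed after removing the `round(0.10·n)` largest absolute residuals.
The trim is a reporting device to assess outlier influence — the model and
its predictions are untouched. Correlations are compared with the Fisher
r-to-z transform, z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), with a
two-sided normal p-value.

Endpoints are modelled on the scale the user supplies; a log10
pre-transform is left to the caller since the appropriate scale for
LC50/LD50-type values is dataset-specific. Hyperparameter grid search is
available but off by default — tuning the forest rarely improves these
models. Models persist via joblib with an adjacent plain-text spec
(algorithm, hyperparameters, seed, feature configuration, training-data
checksum) so a saved model is auditable without unpickling it.

## Substructure mining

The miner exhaustively enumerates connected node-induced subgraphs up to
`max_atoms` atoms (default 8) per molecule using the ESU scheme, which
visits each connected vertex subset exactly once, and deduplicates by
canonical fragment SMILES. Support is molecule-level presence — a molecule
counts once however many embeddings it has — and matching respects
element, aromaticity and bond order but ignores formal charge by default.
Embeddings are node-induced, consistent with the enumeration, which keeps
support anti-monotone along the fragment lattice (a fragment is never
rarer than any of its extensions); the tests verify both the
anti-monotonicity and the agreement of enumeration-derived supports with
an independent VF2 subgraph-isomorphism search.

Fragment canonicalization has one subtlety: RDKit's canonical atom
ranking does not consider aromaticity flags, so a fragment like
aliphatic-C–aromatic-c could canonicalize to different strings depending
on which parent molecule it was cut from. Fragments are therefore ranked
with the aromatic flag temporarily encoded as an atom isotope, rebuilt in
that canonical order, and only then written as SMILES — making the
canonical form a pure function of the fragment graph. Partial aromatic
systems (e.g. a 3-atom path cut from benzene) are written in lowercase
without kekulisation, the usual convention of substructure miners.

Enrichment keeps fragments with support_pos ≥ min_support_pos,
support_neg ≤ max_support_neg and fold_change ≥ min_fold, where
fold_change = support_pos / max(support_neg, ε) and ε = 1/(2·|neg|)
handles zero negative support (configurable). Results are ranked by
fold-change, then positive support, then size — larger first, since among
equally supported fragments the larger one is the more specific
hypothesis. The optional maximal-only filter (on by default) collapses a
fragment into any equally-supported superfragment containing it, so the
report shows the most specific representative of each support class. The
four screened support regimes (1 %, 5 %, 1–10 %, 2–10 %) are shipped as
presets, crossed with 5× or 10× fold requirements. Exhaustive enumeration
replaces external miners such as MoSS: at fragment size ≤ 8 and
desk-scale datasets it is exact, self-contained and testable.

## Synthetic data

The generator assembles molecules from a scaffold/decorator grammar
(benzene, pyridine, furan, thiophene, cyclo- and open-chain alkane
scaffolds; alkyl, halogen, hydroxy, amino, methoxy, carboxyl, nitrile,
trifluoromethyl, nitro, thiol decorators, attached only at free
valences and sanitised by RDKit), so every emitted SMILES is a valid,
single-component molecule of realistic size (4–16 heavy atoms). Binary
labels come from a planted rule. In fragment mode the default planted
substructure is chlorobenzene (`Clc1ccccc1`) — chlorinated aromatics being
a recurring motif of active herbicides — built into positives by forcing a
chlorine onto a benzene scaffold and rejection-sampled out of negatives,
so at zero label noise fragment presence and class label coincide
exactly. Positives are drawn at a target prevalence of 0.22, the class
balance of real herbicidal screening sets; achieved prevalence is binomial
around the target. Label noise flips labels independently with the stated
probability. Descriptor mode labels by a molecular-weight/logP window, or
by the upper MW quantile matching the target prevalence when no window is
given; mixed mode requires both the fragment and the window.

Continuous endpoints are a stated linear function of the molecule's true
descriptors plus Gaussian noise (default: value = 1 + 0.8·logP +
0.01·MW − 0.4·HBD + N(0, 0.3)), emulating log-scale LC50/LD50 endpoints
whose structure a descriptor-based regressor can in principle recover
exactly.

What the generator does **not** emulate: the chemical diversity of real
screening libraries (a few hundred grammar products versus thousands of
scaffolds), activity cliffs, assay noise structure, or any correlation
between activity and toxicity endpoints. Passing the recovery tests
therefore demonstrates that the pipeline is correct and can find planted
structure at realistic prevalence and sample sizes — not that it attains
any particular accuracy on real herbicide data.

## Problem sizes and numerical choices

The recovery experiments run at n = 500 molecules for classification and
mining and n = 300 for regression, with 10-fold cross-validation and the
default 300-tree forest — sizes at which the planted signal is comfortably
identifiable and the full pipeline (generation, featurization, 40 forest
fits, fragment mining) completes in about a minute on one CPU. The
shuffled-label null is averaged over 3 seeds. Mining uses max_atoms = 8,
which covers the 7-atom planted fragment with one atom to spare.

Determinism: every stochastic component (generator, fold shuffling, blind
splits, forests) takes an explicit seed; identical seeds give bit-identical
outputs. Degenerate inputs are errors, not warnings: single-class training
sets, zero-variance correlation inputs, empty datasets after parsing
failures, and fractions yielding empty splits all raise typed exceptions
(`ContractError`, `DatasetError`) rather than returning NaNs, except where
a NaN is the documented output (sensitivity of a fold with no positives).

## Known limitations

- Fragment enumeration is exponential in `max_atoms`; beyond ~10 atoms or
  on fused polycyclic molecules it becomes the bottleneck. The default of
  8 is chosen for exactness at desk scale.
- Pharmacophore typing is 2-D and rule-based; tautomers are typed as
  drawn, and the default table is a stand-in, not a validated model of any
  published labelling scheme.
- The likeness windows are descriptive statistics of known actives, not a
  classifier; passing them is necessary-ish, never sufficient.
- No applicability-domain estimation beyond the 2 kDa warning; predictions
  for chemistry far from the training distribution are extrapolations.
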