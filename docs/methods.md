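# Methods

This note records the scientific and numerical choices behind `somkit`:
what the model computes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Problem setting

Site-of-metabolism (SOM) prediction is an atom-level binary
classification problem: given a small molecule, score every heavy atom's
propensity to be attacked by a metabolic enzyme (phase 1 or phase 2).
Training data consists of molecules with a set of annotated SOM atoms;
every annotated atom is a positive instance and every other heavy atom of
the same molecule a negative instance. Molecules with no annotation at
all are excluded from training (absence of annotation is not evidence of
metabolic inertness). Practical use is usually rank-oriented — "look at
the top two atoms" — so the molecule-level top-2 correctness rate
accompanies the threshold metrics.

## Perception and atom typing

Structures are read as SDF V2000 or SMILES and perceived once with one
aromaticity model (RDKit's default); mixing perception models between
training and prediction is treated as an error, since atom types are the
backbone of the fingerprint. Hydrogens are folded into implicit counts;
the heavy-atom graph is the universe of all downstream computation.
Multi-fragment inputs (salts, counter-ions) keep the largest fragment,
logged. Kekulé bond orders are recorded alongside aromatic flags so that
valence-based descriptors have integer bond orders.

Each atom receives one of 26 SYBYL-style types combining element,
hybridization, aromaticity, and functional context (amide N, carboxylate
O, sulfoxide/sulfone S, guanidinium C, ...). The shipped table —
C.1, C.2, C.3, C.ar, C.cat, N.1, N.2, N.3, N.4, N.ar, N.am, N.pl3, O.2,
O.3, O.co2, S.2, S.3, S.O, S.O2, P.3, F, Cl, Br, I, Si.3, Any — is a
reconstruction of the classic SYBYL assignments for common organic
elements and is loadable from a file, so an alternative table can be
substituted without touching the encoding. Typing is total: an element
outside the table rejects the molecule (default) or maps to `Any` under
the explicit opt-in policy; there is no silent fallback.

Atom indices are 0-based internally and 1-based in all user-facing files,
following the SDF atom-block convention. Input heavy-atom order is
preserved through perception, which keeps file-based label indices
meaningful; all typing and fingerprinting depends only on the rooted
graph, so renumbering the input changes no encoded environment.

## Fingerprints

The binary fingerprint assigns a 32-bit block to every (bond distance,
atom type) pair, distance-major layout, `block = d·T + t`. A block with
*n* neighbors sets its first min(*n*, 32) bits — a thermometer encoding
whose popcount recovers the clamped count. The root's own type is encoded
at distance 0 (exactly one bit). The count variant stores exact counts
without clamping and is otherwise informationally identical; it shrinks
the vector 32-fold (156 vs 4992 columns at radius 5) and is selectable at
training time. Default radius 5: large enough that every fixture
molecule's full environment is visible, and configurable (`--radius`)
because the radius is a modeling choice, not a constant of nature.

The feature schema — the exact ordered column list of fingerprint bits,
enabled physicochemical slots, and topological descriptors — is
serialized inside the model bundle. Prediction recomputes the schema from
the stored configuration and refuses to run on any mismatch, printing
both schemas; train/predict layout drift is therefore structurally
impossible.

## Physicochemical descriptors

Ten named slots behind a provider registry; each provider fills all of a
slot's atoms or declares the slot unsupported, and a slot can be disabled,
removing exactly that named column from the schema (checked at
configuration time, not compute time). The reference implementations are
pure-Python/NumPy:

- **atom_degree** — heavy-neighbor count; **formal_valence** — sum of
  Kekulé bond orders plus implicit hydrogens.
- **PEOE sigma charge / electronegativity** — Gasteiger–Marsili partial
  equalization of orbital electronegativities, χ(q) = a + bq + cq² with
  the classical (a, b, c) parameter table, damping 0.5 per cycle, 6
  cycles, χ⁺ of the less electronegative bond partner as divisor (20.02
  for H). Implicit hydrogens participate as pseudo-atoms; their converged
  charges are folded into the parent heavy atom, so per-heavy-atom
  charges sum exactly to the molecular formal charge. Fixed iteration
  count and damping make convergence behavior bit-reproducible.
- **hybrid_polarizability** — per-(element, hybridization) lookup of
  atomic hybrid polarizabilities in Å³, monotone down the halogen group;
  **effective_polarizability** — α_eff(i) = Σⱼ 0.5^d(i,j) α(j) over all
  reachable atoms (hydrogens one bond beyond their parent), a
  distance-damped environment sum.
- **vsepr_geometry** — steric number (sigma neighbors + lone pairs
  estimated from valence-electron count, charge, and valence) mapped to a
  stable small-integer code (0 linear, 1 trigonal planar, 2 bent,
  3 tetrahedral, 4 trigonal pyramidal, 5 trigonal bipyramidal,
  6 octahedral, 7 other).
- **inductive_effect** — Σⱼ (χⱼ − χᵢ)/d(i,j)² on the Pauling scale,
  hydrogens included; **pi_electronegativity** — per-element lookup for
  atoms engaged in double/triple/aromatic bonds, 0 otherwise. Both are
  documented reference forms: simple, deterministic, and monotone in the
  chemistry they proxy.
- **mmff94_charge** — RDKit's MMFF94 force-field charge assignment (the
  one slot backed by an external toolkit); molecules MMFF cannot
  parameterize are skipped with a logged reason.

Exact numeric parity with any particular cheminformatics toolkit's
descriptor routines is explicitly not a goal; the contract is the named
10-slot schema, pluggable backends, and the invariance/symmetry
properties the tests pin down (symmetry-equivalent atoms receive
identical vectors; charge conservation to 1e−6; halogen polarizability
ordering).

## Topological descriptors

From the all-pairs BFS distance matrix of the heavy-atom graph: the
molecular diameter, the atom's eccentricity, their difference, and their
ratio. A single-atom molecule yields (0, 0, 0, 1.0) — the 0/0 ratio is
defined as 1 because the sole atom trivially attains the molecular
maximum. Disconnected pairs (impossible after largest-fragment selection,
but representable) carry a large-integer sentinel excluded from maxima.

## Classifier

scikit-learn `RandomForestClassifier`, single-job. Defaults: 250 trees,
sqrt feature sampling, balanced class weights (atom labels are ~30%
positive in the fixtures and far sparser in real data), fixed seed. The
decision threshold is 0.3 with a ≥ comparison (an atom at exactly p = 0.3
is called positive); the threshold is a config value, not a constant.
Within-molecule ranking is ordinal by descending probability with
ascending atom index as tie-break, so ranks are always a permutation of
1..n and top-2 evaluation is deterministic. Two runs with the same data,
configuration, and seed produce bit-identical serialized models and
byte-identical output files.

Model bundles are single-file archives (pickled payload with a format
version and SHA-256 integrity hash) containing the forest, the feature
schema, the training configuration, and the packed binary fingerprints of
all training atoms. Storing the reference fingerprints makes
applicability-domain scoring possible without redistributing training
structures; a bundle trained from a bare feature table lacks them and
refuses reliability scoring with an explicit capability error.

## Reliability metrics

The FAME score of a query atom is the mean Tanimoto similarity to its
k = 3 nearest training-atom fingerprints, computed on the binary
fingerprint even when the model was trained on counts (the Tanimoto
similarity is defined on bit vectors; both encodings are derived from the
same counts, so no information is lost). Neighbors are selected by
similarity value with index tie-break — the score is invariant to any
tie-consistent selection because it averages values, but reported
neighbor identities are deterministic. The k-NN search runs as one BLAS
matrix product per molecule; intersections are integer-exact in float32
and divisions are done in float64, so the vectorized path agrees with the
scalar definition to the last bit (tested). An all-zero query fingerprint
is out-of-domain by definition: score 0, logged. The search spans all
training atoms, not only same-class atoms — the neighbor set in the score's
definition is unconditional.

The Shannon entropy H(p) = −(p log₂ p + 1−p terms) needs no reference
set; it is a symmetric, monotone transform of |p − 0.5| and complements
the FAME score (descriptor-space proximity vs. prediction confidence).
The `reliability_correlation` report quantifies the relationship between
the two on a given prediction set: Spearman rank correlation plus
per-quantile-bin accuracy (and MCC when calls and labels are supplied;
correctness flags alone cannot reconstruct a confusion matrix).

## Evaluation

ROC-AUC uses the rank (Mann–Whitney) formulation with half-credit for
tied scores; PR-AUC is step-interpolated average precision (linear
interpolation in PR space over-estimates and is deliberately avoided);
F1/MCC/precision/recall come from the thresholded confusion matrix with
MCC defined as 0 when its denominator vanishes. Single-class label
vectors make the two ranking metrics undefined; they are reported as NaN
with an explicit flag while the threshold metrics still compute. TOP-2
counts a molecule correct when an annotated SOM holds rank 1 or 2;
molecules without annotations are excluded from TOP-2 (the rate is
undefined without a positive) but enter the atom-level metrics as
all-negative, and both exclusion counts appear in the report. A molecule
with a single heavy atom contributes that atom as its top-2 set.

## Synthetic fixtures

The generator emulates the *shape* of curated SOM data, not its
chemistry. Molecules (5–25 heavy atoms) are assembled from a weighted
grammar — benzene scaffolds with 1–3 substituent chains, or branched
chains with interior ethers/amines and optional terminal halides — and
labeled by two deterministic environment rules: carbons alpha to an ether
oxygen or aliphatic amine nitrogen, and aromatic C–H positions ortho to a
ring substituent. Both environments are visible to a radius-2 fingerprint,
so the mapping is learnable by construction: a model trained on 400
noise-free molecules reaches held-out ROC-AUC ≥ 0.99 and TOP-2 = 1.0, and
a label-permutation null (labels shuffled globally across all training
atoms) collapses to ROC-AUC ≈ 0.5. An optional i.i.d. label-flip
probability (< 0.5) emulates annotation error. The positive-atom
prevalence (~29%) is far higher than in real metabolic data, and the
chemistry is deliberately simple — no fused rings, no stereochemistry, no
real enzyme selectivity. Passing the recovery test therefore demonstrates
that the pipeline extracts an atom-environment signal its features can
express, not that it predicts real metabolism at any particular accuracy.

Splitting is molecule-level with stereo-agnostic canonical-SMILES
grouping: duplicate skeletons always land in the same partition, so
near-duplicates can never inflate held-out performance.

## Problem sizes and determinism

The reference experiment (and `scripts/acceptance.py`) uses 400
molecules, an 80/20 split, and the default model — roughly 3,500 training
atoms by 5,006 features, a deliberately desk-scale configuration that
keeps the full pipeline under a minute on one core while leaving the
learnability and null conclusions unambiguous. All randomness flows from
explicit seeds (fixture grammar, split, forest); no operation uses hidden
parallelism, wall-clock time, or iteration over unordered containers that
could perturb results. CSV/JSON writers use fixed float formats, sorted
keys, and LF endings so repeat runs are byte-identical.

## Known limitations

- The SYBYL table and the functional forms of the inductive-effect and
  pi-electronegativity descriptors are documented reference constructions;
  both are replaceable (config file / provider registry) where strict
  comparability with another toolkit is needed, and single slots can be
  disabled outright.
- PEOE parameters cover H, C, N, O, S, P and halogens (P approximate);
  molecules with other elements are rejected rather than guessed at.
- Reliability scores qualify, but do not calibrate, probabilities; no
  conformal or isotonic machinery is included.
- Precision is not mathematically monotone in the decision threshold for
  arbitrary score sets; the documented monotonicity check holds on
  well-separated prediction sets such as the recovery experiment's.
- The fixtures' label rules are surrogates; no conclusion about real
  phase 1/phase 2 regioselectivity follows from fixture performance.
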