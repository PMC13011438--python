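# somkit

**Trainable atom-level site-of-metabolism (SOM) prediction.**

Which atom of a drug-like molecule will an enzyme attack first? Knowing the
likely sites of phase 1 (oxidation/reduction/hydrolysis) and phase 2
(conjugation) metabolism early lets medicinal chemists anticipate metabolic
hotspots and design more stable compounds. `somkit` is a toolkit for
building and evaluating such predictors: it turns every heavy atom of a
molecule into a feature vector, trains a random forest to score each atom's
probability of being a SOM, ranks the atoms within each molecule, and
attaches two per-atom reliability measures to every prediction.

## The model

Each heavy atom *x* is described by:

- **A rooted circular fingerprint.** Every atom carries one of 26
  SYBYL-style types (C.3, C.ar, N.am, O.co2, ...). For every combination of
  bond distance *d* ∈ [0, R] from the root and atom type *t*, the
  fingerprint owns a 32-bit block; the first *n* bits of block (*d*, *t*)
  are set when the root has *n* neighbors of type *t* at distance *d*
  (default radius R = 5). An equivalent count-fingerprint variant stores
  the exact counts in a T·(R+1) vector instead.
- **Ten physicochemical descriptors:** heavy-atom degree, formal valence,
  hybrid and effective polarizability, VSEPR coordination geometry code,
  inductive effect, PEOE (Gasteiger–Marsili) sigma charge and sigma
  electronegativity, pi electronegativity, and MMFF94 partial charge.
- **Four topological descriptors:** the molecular diameter (maximum bond
  distance between any two atoms), the atom's eccentricity (its maximum
  bond distance to any atom), and their difference and ratio.

A scikit-learn random forest (250 trees, balanced class weights, fixed
seed) maps the feature vector to a SOM probability *p*; atoms are called
positive at *p* ≥ 0.3 and ranked within each molecule by descending *p*
(ties by atom index). All predictions are fully deterministic.

Two reliability scores qualify every prediction:

- **FAME score** — applicability domain:
  FAMEScore(**x**) = (1/k) Σᵢ Tanimoto(**x**, **x**ᵢ) over the k = 3
  nearest training-atom fingerprints, with
  Tanimoto(**a**, **b**) = **a**·**b** / (‖**a**‖² + ‖**b**‖² − **a**·**b**).
  1.0 means the atom's environment is literally present in the training
  set; low values flag extrapolation.
- **Shannon entropy** — uncertainty of the probability itself:
  H = −(p log₂ p + (1−p) log₂(1−p)) ∈ [0, 1], low is confident.

Because curated SOM datasets are licensed, the package ships a synthetic
generator: molecules built from a fragment grammar (alkyl chains, ethers,
amines, benzene rings, halides) whose labels follow a deterministic
atom-environment rule (carbons alpha to an ether/amine heteroatom;
aromatic C–H ortho to a ring substituent), with optional label noise. It
exercises every stage of the pipeline and supports parameter-recovery
experiments.

## Worked example

```bash
somkit fixtures --n 100 --seed 7 --out train.sdf
somkit train    --in train.sdf --seed 1 --out model.bundle
somkit fixtures --n 10 --seed 99 --out query.sdf
somkit predict  --model model.bundle --in query.sdf --reliability --out pred.csv
somkit evaluate --pred pred.csv --truth query.sdf --out report.json
```

The prediction CSV has one row per heavy atom (`atom_idx` is 1-based):

```
mol_id,atom_idx,element,probability,call,rank,fame_score,shannon_entropy
FIX00000,1,C,0.080000,0,4,0.875000,0.402179
FIX00000,2,C,0.892000,1,1,0.881127,0.493854
FIX00000,3,C,0.040000,0,6,0.933333,0.242292
```

Atom 2 of `FIX00000` is called a SOM (p = 0.892 ≥ 0.3) and ranks first in
its molecule; its FAME score of 0.88 says its environment is close to the
training data. The evaluate step prints atom-level metrics and the
molecule-level top-2 correctness rate (fraction of molecules with a true
SOM among the two top-ranked atoms):

```
atoms=108 molecules=10 roc_auc=1.000 pr_auc=1.000 f1=0.963 mcc=0.952 precision=0.929 recall=1.000 top2=1.000
```

The same functionality is available from Python:

```python
import somkit
from somkit import fixtures as fx

mols = fx.generate(fx.FixtureSpec(n_molecules=400, seed=7))
train_m, test_m = fx.split(mols, (0.8, 0.2), seed=7)
model = somkit.train(train_m, somkit.TrainingConfig(seed=1))
preds = somkit.predict(model, test_m, with_reliability=True)
```

## Package layout

| Module | Contents |
| --- | --- |
| `somkit.chem_core` | perception, SYBYL typing, topological distances |
| `somkit.fingerprints` | binary-block and count rooted circular fingerprints |
| `somkit.descriptors` | physicochemical + topological descriptors, provider registry |
| `somkit.reliability` | Tanimoto, FAME score, Shannon entropy |
| `somkit.som_model` | random-forest training, prediction, model bundles |
| `somkit.evaluation` | atom metrics, TOP-2, reliability comparison |
| `somkit.fixtures` | synthetic labeled molecules, train/test splitting |
| `somkit.io` / `somkit.cli` / `somkit.config` | SDF/CSV/JSON I/O and the CLI |

See `docs/methods.md` for the modeling choices, parameter defaults, and
limitations.
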