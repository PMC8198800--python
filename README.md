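# lnqspr

Stability-constant QSPR for lanthanide(III) complexes, with decodable
models: predict logK of Ln(III)-ligand complexes from feature-class
circular fingerprints with a cross-validated dense-network ensemble,
then decompose the trained models into additive per-fragment
contributions via Shapley attribution.

## Who this is for

Designing a ligand with a target binding strength or selectivity for a
lanthanide cation usually starts from a few hundred literature
stability constants per metal.  A black-box regressor can interpolate
them; `lnqspr` additionally answers the design question - *which
fragments of the ligand push logK up or down, and by how much* -
while tracking exactly which fingerprint bits are chemically
interpretable and which are ambiguous hash collisions.

## The model

For a ligand with fingerprint x in {0,1}^256 (Morgan radius 2 over
pharmacophoric atom invariants), a 10-fold cross-validated ensemble of
multilayer perceptrons f_1..f_10 (3 x 512 rectifier units, l2 and
input dropout, early stopping per fold) predicts

    logK(x) = (1/10) * sum_k f_k(x),

with the endpoint MinMax-scaled during training.  The fitted ensemble
is decoded per training molecule into Shapley values phi_b against a
background of k = 30 k-means medoids of the training fingerprints:

    base + sum_b phi_b = logK(x),    base = mean prediction over the background.

Per non-colliding bit b, contributions from molecules containing the
fragment are pooled; bits with dispersion exceeding |mean| or with
support below 3 molecules are discarded; the survivors form the
fragment-importance table (fragment SMILES, mean contribution in logK,
dispersion, support), per metal.

## Worked example

Everything below runs from scratch in a few minutes on one CPU; the
synthetic library has known additive fragment effects, so the decoded
table can be read against the truth.

```python
import numpy as np
from lnqspr import (
    SyntheticSpec, generate, fingerprint_dataset, detect_collisions,
    StabilityModel, SplitSpec, NetConfig,
    kmeans_background, shapley_attribute, filter_contributions,
)

ds = generate(SyntheticSpec(seed=3))          # 200 ligands, 8 planted effects
fp = fingerprint_dataset(ds.smiles)            # 256-bit radius-2 FCFP-style
y = np.array([r.logk for r in ds.records])

model = StabilityModel(y, fp.X.astype(float), split_spec=SplitSpec(seed=3))
res = model.fit(NetConfig(seed=3))
print(res.summary())

Xtr = model.exog[model.train_idx]
bg = kmeans_background(Xtr, k=30, seed=3)
attr = shapley_attribute(res.ensemble.predict, Xtr, bg,
                         mode="sampled", budget=512, seed=3,
                         molecule_indices=model.train_idx)
table = filter_contributions(attr, fp, metal="Eu")
print(table.head(6).to_string(index=False))
```

Output (abridged):

```
logK ensemble regression
========================================
molecules (train/test):  160/40
architecture:            3 x 512 nodes
sub-models:              10
R2  (validation mean):   0.791
RMSE(validation mean):   0.584 logK
R2  (test):              0.867
RMSE(test):              0.484 logK
metal  bit environment_key  mean_contribution  dispersion  support
   Eu   66    CC[C:1](=O)O           0.367910    0.081845       25
   Eu    8          [Cl:1]          -0.358096    0.066725       24
   Eu   71         C[Cl:1]          -0.309015    0.120534       24
   Eu   40    CC[CH2:1]CCl          -0.306374    0.089305       21
   Eu  184       C[CH2:1]C           0.294301    0.089080       25
   Eu  129 CC[CH2:1]C(=O)O          0.288471    0.100589       25
```

Reading: the test R^2 of 0.87 with RMSE 0.48 logK is what a 200-ligand
additive library with 0.5 logK noise supports.  In the fragment table,
the carboxylate environments (bits 66/129 and their chain-side
companion 184) carry positive mean contributions and the chloro
environments (bits 8/71/40) negative ones - matching the planted
effects (+1.8 and -1.4 logK).  One substituent splits its credit
across its handful of perfectly correlated bits, so the per-bit values
of a fragment sum to roughly its planted weight;
`truth_alignment(ds, fp)` gives the bit-to-substituent map.

The same pipeline runs from the shell:

```
lnqspr simulate --out runs/sim --n-molecules 200 --seed 3
lnqspr run-all --input-csv runs/sim/synthetic.csv --out runs/demo --seed 3
```

For literature data, supply a CSV with columns
`smiles,metal,stoich,logk,ionic_strength,temperature,method,source`;
curation keeps measurements at 0.1-0.3 M and 20-25 C and resolves
duplicates (potentiometric preferred).

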