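# Methods

`lnqspr` predicts stability constants (logK) of lanthanide(III)-ligand
complexes from circular fingerprints and then decodes the trained
models into additive per-fragment contributions.  This note records
the models, the parameters that matter, the synthetic study design,
and the numerical choices, in enough detail to re-derive every default.

## The regression model

For each (metal, stoichiometry) dataset the endpoint is logK, the
base-10 logarithm of the complex formation constant.  Ligand
structures are encoded as feature-class circular (Morgan) fingerprints:
atom invariants are the six pharmacophoric classes (donor, acceptor,
aromatic, halogen, basic, acidic), neighbourhoods are hashed out to
bond radius 2, and the 32-bit environment identifiers are folded by
modulus into 256 binary bits.  Connectivity (ECFP-style) invariants
and counted bits are available behind flags.

The estimator is an ensemble of 10 multilayer perceptrons built by
cross-validation:

1. stratified 80/20 train/test split - the endpoint is cut into 10
   equal-frequency bins and the test fraction drawn within each bin,
   so train and test endpoint distributions match (bins with fewer
   than two members merge into a neighbour; largest-remainder
   allocation keeps the global test size exact);
2. the training 80% is shuffled into 10 folds; each sub-model trains
   on its 90% and early-stops on its 10% (patience 30 epochs,
   max 500, best-validation weights restored);
3. the ensemble prediction is the arithmetic mean of the sub-model
   outputs, mapped back to logK units.

Targets are MinMax-scaled to [0, 1] before fitting; binary features
are numerically invariant under MinMax scaling and enter the network
as 0/1.  Consequently training is exactly invariant to affine
transformations of the endpoint.

Architecture default: 3 hidden layers x 512 rectifier units with a
linear output, the accuracy/cost compromise for datasets of 82-324
ligands; the `architecture_sweep` helper reproduces the comparison
over 1-5 layers x 256-4096 nodes on identical folds.  Optimisation:
Adam, learning rate 1e-3, batch size 32, mean-squared error on the
scaled target.  Regularisation: l2 weight penalty 1e-4 plus
input-layer dropout 0.2, realised as per-epoch Bernoulli masking of
the training features with inverted scaling (the scikit-learn backend
has no hidden-layer dropout; input dropout is the variant that
matters for a model that will later be decoded bit by bit).
Validation is always computed on unperturbed features.  Per-fold
seeds derive deterministically from the configuration seed.

Evaluation: R^2 = 1 - SS_res/SS_tot about the evaluated set's own
mean, and RMSE in logK units, on the per-fold validation sets and on
the held-out test set.

## Fingerprint provenance and collisions

Every bit keeps the full map back to the atom environments that set
it: the environment key is the canonical SMILES of the bond-radius-r
neighbourhood with the central atom carrying atom-map 1.  A bit is a
*collision* when two or more distinct environment keys were observed
at it in the dataset at hand - collision status is dataset-relative,
because that is what interpretation needs and all that is observable.
Only non-colliding bits enter the fragment-importance analysis.  Note
that with feature-class invariants the radius-0 bits pool chemically
different atoms of the same pharmacophoric class by construction;
they are flagged as collisions by the structural key comparison and
excluded, which matches the intuition that "a donor atom is present"
is not a depictable fragment.

## Shapley fragment attribution

The trained ensemble f is decomposed molecule by molecule into
per-bit contributions phi with the efficiency property
base + sum_b phi[b] = f(x), where base is the mean prediction over a
background set.  The coalition value is interventional:
v(S) = mean_z f(x_S, z_notS) over background vectors z.

*Background.*  The training fingerprints are summarised by k-means
(k = 30, 10 restarts) and each centroid is replaced by its nearest
distinct training vector (medoid).  Fingerprint space is binary, so
fractional centroids are not valid model inputs; the medoid variant
keeps the background on-manifold (raw centroids remain available
behind a flag).  The stored objective is the total within-cluster
squared distance to the chosen representatives.

*Exact mode.*  Only bits at which the molecule differs from at least
one background vector carry non-zero attribution; the rest are
provably zero and skipped.  Over the M differing bits all 2^M
coalitions are enumerated (M <= 15 by default, cost 2^M x k model
evaluations) and the Shapley sum is computed directly.  This mode is
the oracle: efficiency holds to machine precision and the values
match closed forms for additive models.

*Sampled mode.*  The kernel-regression estimator: coalitions are
drawn from the Shapley-kernel size distribution in antithetic
(coalition, complement) pairs, each evaluated against one cycling
background vector, and phi solves the weighted least squares with the
efficiency constraint eliminated exactly - so base + sum(phi) = f(x)
holds to machine precision in this mode too.  The budget counts model
evaluations per molecule (default 512 in the pipeline, at least
4M + 8 for identifiability).  When the budget covers full enumeration
against the full background the estimator enumerates and coincides
with exact mode.  Attribution is computed for training-set molecules,
and the explained function is the ensemble average (one explanation
per molecule), not per-sub-model explanations averaged afterwards.

## The filtering cascade

Per bit: (1) colliding bits are discarded; (2) zero values are
discarded - a value is zero structurally when the bit is inactive in
the molecule (the fragment is absent); exact numeric zeros are
likewise discarded; (3) the mean and the dispersion (root mean
squared deviation from the mean, i.e. the population standard
deviation - the only reading under which "dispersion bigger than the
mean in absolute value" is a meaningful comparison) are computed over
the remaining values and the bit is dropped when dispersion > |mean|;
(4) the bit must keep at least 3 values (support >= 3).  Surviving
bits are reported with their fragment SMILES, mean contribution in
logK, dispersion and support, per metal, plus a cross-metal pivot.

## Synthetic study design

The generator emulates per-metal literature tables: a few hundred
distinct small ligands, logK additive over the substituents present
plus Gaussian noise (heavier-tailed noise behind a flag).  Molecules
are alkyl chains (default length 3-6) carrying 0-2 substituents at
the chain ends.  Two deliberate design choices:

- *End attachment.*  Substituents attach only at chain ends, keeping
  the dataset's environment vocabulary (~75 distinct keys) below the
  shortest fingerprint length studied (64).  With interior attachment
  the same grammar produces ~400 environments and every length below
  512 is saturated with collisions, a regime in which no length
  comparison is informative.
- *Disjoint planted set.*  The eight substituents carrying effects
  (carboxyl +1.8, 4-pyridyl +1.2, vinyl +1.1, hydroxyl +0.8, amino
  +0.6, nitrile -0.8, methoxy -1.0, chloro -1.4 logK) are pairwise
  disjoint in their radius-<=2 environments, so each owns its bits
  and additive credit cannot leak between planted fragments.  The
  zero-effect decoys deliberately include overlapping chemistry
  (aminodiacetate contains carboxyl groups; phenyl shares ring
  environments with pyridyl), so the collinearity of real ligand sets
  is present in the library without making the ground truth
  unidentifiable.

Effects are planted on substituents, not on bits; `truth_alignment`
finds, per substituent, the non-colliding bits whose activity pattern
equals the substituent's presence indicator exactly (perfect tags)
and reports substituents that have none.  Defaults: 200 molecules,
noise 0.5 logK, intercept 8 logK, one metal; a monotone per-metal
intercept gradient emulates the rising mean logK across the
lanthanide series.

What the generator does not emulate: chelate-ring energetics,
ionic-strength and temperature dependence, measurement-method biases,
and scaffold diversity beyond one homologous series.  Passing tests
on this generator demonstrate that the pipeline recovers additive
structure through the fingerprint/model/attribution stack - not that
literature data are additive.

## Scoring recovery

A planted substituent activates g perfectly-correlated tag bits
(g between 1 and ~5), and Shapley attribution splits its credit
near-equally among them, so individual bit means scale like w/g -
with the redundancy of the fingerprint, not the planted effect.
Recovery is therefore scored at the fragment (substituent) level: the
reported contribution of a substituent is the sum of the mean
contributions of its reported tag bits; signs are additionally
required to be correct for every reported tag bit individually.  The
reference check requires a Spearman correlation >= 0.8 between the
per-substituent aggregates and the planted weights, in at least 4 of
5 seeds.

## Numerical choices and degenerate inputs

- Duplicate measurements (same standardized SMILES, metal,
  stoichiometry) collapse by a deterministic cascade: potentiometric
  method preferred, then conditions closest to 25 C / 0.1 M (distance
  scaled by the curation half-windows), then the median-logK member.
- Constant endpoint: R^2 is refused as undefined; splitting
  degenerates to a plain random split of the correct sizes.
- Constant feature columns MinMax-scale to 0; scaling inverts to
  within 1e-9.
- Ties in quantile binning are resolved by stable sorting; bins with
  fewer than two members merge leftward.
- k-means backgrounds with k equal to the training size return the
  training set itself (objective 0); duplicate medoids are avoided by
  taking the nearest not-yet-chosen vector.
- Exact attribution with more than `max_exact_bits` differing bits
  raises a capability error that names the sampled alternative.

## Known limitations

- *False-discovery behaviour of the cascade.*  The dispersion filter
  is scale-free: it tests consistency of a bit's contributions across
  molecules, not their magnitude.  A cross-validated ensemble fitted
  to a pure-noise endpoint retains small but genuine structure (the
  sub-models share 90% of their training rows and fit the same noise
  draw; per-bit effects of ~0.02-0.05 logK remain after early
  stopping, l2 and dropout), and the attribution faithfully reports
  it, so on null data a substantial fraction of clean bits can
  survive filtering with tiny mean contributions.  The cascade as
  specified has no magnitude scale that could reject them; a
  calibrated variant would need a significance test of each per-bit
  mean against the estimator's noise, which is deliberately not
  smuggled into the published procedure.  Users should read
  fragment tables jointly with the model's test R^2 and treat
  contributions below ~0.1 logK as unresolved.
- Dropout is input-layer only (backend limitation); hidden-layer
  co-adaptation is controlled by l2 and early stopping.
- Published headline numbers for the literature datasets can only be
  recomputed from the deposited per-metal tables, which have no
  public accession; `validation.literature_reproduction` implements
  the protocol and refuses cleanly when the tables are absent.
- The CLI's train/evaluate/explain subcommands run the same resumable
  pipeline up to their stage; stages already on disk are not redone.
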