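# Methods

## Problem setting

Ionic liquids (ILs) are organic salts that are liquid near room
temperature.  Their physicochemical properties — density, viscosity,
surface tension — depend on the combination of a discrete cation and
anion and on the measurement conditions (temperature, sometimes
pressure).  `iongraph` implements a quantitative structure–property
(QSPR) pipeline that predicts such properties directly from the two
ions' SMILES strings with a graph neural network, without hand-crafted
group-contribution descriptors.  The pipeline covers data curation,
IL-aware splitting, three ways of turning an ion pair into graph input,
five charge featurizations, four graph-convolution families, and
transfer learning between property tasks.

## Ion preparation

An IL is a `(cation, anion)` SMILES pair with formal charges +1/−1
(configurable magnitude; multivalent pairs are rejected unless the check
is relaxed).  SMILES are canonicalized with RDKit so identical ions
deduplicate.

3D geometries are produced by a conformational search: `n_conformers`
(default 10) ETKDG embeddings with a fixed, configurable random seed,
each refined by force-field optimization, keeping the lowest-energy
conformer.  Two refinement engines are supported and form an
experimental axis:

* **rdkit** — MMFF94, falling back to UFF when MMFF94 parametrization is
  unavailable for an ion;
* **openbabel** — Open Babel's `mmff94` local optimizer (fallback
  `uff`), applied to the same seeded starting coordinates.

Both engines share the seeded RDKit embedding because Open Babel's own
3D builder draws its random state from the wall clock, which would break
the package's reproducibility contract (identical coordinates for
identical seeds).  Open Babel's local optimizer itself is deterministic,
so engine comparisons remain meaningful: the engines differ in the
force-field implementation that shapes the final geometry and in the
charge models computed from it.

Joint mode relaxes the cation and anion as one system, starting from
the two separately optimized ions placed at a 4 Å centroid separation
along the x-axis.  Counterion screening makes the resulting partial
charges differ from the separately-optimized ones, which is exactly the
contrast the joint/separate axis probes.

Graphs are heavy-atom only: hydrogens are folded into a per-atom
`h_count` feature, and hydrogen partial charges are summed onto the
bonded heavy atom so every charge scheme conserves the ion's net charge
over graph nodes.

## Charge schemes

| scheme | backend | notes |
|---|---|---|
| `none` | — | zero vector; electrostatics-blind baseline |
| `formal` | RDKit bookkeeping | integers, exact conservation |
| `gasteiger` | RDKit | electronegativity equalization; always RDKit because Open Babel's implementation zeroes ion totals, violating charge conservation |
| `mmff94` | geometry's engine | force-field parametrized charges |
| `qtpie` | Open Babel | charge transfer + polarization; only Open Babel provides it |

Iterative schemes must conserve the net ion charge to 0.05 e; a larger
deviation raises a warning.

## Graph construction

Node features (d = 8, fixed order): atomic number (raw integer), number
of hydrogens, hybridization one-hot over {sp, sp2, sp3, other}
(monoatomic ions map to *other*), aromaticity flag, charge.  Edges are
chemical bonds stored as two directed arcs with weight equal to the
kekulized bond order (1, 2, 3) or 1.5 for aromatic bonds.  Distances and
angles are deliberately not features; geometry only enters through the
charge calculation.

Three ion-pair scenarios:

* **A (`merged_a`)** — each ion featurized separately, merged
  block-diagonally with cation atoms first; the dense adjacency of the
  result is exactly block-diagonal.
* **B (`joint_b`)** — a single graph from the jointly relaxed pair;
  cation atoms precede anion atoms.
* **C (`GraphPair`)** — both ions stay separate graphs processed by
  parallel convolution towers; `separate` pooling concatenates the two
  pooled vectors, `join` pooling sums them.

The **virtual ionic bond** (scenarios A and B only) appends two directed
arcs of weight −1 between cation atom 0 and the last anion atom at the
end of the edge list.  It is inserted in both directions: a one-way edge
would make the readout depend on which ion was listed first, breaking
the symmetry of message passing.  The specific atom pairing is
arbitrary; inserting it twice is an error.

## Network

Default architecture: 4 graph convolutions of widths 128/256/256/128
with ReLU, dropout 0.2 after the convolution stack, permutation-
invariant sum readout, concatenation of z-scored conditions
(temperature; pressure when present), then fully connected layers
256 → 128 with ReLU, batch normalization and dropout before the final
scalar layer.  The wording of the source protocol is ambiguous about
whether "256 plus one neuron per condition" is an input or output
width; here the pooled vector and conditions are concatenated at the
head input and the first head layer outputs 256.

Convolution families (all built on a small NumPy reverse-mode autodiff
engine; no deep-learning framework is used):

* **gcn** — x′_v = Σ_{w∈N(v)∪{v}} (e_wv/√(d_v d_w)) · W x_w with an
  implicit unit self-loop.  Degrees are accumulated from |edge weight|
  so the −1 ionic bond cannot zero or negate a normalization factor; the
  signed weight still scales the message.
* **gat** — single-head attention (head count configurable): softmax
  over incoming edges of a leaky-ReLU score, message scaled by the edge
  weight.
* **kgc** — un-normalized neighborhood convolution with a separate root
  transform, x′_v = W₁x_v + W₂ Σ e_wv x_w.
* **mfc** — fingerprint-style convolution with degree-specific weight
  matrices (degree capped at 6 by default); edge weights do not enter,
  following the published formulation, so the ionic-bond weight is
  invisible to this family.

Scenario C towers share weights by default (keeps the parameter count
equal to scenarios A/B; configurable off).  Targets are z-scored with
training-split statistics during optimization and predictions are
returned in dataset units; condition standardization constants are
stored with the model and serialized in checkpoints (.npz with a JSON
header, round-trip bitwise).

## Curation

Outlier detectors over the property column, applied globally (per-IL
stratification is an option): z-score (threshold 3), IQR (k = 1.5), and
MAD (k = 3.0, the middle of the conventional 2.5–3.5 band).  The MAD is
used unscaled — no 1.4826 normal-consistency factor — because the rule
is defined directly as "k times the MAD from the median".  Detection
runs on untransformed values; heavy-tailed properties (viscosity spans
seven orders of magnitude) are exactly where the robust detectors and
the optional log10 target transform matter.  Skewness is the adjusted
Fisher–Pearson sample estimate.

## Splitting

The test set is drawn exclusively from clean records at whole-IL
granularity: a seeded shuffle of ILs is consumed until their records
first reach 10% of the clean set.  Remaining records are split 5:1
train:validation — note the overall 75:15:10 proportion is the
authoritative statement; record-level `random` mode is the default, and
`restricted` mode keeps each IL's temperature series within a single
partition.  The same test ILs are reused across clean/raw variants so
scores stay comparable.  The 10% target counts records, not ILs, which
matches the observation that whole-IL selection yields a much smaller
share of unique liquids.

## Training

MSE loss, Adam (lr 0.001), cosine annealing restarting every 40 epochs,
300 epochs by default, batch size 64 (not stated by the source
protocol; a common default).  The reported model is the
best-validation-RMSE epoch.  Aggregation runs `n_seeds` (4) ×
`n_reps` (10) trainings: the seed varies the split and initialization,
repetitions re-draw the initialization only; metrics are reported as
mean ± sample std.  All randomness (embedding, init, batching, dropout)
is seeded; CPU runs are bitwise reproducible.

Transfer learning: `fine_tune` updates all parameters from pretrained
values; `linear_only` freezes the convolution towers bitwise and
retrains the head.  When the condition count changes, the head is
re-initialized (its input width changes); convolution weights always
transfer.

## Synthetic data

The generator emulates the *shape* of curated IL property databases,
not their physics: templated cations (imidazolium, pyridinium,
tetraalkylammonium, tetraalkylphosphonium with seeded chain lengths
1–12), a fixed anion library (halides, tetrafluoroborate, alkylsulfates,
dicyanamide, ...), a temperature grid (default 283–353 K in 10 K steps),
optional pressure grid, and a ground truth linear in graph-computable
descriptors: per-ion heavy-atom counts, aromatic-atom count, aliphatic-
carbon count, plus linear temperature (−0.08 per K) and pressure terms.
Default coefficients give a surface-tension-like scale (≈35–55 mN/m,
decreasing with temperature) so relative errors are well defined.
Because every descriptor is a sum of node-local indicator functions,
the map is exactly representable by a sum-pooled graph network — which
makes held-out R² a parameter-recovery measure.  What the generator
does **not** emulate: nonlinear temperature laws (e.g. Arrhenius-type
viscosity), inter-ion synergy beyond additivity, heteroscedastic
measurement error, or literature-style per-source bias.  Passing tests
therefore certify the machinery, not chemical accuracy on real data.

Mislabels are multiplicative — a seeded subset of records is multiplied
or divided by `mislabel_scale` (default 10) on a fair coin — mimicking
unit errors and impurity effects, and are re-flagged `raw`.

### A note on mislabel robustness

Multiplicative corruption with a fair multiply/divide coin preserves
the median but not the mean: a corrupted record's expected factor is
(s + 1/s)/2, so at fraction φ the conditional mean of observed values
is inflated by 1 + φ((s+1/s)/2 − 1) — a factor 1.405 at φ = 0.1,
s = 10.  A least-squares learner converges to that inflated map, so
*direct* training on grossly corrupted records carries a systematic
scale bias and held-out R² collapses; best-validation checkpointing
does not rescue it because every point of the trajectory is biased.
Robustness in this pipeline comes from the curation stage: MAD
filtering of the corrupted training records (scale-10 errors are far
outside the MAD band) restores held-out accuracy to within a few
hundredths of R² of clean training.  Both numbers — direct and
curated — are measured by the benchmark protocols and reported by the
acceptance script.  Direct-training robustness would require either
mean-preserving corruption or a robust loss, both outside this
package's corruption and loss definitions.

## Benchmark problem sizes

Reference protocols (`iongraph.benchmarks`) use: parameter recovery —
300 ILs × 8 temperatures, default widths, 100 epochs (the loss curve is
flat well before that); mislabel robustness — 80 ILs × 6 temperatures,
widths 32/64/64/32, 100 epochs, 5 seeds, chosen so the clean baseline
is converged (an underfit baseline would confound optimization noise
with label-noise effects); transfer contracts — 24 ILs, 2 epochs.

## Numerical choices and degenerate inputs

* Zero dispersion: z-score and MAD detectors flag nothing and log a
  warning; skewness raises on zero-variance input.
* R² is undefined for zero-variance targets and MARE for any zero true
  value; both raise rather than returning NaN.
* Batches with a single record are skipped (batch normalization needs
  at least two rows); validation/prediction run in eval mode on running
  statistics, so single-graph prediction is well defined.
* GCN degree normalization uses |weight|, making the −1 ionic bond safe
  in every graph configuration.
* Empty graphs are rejected at construction; the anion of a merged
  graph must have at least one atom.

## Known limitations

* The synthetic ground truth is additive; the pipeline's ability to
  capture genuinely synergistic cation–anion effects is untested here.
* MFC ignores edge weights (published formulation), so bond orders and
  the ionic bond do not reach it except through degree counts.
* Gasteiger charges always come from RDKit; an Open Babel Gasteiger
  variant would not conserve ion totals.
* Training is CPU-bound NumPy; it is sized for datasets of order 10³–10⁴
  records, not the 10⁵ scale of full literature databases.
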