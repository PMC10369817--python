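# Methods

## Problem setting

Lead-optimization programs revolve around congeneric series: compounds that
share a structural core (scaffold) and differ in substituents at one or more
sites.  When two analogs share most of their structure but differ in potency
by an order of magnitude or more (an *activity cliff*), the substituents
outside the shared core are the natural explanation for the change.  This
package builds a model-explainability benchmark on that idea and implements a
substructure-aware training objective — the *uncommon-node* (UCN) loss — that
encourages a graph neural network's atom embeddings to carry that
responsibility explicitly.

## Pair construction and ground truth

For each protein target, every unordered pair of compounds is a candidate.
A pair qualifies when

* the maximum common substructure (MCS) covers at least a fraction
  `mcs_threshold` (default 0.5) of *both* molecules — the conservative
  `min(|MCS|/N_i, |MCS|/N_j)` reading — and
* the potency difference is at least `min_delta` (default 1.0) pIC50 log
  units, inclusive.

MCS is computed with RDKit's FMCS with element-identity atom matching,
bond-order matching, ring-atoms-only-match-ring-atoms, and **complete-ring
matching**.  The last flag departs from the FMCS default: without it the
common substructure may contain partial rings, which lets a substituent at
one site match a substituent at a different site through a reoriented ring
fragment.  A scaffold containing half a ring is not chemically meaningful,
and complete-ring matching makes the common core coincide with the planted
scaffold of the synthetic generator exactly.  When several embeddings of the
MCS exist, the lexicographically smallest atom-index match is taken, so all
downstream masks are deterministic.

Atoms outside the MCS are the pair's *uncommon* atoms.  Ground-truth colors
are `+1` on uncommon atoms of the more potent compound, `-1` on those of the
less potent one, `0` on the shared core.  Pairs where either compound has an
empty uncommon set (one molecule is a substructure of the other) carry no
usable ground truth; they are excluded from metric evaluation and from the
UCN term during training (their absolute-potency MSE terms are kept).

Splits are leakage-free by construction: compounds, not pairs, are randomly
partitioned 80/20; a pair joins the training (test) set only if both
compounds are training (test) compounds, and straddling pairs are dropped and
counted.  Targets with fewer than 50 training pairs are discarded.

## Model

The regressor is a message-passing neural network implemented in NumPy with
explicit reverse-mode gradients (forward caches plus a hand-written backward
pass; a finite-difference gradient check is part of the test suite).  Per
molecule:

* node states are initialised by a linear-plus-ReLU encoding of atom features
  (one-hot element over {C, N, O, S, F, Cl, Br, I, P, other}, one-hot degree,
  formal charge, aromaticity and ring flags);
* for `n_message_passes` rounds, each directed edge sends a linear message
  computed from the source state and the edge features (one-hot bond order
  plus ring flag); messages are sum-aggregated at the destination and the
  node state is updated by a single-layer perceptron;
* the potency prediction is a two-layer head on the *mean* over all node
  embeddings.

A second head `xi`, a two-layer perceptron with linear activations and
parameters separate from the prediction head, maps the mean embedding of a
masked atom subset to a scalar — the UCN readout.  Keeping the heads separate
means the absolute-potency path never consumes mask information, so a trained
model predicts on arbitrary single molecules (no scaffold needed at inference
time).

### Losses

For a pair (i, j) with observed potencies y and predictions yhat:

* `L_MSE = (y_i - yhat_i)^2 + (y_j - yhat_j)^2`
* `L_AC  = ((y_i - y_j) - (yhat_i - yhat_j))^2` (activity-cliff control:
  pair sampling alone augments the data, so a pairwise objective without
  substructure information separates that effect)
* `L_UCN = ((u_i - u_j) - (y_i - y_j))^2`, where `u = xi(mean of uncommon-atom
  embeddings)`

Training minimises `L_MSE`, `L_MSE + lambda*L_AC`, or `L_MSE + lambda*L_UCN`
with `lambda = 1` by default.  Batch values are means over pairs so `lambda`
is batch-size independent.  All three modes iterate over identical pair
batches (same shuffles for a given seed), so runs differ only in the
objective; with `lambda = 0` the combined modes reproduce the plain-MSE run
bit for bit, which is asserted in the tests.  The optimiser is Adam at a
fixed step (default 1e-3) for a fixed number of epochs; the prediction-head
bias is initialised to the training-label mean.  All randomness
(initialisation, shuffling) derives from the config seed, and training is
bitwise reproducible.

## Attribution methods

All methods return one signed score per heavy atom; feature-resolved scores
are collapsed by the mean over the feature dimension.  Scores are not
normalised per molecule — the metrics consume raw signs and magnitudes.

* **CAM** — `score_v = w . h_v` with `w` the prediction head linearised at
  the pooled embedding (for a linear head this is classical CAM and
  `mean_v score_v = yhat - bias` exactly; the bias is excluded because a
  per-graph constant cannot be attributed to atoms).
* **Grad-CAM** — channel weights `alpha_c = mean_v d yhat / d h_{v,c}`,
  `score_v = alpha . h_v`, with no ReLU clamp since the benchmark needs
  negative contributions.  With mean pooling this is CAM scaled by `1/N`.
* **GradInput** — `mean_f(d yhat/d x_v * x_v)`.
* **Integrated Gradients** — midpoint-rule path integral from an all-zero
  feature baseline, 128 steps by default, evaluated in one packed batch.
  For ReLU models the path derivative is piecewise constant; cells whose
  ReLU activation pattern changes between their edges are re-integrated with
  16 interior points, improving the completeness identity
  `sum(raw) = yhat(x) - yhat(0)` from O(1/steps) to O(1/(steps*refine))
  (observed residuals are below 1e-4 relative).
* **Node masking** — `yhat(x) - yhat(x with atom v's feature row zeroed)`,
  N+1 forward passes.
* **RF atom masking** — for the random-forest comparator (ECFP4 bits,
  500 trees): each atom in turn is replaced by xenon, an atom type absent
  from the benchmark chemistry, the fingerprint is recomputed and the score
  is the prediction drop.  If the sentinel molecule cannot be sanitised the
  fallback drops the fingerprint bits whose environments contain the atom.
* **Random** — i.i.d. standard-normal scores; the chance baseline.

## Metrics

* **Global direction** (per pair): 1 if the difference of mean attributions
  over the two uncommon-atom sets has the same sign as the activity
  difference.  Signs use a tolerance of 1e-12; an exact-zero difference
  matches neither sign and counts as a failure, the conservative choice.
* **Color agreement** (per compound): fraction of uncommon atoms whose
  attribution sign matches the +/-1 ground truth; undefined on common atoms,
  which is why evaluation is restricted to the uncommon set.
* **RMSE / Pearson r** on test-compound potencies; Pearson r is reported as
  missing for zero-variance inputs.
* Aggregation over targets reports simple and weighted means plus standard
  deviations; weights default to test-pair counts per target (test-compound
  counts are available as an option, since both conventions appear in
  practice).  Results can be stratified by cumulative minimum-MCS thresholds
  {0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.95}, by single vs multiple substitution
  sites (connected components of the uncommon subgraph), and by per-target
  scaffold diversity (distinct Bemis-Murcko scaffolds / compounds).

## Synthetic benchmark

Real activity-cliff benchmarks require large curated bioactivity collections;
the generator instead plants a known structure so every pipeline stage can be
verified exactly.

Each target is one congeneric series: an asymmetric heteroaromatic scaffold
(five variants, 11-16 heavy atoms) with three marked attachment sites.  Each
compound draws one substituent per site from an 18-fragment
medicinal-chemistry library (alkyls, halogens, ethers, amines, nitrile, CF3,
thioether); its activity is `base + sum of per-(site, fragment) weights +
Normal(0, noise_sd)`.  Weights are drawn once per target and standardised
within each site to mean zero and standard deviation 0.5, so every target
carries the same substituent-effect spread (a target's difficulty does not
hinge on a lucky draw of dominant weights) and pIC50 values stay inside
4-10 with ample >= 1 log-unit cliffs.  Defaults: 5 targets x 80 compounds,
noise_sd 0.1.

Three generator properties matter for verification:

1. *Exact pair enumeration.*  The pairwise MCS of two analogs is the scaffold
   plus, per site, the largest common attachment-rooted subtree of the two
   fragments.  Those overlap sizes are computed by brute force on the
   fragment trees, so the set of qualifying pairs (and every filter count
   downstream) can be enumerated independently from the truth table; a test
   asserts the FMCS sizes agree.  This relies on the scaffolds being
   asymmetric (no automorphism maps one site to another) and on complete-ring
   MCS matching (no partial-ring shortcuts), both verified empirically.
2. *Exact coloring on single-site cliffs.*  With zero noise, the +/-1
   coloring produced by the pairing stage agrees with the sign of the planted
   weight difference for every pair differing at a single site.
3. *Calibrated difficulty.*  The library is large relative to the series, so
   each (site, fragment) effect is observed only a handful of times in a
   training set — the low-data regime of real lead optimization.  This keeps
   baseline attribution performance below ceiling, which is the regime the
   benchmark needs to discriminate between training objectives: with small
   substituent vocabularies the task saturates (every method scores near
   1.0) and comparisons between losses are meaningless.  Even so, per-target
   direction scores rest on a few dozen test pairs each, so per-target
   comparisons between losses remain coarsely quantised; averaged
   comparisons across targets are the stable summary.

What the generator does *not* emulate: real BindingDB-scale chemistry
(scaffold diversity within a target, assay heterogeneity, non-additive SAR,
stereochemistry).  Passing results here show the pipeline is correct and that
the UCN loss recovers planted substituent responsibility under additive,
low-data conditions; they are not evidence about any particular real target
class.

## Study sizes and numerical choices

The default end-to-end benchmark (5 targets x 80 compounds; GNN with
hidden dimension 32, 2 message passes, 100 epochs, Adam 1e-3; five GNN
attribution methods; RF with 500 trees; random baseline) was chosen so a full
three-loss grid completes in minutes on one CPU core.  MCS calls time out at
10 s per pair (timed-out pairs are dropped with a warning; none occur on the
synthetic chemistry).  Float64 is used throughout; ReLU subgradient at zero
is 0; sign tolerances are 1e-12; Adam uses beta = (0.9, 0.999), eps = 1e-8.
Checkpoints are JSON with a schema hash over the featurization dimensions,
and loading fails loudly on a mismatch.

## Known limitations

* The exact atom/bond feature sets and architecture hyperparameters of
  published GNN-QSAR models vary; the ones here are reasonable defaults, and
  conclusions should be read per-configuration.
* CAM on the default two-layer head is a local linearisation; it is exact
  only for a linear head (the identity is tested in that regime).
* The MCS-based ground truth inherits the usual caveat that colors assigned
  to a compound depend on its partner; the global-direction metric is the
  primary, partner-stable criterion, mirroring standard practice.
* Brute-force MCS verification covers acyclic random molecules exhaustively
  plus curated ring cases; ring-system MCS correctness otherwise rests on
  RDKit's FMCS.
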