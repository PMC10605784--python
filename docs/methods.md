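# Methods

## Problem and approach

Lead optimization in drug discovery asks a *comparative* question: will
modifying this molecule improve its ADMET profile? `deltamol` frames that
question directly. Given a table of molecules with one measured property
(typically log-transformed, e.g. LogS solubility or Log CLr renal
clearance), it builds every ordered pair of molecules and learns to predict
the property *difference* Δ(x, y) = v(y) − v(x), instead of predicting
absolute values v(x) and subtracting.

Two model philosophies are compared behind one prediction contract:

* **Traditional (predict-then-subtract).** A single-molecule regressor
  f(x) ≈ v(x); the pair prediction is f(y) − f(x). Implemented as a
  500-tree random forest or a LightGBM regressor on Morgan fingerprints
  (radius 2, 2048 bits), and as a single D-MPNN graph encoder with a
  feed-forward head.
* **Delta (direct pairwise).** A regressor g(x, y) ≈ v(y) − v(x) trained on
  ordered pairs. Implemented as LightGBM on concatenated pair fingerprints
  (4096 bits, order-sensitive), and as the two-encoder graph model: each
  molecule passes through its own D-MPNN, the two latents are concatenated,
  and linear feed-forward layers emit the difference.

Pairing expands n molecules into n² training points, which is what lets
deep models train effectively on the sub-1,500-molecule datasets common in
ADMET work; it also cancels any constant systematic error in an assay,
because an offset added to every value vanishes from every difference.

## Leakage firewall

Pairs share molecules, so pair-level random splits leak: a test pair whose
left molecule appeared in training pairs is partially memorized. All
cross-validation here therefore splits *molecules* into folds first
(`make_fold_plan`) and cross-merges into exhaustive ordered pairs within
each side afterwards (`pairs_for_fold`). `leakage_check` asserts the
resulting molecule sets are disjoint. Default protocol is 5 repeats of
10-fold CV; fold shuffles derive per-repeat seeds from one master seed via
`SeedSequence([seed, repeat])` so any fold is reconstructible in isolation.

Sign convention: `true_delta = value(second) − value(first)`, everywhere.
Self-pairs (x, x) are included by default in both train and test pair sets —
they anchor the zero of the difference scale — and both orientations of
every unordered pair are kept, so metrics count each unordered pair twice;
both toggles are exposed.

## Invariant diagnostics

A perfect difference predictor satisfies three identities: g(x, x) = 0,
g(x, y) = −g(y, x), and g(x, y) + g(y, z) = g(x, z). Predict-then-subtract
models satisfy all three *exactly* because subtraction telescopes — the
test suite asserts this to machine precision. Direct delta models only
approximate them, and the residuals are label-free quality measures:

* `self_difference_mae` — mean |g(x, x)|,
* `swap_correlation` — Pearson r between g(a, b) and g(b, a) over
  unordered pairs (self-pairs excluded; −1 is ideal),
* `additivity_mae` — mean |g(x, y) + g(y, z) − g(x, z)| over ordered
  triplets, enumerated exhaustively up to `max_triplets` (default 100,000)
  and uniformly sampled with a recorded seed beyond that.

`anticipate_performance` correlates an invariant residual with a CV metric
across datasets; on the synthetic noise sweep the self-pair residual tracks
CV MAE with strongly positive rank correlation, so the diagnostics can
triage datasets before any labels are spent on validation. Diagnostics
default to held-out (test-fold) molecules; train-fold evaluation is a
caller choice.

## Models: parameters that matter

| parameter | default | notes |
|---|---|---|
| forest `n_trees` | 500 | sklearn RandomForestRegressor, otherwise defaults |
| GBM `subsample_freq` | 0.1 | LightGBM `subsample=0.1, subsample_freq=1` (bag 10% of rows each iteration) |
| GBM `min_child_samples` | 5 below 300 molecules | small-dataset exception; LightGBM default 20 otherwise |
| fingerprint | radius 2, 2048 bits | binary Morgan, concatenated to 4096 for pairs |
| graph `hidden_size` | 64 | desk-scale; larger values are config-exposed |
| graph `depth` | 3 | message-passing steps |
| graph `aggregation` | sum | atom-readout; mean available |
| graph epochs | 5 (delta) / 50 (traditional) | the delta task converges fast because pairing multiplies data |
| graph optimizer | Adam, lr 5e-3, batch 256 | MSE on SD-standardized targets |
| `encoder_sharing` | off | separate weights per pair position; sharing enforces a symmetry prior |

The D-MPNN is implemented directly on NumPy arrays with hand-derived
backpropagation and an Adam optimizer, which keeps training bit-reproducible
for a given seed on one CPU. Messages live on directed bonds; each step is
`h_b = relu(h0_b + (Σ incoming − reverse) W_h)` with the initial-state skip
connection; atom states are the sum of incoming bond states passed through
one more ReLU layer. Atom features are one-hots of element (C, N, O, F, P,
S, Cl, Br, I, other), degree 0–5, formal charge (−1, 0, +1, other),
aromaticity, and hybridization (SP, SP2, SP3, other); bond features are
bond-type one-hot (single, double, triple, aromatic), conjugation, and
ring membership. Bondless molecules (methane) skip message passing and
read out atom features alone. Training amortizes the quadratic pair count
by encoding each distinct molecule once per batch and back-propagating the
summed per-molecule latent gradients. The feed-forward head has one hidden
layer (default width 64); width/depth are config-exposed.

Analytic gradients are verified against central differences in the test
suite. One subtlety: with zero-initialized biases, directed bonds whose
source atom has degree one carry an exactly-zero message, which parks
pre-activations exactly on the ReLU kink; the gradient tests randomize
biases first because numeric differentiation is undefined there (the
analytic pass uses the standard z > 0 subgradient).

## Curation

Raw tables (CSV, `smiles`/`value` columns, names configurable) pass
through ordered filters — qualifier values ("<", ">") removed, non-numeric
values removed, unparseable SMILES removed — with per-rule counts in a
provenance log. Structures are canonicalized with RDKit; within-dataset
duplicate structures keep the first occurrence (logged), since duplicates
would put identical molecules on both sides of a fold boundary. Value
transforms are log10 with an optional pre-offset (e.g. +1 where zero
readouts occur) or identity (where negative values prohibit the log, as
for hydration free energies). Manual structure corrections are supported
as an explicit user-supplied substitution table, never automated.
External test sets are deduplicated against training data by Morgan/Tanimoto
similarity at threshold 1.0 (exact structural matches).

## Synthetic benchmark generator

The generator emulates the *shape* of ADMET benchmark tables — hundreds to
~1,300 molecules, a continuous log-scale property, multiple Bemis–Murcko
scaffolds — with a fully known ground truth. Molecules are ring cores
(benzene, pyridine, cyclohexane, furan, thiophene, naphthalene) decorated
at up to three sites with substituents (halogens, methyl/ethyl, hydroxy,
amino, nitro, methoxy, carboxyl, nitrile; ~10⁴ distinct structures). The
noiseless value is the core's base value plus the sum of substituent
contributions — an exactly additive structure–property landscape. Observed
values add Gaussian noise on the log-like scale (the natural noise model
for log-transformed assays) and an optional constant assay offset.

Values are snapped to a dyadic 2⁻²⁰ grid (~10⁻⁶, far below assay noise) so
that adding a constant offset cancels *bit-exactly* in every pair
difference rather than merely to rounding error; "offset invisibility" is
then a byte-identity of pair tables, not a tolerance.

What passing on synthetic data does and does not show: the landscape is
additive by construction, has no activity cliffs, no inter-assay batch
structure, and a narrow, clean chemistry. Recovery there validates the
pipeline's correctness — pairing, features, training, evaluation — not the
expected accuracy on real ADMET data, where the published benchmark
experiments with externally downloaded tables are the relevant evidence.

## Evaluation choices

* Metrics: Pearson r, MAE, RMSE, and sign accuracy (fraction of pairs with
  the correct difference direction, computed over pairs with nonzero true
  difference; self-pairs still count toward MAE/RMSE).
* Aggregation: each repeat is scored over its pooled test-pair predictions
  across folds; summaries report mean ± SD over repeats, and paired model
  comparisons (paired t-test, with Wilcoxon and a normality check offered,
  never auto-selected) operate on the repeat-level values.
* Zero-variance prediction vectors make Pearson r undefined; a NaN
  sentinel with a warning is returned rather than an exception.
* Bemis–Murcko scaffold of an acyclic molecule is the empty string and two
  empty scaffolds compare as "same".
* Decile stratification of |Δ| uses a stable sort on (|Δ|, index), so
  group sizes are exactly ⌊0.1·n⌋ under ties.

## Problem sizes used in the automated checks

The test suite and the acceptance script run entirely on generated data:
300 molecules for the leakage and delta-recovery checks (one fold of a
10-fold plan, i.e. 72,900 training pairs), 200 molecules for the graph
delta model, 100–150 molecules for CV comparisons and the six-level noise
sweep. These sizes sit at the small end of the benchmark range by design —
they exercise every code path at full fidelity while keeping a complete
run on one CPU in a few minutes.

## Known limitations

* The graph models are NumPy implementations sized for datasets of a few
  hundred molecules; no GPU path, no minibatch parallelism.
* No uncertainty estimation, hyperparameter search, or classification-mode
  pair models.
* Matched-molecular-pair analysis and free-energy methods are different
  tools for the same comparative question and are out of scope.
* Within-dataset duplicate handling is keep-first; averaging replicate
  measurements is left to upstream curation.
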