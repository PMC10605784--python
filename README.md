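# deltamol

Pairwise ("delta") machine learning for molecular property differences.

Lead optimization rarely asks "what is this molecule's solubility?" — it
asks "will this modification *improve* solubility?" `deltamol` answers the
comparative question directly: it turns a molecule/property table into
every ordered pair of molecules and trains regressors on the difference

    Δ(x, y) = v(y) − v(x)

comparing them against the traditional route of predicting absolute values
and subtracting. It is aimed at ADMET-style datasets of a few hundred to a
couple of thousand molecules, where the n² pair expansion is what makes
deep models competitive at all.

The package provides:

* **Curation** (`deltamol.chemdata`) — CSV in, canonical deduplicated
  dataset + per-rule provenance log out; qualifier removal, log10 / identity
  transforms, Tanimoto dedup against external references.
* **Leak-free pairing** (`deltamol.pairing`) — molecules are split into CV
  folds *first* and exhaustively cross-merged into ordered pairs *within*
  each side afterwards, so no molecule contributes pairs to both train and
  test. Default protocol: 5 × 10-fold.
* **Models** (`deltamol.models`) — predict-then-subtract baselines
  (500-tree random forest, LightGBM, single graph encoder) and direct delta
  models (LightGBM on concatenated 2×2048-bit Morgan fingerprints; a
  two-encoder directed message passing neural network whose latents are
  concatenated into a feed-forward head). The graph stack is a NumPy
  implementation with hand-derived backpropagation — deterministic per seed
  on one CPU.
* **Invariant diagnostics** (`deltamol.invariants`) — a perfect difference
  model obeys Δ(x,x) = 0, Δ(x,y) = −Δ(y,x) and Δ(x,y)+Δ(y,z) = Δ(x,z).
  Subtraction-based models satisfy these exactly (they telescope); for
  direct delta models the residuals are label-free quality scores that
  anticipate cross-validation performance.
* **Evaluation** (`deltamol.evaluation`) — Pearson r / MAE / RMSE / sign
  accuracy, repeat-level mean ± SD summaries, scaffold-hop stratification,
  difference-magnitude deciles, similarity analyses, paired model tests.
* **Synthetic benchmarks** (`deltamol.synthdata`) — scaffold + substituent
  libraries with an exactly additive ground truth, tunable Gaussian noise
  and a constant assay offset that provably cancels in every pair.

## Worked example

```python
from deltamol import (GeneratorConfig, generate_library, make_fold_plan,
                      ModelConfig, run_cv, summarize_cv, evaluate_invariants,
                      train_model)
from deltamol.pairing import cross_merge

# 120 molecules over six ring scaffolds, additive truth + mild noise
synth = generate_library(GeneratorConfig(n_molecules=120, noise_sd=0.15, seed=7))

plan = make_fold_plan(synth.records, n_folds=5, n_repeats=2, seed=1)
preds = {}
reports = run_cv(synth.dataset,
                 [ModelConfig(family="gbm_delta", seed=1),
                  ModelConfig(family="forest_traditional", seed=1)],
                 plan, predictions_out=preds)
for s in summarize_cv(reports, preds):
    print(f"{s.family:20s} r = {s.pearson_r_mean:.3f} +/- {s.pearson_r_sd:.3f}   "
          f"MAE = {s.mae_mean:.3f} +/- {s.mae_sd:.3f}   sign acc = {s.sign_accuracy_mean:.3f}")

model = train_model(ModelConfig(family="gbm_delta", seed=1),
                    synth.records, cross_merge(synth.records))
rep = evaluate_invariants(model, synth.records[:30], max_triplets=10000, seed=0)
print(f"self-pair MAE = {rep.self_mae:.3f}   swap r = {rep.swap_r:.3f}   "
      f"additivity MAE = {rep.additivity_mae:.3f}")
```

prints

```
forest_traditional   r = 0.847 +/- 0.000   MAE = 0.685 +/- 0.004   sign acc = 0.845
gbm_delta            r = 0.886 +/- 0.007   MAE = 0.578 +/- 0.011   sign acc = 0.859
self-pair MAE = 0.102   swap r = -0.996   additivity MAE = 0.173
```

Reading the output: each row is a model family scored on held-out ordered
pairs, mean ± SD over the two CV repeats. The direct pair model (`gbm_delta`)
beats predict-then-subtract on correlation and MAE, and gets the *direction*
of the property change right for 86% of pairs. The invariant block is
label-free: the trained delta model predicts near-zero change for identical
molecules (0.102 on a property spanning several log units), near-perfect
anti-symmetry under input swapping (−0.996), and a small triplet-additivity
residual — a subtraction-based model scores exactly 0 / −1 / 0 on these by
construction.

The same pipeline runs from the shell:

```bash
deltamol generate --n-molecules 300 --noise-sd 0.1 --seed 7 --out run/gen
deltamol cv run/gen/dataset.csv --families gbm_delta,forest_traditional \
         --folds 10 --repeats 5 --seed 1 --out run/cv
deltamol report run/cv --out run/report
```

Every subcommand writes a JSON run manifest (config, seeds, input digests)
next to its outputs.

### Using your own benchmark tables

Any CSV with `smiles` and `value` columns works: `deltamol curate` applies
the qualifier/validity filters and the log10 transform (use
`--transform identity` for properties with negative values, and
`--pre-offset 1` where zero readouts occur), then `deltamol cv` produces
the mean ± SD report. Absolute numbers on public ADMET benchmarks depend
on the dataset version you download, so none are asserted by the test
suite.

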