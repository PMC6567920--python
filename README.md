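# pcdcea

Decision-analytic cost-effectiveness modelling of multi-test diagnostic
algorithms for primary ciliary dyskinesia (PCD).

A yearly referral cohort is pushed through three diagnostic algorithms —
nasal nitric oxide followed by transmission electron microscopy
(`nNO+TEM`), nasal nitric oxide followed by high-speed video microscopy
(`nNO+HSVM`), and parallel nNO/HSVM with TEM arbitration of discordant
results (`nNO/HSVM+TEM`) — plus a do-nothing baseline. The package provides:

- **Parameter registry** (`pcdcea.params`, `pcdcea.distributions`):
  a validated schema for every model input (beta/gamma/normal/lognormal/point
  distributions fitted to best estimate + 95 % interval) and Latin-Hypercube
  sampling with exact stratification and seed-reproducible draws.
- **Decision model** (`pcdcea.decision`): Bayes-consistent expected-value
  classification of the cohort per algorithm (TP/FP/TN/FN), net
  sensitivity/specificity/PPV/NPV, and expected per-test volumes.
- **Micro-costing** (`pcdcea.costing`): annualized capital + maintenance
  fixed costs, per-test variable costs (consumables, operator time,
  physician sampling time) scaled by test volumes, with shared-brushing
  handling in the parallel arm.
- **PSA engine** (`pcdcea.psa`): vectorized propagation of parameter draws
  to an iteration-level (cost, effect) table per strategy with common random
  numbers across strategies.
- **CEA statistics** (`pcdcea.cea`): CER/ICER (both ratio-of-means and
  mean-of-per-iteration-ratios estimators), simple/extended dominance
  frontier, cost-effectiveness acceptability curves, and one-way tornado
  sensitivity analysis.
- **Microsimulation oracle** (`pcdcea.microsim`): patient-level Bernoulli
  simulation of every pathway, used as the independent cross-check of the
  analytic model.

## Command line

All analyses run off a YAML parameter config; omit `--config` to use the
shipped defaults (`src/pcdcea/data/default_params.yaml`). Every stochastic
command requires an explicit `--seed` and writes a JSON manifest for
reproducibility.

```sh
pcdcea validate                                   # schema + distribution fits
pcdcea run  --out out/det                         # deterministic tables
pcdcea psa  --seed 1 --out out/psa                # 3000-iteration PSA
pcdcea ceac --seed 1 --out out/ceac               # acceptability curve CSV
pcdcea tornado --out out/tornado                  # one-way sensitivity CSV
pcdcea microsim --seed 1 --n 10000 --out out/sim  # synthetic patient cohort
```

## Notes on reproducibility scope

Two published quantities are deliberately *not* reproduced because their
inputs were never published: the absolute classification counts of the
confirmatory stages (they depend on unpublished post-positive-screen
conditional accuracies — the config exposes optional
`conditional_sensitivity` / `conditional_specificity` blocks to supply them)
and the absolute aggregate annual costs (the full cost build-up appendix is
unavailable; this package implements a transparent bottom-up formula instead
and exposes an `overhead_per_patient` calibration term, default 0). The
qualitative results — dominance structure and frontier ordering — are
reproduced and tested.
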