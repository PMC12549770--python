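# rlwmlba

A tested, reusable pipeline for analysing instrumental learning with a joint
reinforcement-learning / working-memory / choice-dynamics model:

- **`rlwmlba.task`** — generator for the three-response learning task:
  a training block plus ten learning blocks (468 trials) with set sizes 2-5,
  pseudo-randomized interleaving with bounded, approximately uniform delays,
  deterministic feedback, and derived trial-level task factors (iteration,
  delay, reward history).
- **`rlwmlba.model`** — the generative model: delta-rule value learning with
  a positive-feedback bias, a fast decaying capacity-limited working-memory
  module, policy mixing, entropy-scaled drift rates, and a three-accumulator
  linear ballistic accumulator for joint choice/RT likelihood and sampling.
  A numba fast path (`rlwmlba._fast`) mirrors the reference implementation.
- **`rlwmlba.inference`** — hierarchical Bayesian MAP estimation
  (non-centered subject deviations, normal-CDF / exponential / shifted
  inverse-logit transforms, multi-start quasi-Newton with a structured
  numerical gradient), posterior predictive checks, and a parameter-recovery
  harness.
- **`rlwmlba.cohort`** — synthetic cohorts: adolescent-like covariates
  (truncated-normal age, 72% female, right-skewed symptom scales), latent
  parameters with configurable planted covariate effects, and simulated
  behavior.
- **`rlwmlba.associations`** — Bayesian linear regression with N(0,1)
  coefficient priors, Savage-Dickey BF01 with the conventional evidence
  bands, a trial-level mixed logistic model of accuracy, and item-level
  cumulative-logit ordinal regression with subject intercepts.
- **`rlwmlba.prediction`** — repeated (100x) stratified 80/20 + 10-fold-CV
  ridge regression comparing model parameters vs behavioral summaries as
  predictors of subject-level targets.
- **`rlwmlba.io`** — CSV/JSON/YAML readers and writers with schema
  validation, configuration with guarded fixed constants, and run manifests.

## CLI

All commands accept `--seed`, `--config` (JSON/YAML), and `--log-level`,
and write a JSON run manifest next to their outputs.

```sh
rlwmlba simulate-task  --seed 1 --out trials.csv --n-subjects 5
rlwmlba simulate-cohort --seed 1 --n 50 \
    --effects '[["age", "A", -1.13]]' --residual-sd 0.5 --out cohort/
rlwmlba fit       --trials cohort/trials.csv --out fit/ --restarts 4 --seed 1
rlwmlba recover   --n-subjects 20 --seed 1 --out recovery/
rlwmlba ppc       --fit fit/ --reps 10 --seed 1 --out ppc.csv
rlwmlba associate --covariates cohort/covariates.csv \
    --params fit/fitted_params.csv --model linear --target age \
    --seed 1 --out assoc.json
rlwmlba predict   --features features.csv --target age --seed 1 --out pred.json
```

## Conventions

Trial tables are UTF-8 comma-separated CSV with a header row; empty fields
are missing values (non-responses, undefined first-presentation delays).
Actions and trial indices are 0-based. Fixed model constants (softmax
inverse temperature 50, non-decision time 0.15 s, unit drift-rate SD) are
surfaced read-only in the configuration and require an explicit override
flag to change.
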