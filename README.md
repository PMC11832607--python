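# crimpsim

Monte Carlo comparison of multiple-imputation strategies for missing
covariates when the analysis model is a **cause-specific Cox model with
competing risks**.

Applied survival analyses routinely face both problems at once: several
mutually exclusive event types (e.g., cardiovascular death, cancer
death, other death) and covariates that are missing for a large share of
records.  Multiple imputation requires the analysis-model outcome inside
each imputation model, but with K competing event types there are K
cause-specific cumulative hazard functions H_k(t) and it is not obvious
which of them belong in the imputation models — or whether one should
instead use an imputation scheme that is *compatible* with the
substantive model by construction.  `crimpsim` implements and compares,
under a clinically realistic simulation design:

- **`mice_all`** — MICE with predictive mean matching; imputation models
  use the 9 other covariates, all three Nelson–Aalen cause-specific
  cumulative hazards Ĥ_k(T) with their event indicators, and all
  hazard × covariate interactions;
- **`mice_primary`** — as above, but only the primary-cause
  (cardiovascular) hazard and indicator;
- **`smcfcs`** — substantive-model-compatible FCS: rejection sampling
  against Π_k exp(x'β_k)^{1(D=k)} exp(−H0_k(T) e^{x'β_k}), compatible
  with all three cause-specific hazard models simultaneously;
- **`complete_case`** and a **`no_missing`** reference arm.

Data are simulated from three constant cause-specific hazards
λ_k·exp(x'β_k) over 10 covariates (published AMI-cohort log-hazard
ratios as defaults), with event time T = −log(u)/Σ_k λ_k e^{x'β_k} and
multinomial event type; censoring is calibrated by bisection to 25%;
missingness is a 67-pattern MAR design calibrated to a target
incomplete-record share.  Estimates are pooled with Rubin's rules and
Barnard–Rubin degrees of freedom, and methods are scored by relative
bias and empirical 95% CI coverage against super-population truth.
See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from crimpsim import (ScenarioConfig, default_covariate_model,
                      default_coefficient_set, build_superpopulation,
                      ampute, default_pattern_library, smcfcs, pool_stack)

cfg = ScenarioConfig(n_super=20_000, p_missing=0.3, seed=42)
pop, truth = build_superpopulation(cfg, default_covariate_model(),
                                   default_coefficient_set())
print(f"censored: {(pop.event == 0).mean():.3f}")
amp = ampute(pop, lib=default_pattern_library(), p_missing=0.3,
             seed=cfg.seed)
print(f"incomplete records: {amp.iloc[:, :10].isna().any(axis=1).mean():.3f}")

sample = amp.sample(1000, random_state=1).reset_index(drop=True)
stack = smcfcs(sample, m=5, seed=7)                 # 5 completed datasets
pooled = pool_stack(stack)                          # Rubin's rules
row = pooled[(pooled.cause == 1) & (pooled.variable == "cholesterol")].iloc[0]
true = truth.beta_true_cvd[4]
print(f"cholesterol (cardiovascular): {row.qbar:+.3f} "
      f"[{row.ci_low:+.3f}, {row.ci_high:+.3f}], true {true:+.3f}")
```

prints

```
censored: 0.251
incomplete records: 0.301
cholesterol (cardiovascular): -0.114 [-0.257, +0.028], true -0.067
```

The censoring calibration lands on the 25% target, the amputer hits the
requested 30% incomplete-record share, and the pooled SMCFCS estimate of
the cardiovascular cholesterol log-hazard ratio covers the
super-population truth (−0.067) with a confidence interval widened by
the between-imputation variance of a variable that is missing for most
incomplete records.

## Command line

```bash
crimpsim simulate --n 100000 --seed 1 --out pop.csv
crimpsim ampute   --data pop.csv --p-missing 0.5 --seed 1 --out amp.csv
crimpsim impute   --data sample.csv --method smcfcs -m 10 --seed 1 --out-prefix imp
crimpsim analyze  --stack-prefix imp -m 10 --out pooled.csv
crimpsim grid     --seed 1 --scaled-down --out results/grid
```

`grid` runs the full 30-scenario factorial design (5 baseline-rate
triplets × 6 missingness levels), writes per-scenario pooled results and
a combined `metrics.csv`, and resumes past completed scenarios.

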