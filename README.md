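# priorityrank

Empirical-Bayes joint ranking of variables by statistical significance
**and** effect size.

Large-scale association studies usually rank findings by p value alone, which
favours well-measured small effects over poorly-measured large ones.
`priorityrank` estimates, for every variable, the **priorityFDR**: the
posterior probability that the variable is either null *or* out-ranked in
true effect size by a randomly chosen non-null variable,

```
priorityFDR_i = FDR_i + effect_priority_i * (1 - FDR_i)
```

so a variable ranks highly only when it is both likely real and likely large.
The package provides:

- **Two-group model** (`priorityrank.density`): a point-null standard normal
  plus a flexible non-null density fitted to the histogram of Z-scores by
  Poisson regression on a polynomial basis (Lindsey's method), with a
  conservative null-proportion estimate and local / tail-area FDRs.
- **Prior splitting and pair models** (`priorityrank.priorsplit`): the
  non-null density is decomposed into sign-constrained components; models of
  standardized pairwise effect *differences* and *sums* turn posterior sign
  probabilities into the probability that one variable's true effect exceeds
  another's, averaged by Monte Carlo into the per-variable effect priority.
- **Simulation benchmark** (`priorityrank.simulate`): a 20-component mixture
  generator of realistic genetic architectures (normal or Laplace effect
  families, optional LD-block correlation, optional power boost),
  ground-truth error functionals and rank-recovery metrics.
- **GWAS post-processing** (`priorityrank.gwas`): inverse-variance
  meta-analysis, TDT odds ratios with continuity correction, genomic-control
  lambda, greedy LD clumping with an artifact-excluding singleton rule,
  red/blue/grey signal prioritisation and exact enrichment tests.
- **CLI** (`priorityrank`): `estimate`, `simulate`, `evaluate`, `clump`,
  `group`, `meta`, `fixture`.

## Quick start (Python)

```python
import numpy as np
from priorityrank import EffectsTable, draw_architecture, draw_dataset, estimate

# a synthetic half-null dataset of 2000 log odds-ratio estimates
arch = draw_architecture(11)
data = draw_dataset(arch, n=2000, seed=12)

effects = EffectsTable.from_frame(data.to_frame())
result = estimate(effects, seed=13)

print(f"pi0 = {result.pi0:.3f}")
top = result.table.nsmallest(3, "pfdr_tail")[
    ["id", "beta", "se", "fdr_tail", "pfdr_tail"]]
print(top.to_string(index=False))
```

typical output:

```
pi0 = 0.977
   id     beta       se     fdr_tail  pfdr_tail
v1376 0.340416 0.081717 4.569041e-03   0.158266
 v682 0.241696 0.037009 4.706221e-08   0.165623
 v417 0.244143 0.041814 2.757408e-06   0.172078
```

The result table also carries local estimates (`fdr_local`, `pfdr_local`,
`effect_priority`) and the inclusive variant `pfdr_inc` / `pfdr_inc_tail`,
which ranks against *all* variables (nulls included) and is the quantity used
by the rank-recovery benchmark.

## Quick start (CLI)

```bash
priorityrank simulate --seed 2 --n 2000 --out run/
priorityrank estimate --in run/dataset.tsv --out run/estimates.tsv --seed 3
priorityrank evaluate --data run/dataset.tsv --estimates run/estimates.tsv \
    --out run/eval.json
```

`eval.json` reports the mean true FDR / effect-priority / priorityFDR errors
among the variables selected at each threshold of the alpha grid; with a
calibrated estimator these stay at or below the diagonal.

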