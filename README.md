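# regenddr

Quantification pipeline for DNA-damage-response (DDR) readouts in
regenerating axolotl limbs. When a salamander limb is amputated, a
blastema of proliferating progenitors re-enters the cell cycle; studies of
this process quantify DDR activity from several derived measurement
tables, and `regenddr` implements that downstream arithmetic as a tested,
reusable library:

- **Timecourse regulation calls** on gene × days-post-amputation (dpa)
  expression matrices. RNA-seq rule: gene g is *up* if
  `x_g(t) ≥ 2·x_g(0)` at any regeneration timepoint t, *down* if
  `x_g(t) ≤ x_g(0)/2`, *mixed* if both (at different timepoints), else
  *none*. Microarray rule: strict `x_g(t) > μ₀ ± 1·σ₀` thresholds around
  the intact mean.
- **Composite DDR score** of a curated gene set:
  `S(t) = mean_g [ x_g(t) / x_g(0) ]`, identically 1 at 0 dpa; genes
  silent in intact tissue are excluded.
- **Anchor co-expression screen**: Pearson r of every gene against an
  anchor gene's profile; genes with `R² > 0.8` split by OLS slope sign
  into positively/negatively associated sets.
- **γ-H2AX focus densities**: per-nucleus density = foci/area, binned
  Zero / Low (<10·10⁶) / Med (<20·10⁶) / High, with stratified
  percent-in-bin tables and percent-positive arithmetic.
- **H2AX phospho-state arithmetic**: per-lane normalization and the
  derived mono-pY142 level, `rel pY142 = rel pS139/Y142 − rel γ-H2AX`.
- **Skeletal pattern completeness** (exactly 4 digits, 9
  phalanges/metacarpals, 8 carpals), relative zeugopod length, and
  comet-assay stage distributions.
- **Exact r×c contingency test** by full enumeration of
  margin-preserving tables under the multivariate hypergeometric law
  (two-sided probability-ordering p-value).
- **Synthetic-data generator** producing all of the above inputs with
  planted ground truth, so every stage is verifiable without external
  data.

qPCR standard-curve quantification, volcano-cutoff gene selection and
line-profile peak extraction round out the toolkit. See
[docs/methods.md](docs/methods.md) for the full model description and
conventions.

## Worked example

```python
import numpy as np
from regenddr import (SimulationConfig, generate_timecourse,
                      classify_expression_set, summarize_categories)

cfg = SimulationConfig(seed=42, n_genes=200, noise_cv=0.1)
expr, truth = generate_timecourse(cfg)
calls = classify_expression_set(expr)
for category, (count, frac) in summarize_categories(calls).items():
    print(f"{category:>5}: {count:4d} genes ({100*frac:.1f}%)")
acc = np.mean([c.category == truth.gene_regulation[c.gene_id] for c in calls])
print(f"planted-label recovery: {100*acc:.1f}%")
```

prints

```
   up:   50 genes (25.0%)
 down:   50 genes (25.0%)
mixed:   50 genes (25.0%)
 none:   50 genes (25.0%)
planted-label recovery: 100.0%
```

The generator planted 25% of genes in each regulation class; at 10%
multiplicative noise the fold-2 caller recovers every planted label in
this instance. The `examples/` directory has one short script per
capability (regulation calls, the anchor screen, foci binning, phospho
ratios, skeletal scoring + exact test), each printing its numbers with a
note on what they mean.

A thin CLI chains the stages on files:

```sh
regenddr simulate --seed 1 --out results/
regenddr classify --expression results/expression.tsv --out results/
regenddr fisher --table mytable.csv --out results/
```

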