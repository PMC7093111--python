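"""Call timecourse regulation on a synthetic expression matrix.

Generates a 200-gene matrix over the 0-28 dpa grid with planted
up/down/mixed/none classes, classifies every gene with the fold-2 rule,
and compares the calls to the planted truth.
"""

import numpy as np

from regenddr import (
    SimulationConfig,
    classify_expression_set,
    composite_relative_score,
    generate_timecourse,
    summarize_categories,
)

cfg = SimulationConfig(seed=42, n_genes=200, noise_cv=0.1)
expr, truth = generate_timecourse(cfg)
calls = classify_expression_set(expr)

summary = summarize_categories(calls)
for category, (count, frac) in summary.items():
    print(f"{category:>5}: {count:4d} genes ({100 * frac:.1f}%)")

accuracy = np.mean([c.category == truth.gene_regulation[c.gene_id]
                    for c in calls])
print(f"planted-label recovery: {100 * accuracy:.1f}%")

score = composite_relative_score(expr, expr.gene_ids)
print("composite score by dpa:",
      ", ".join(f"{t}:{s:.2f}" for t, s in score.items()))
# The category counts track the planted 25% proportions; the composite
# score is exactly 1 at 0 dpa and reflects the balanced up/down planting
# elsewhere.
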