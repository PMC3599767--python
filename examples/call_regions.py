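"""Call differentially enriched regions on a small simulated experiment.

Builds a 2,000-probe tiling matrix (10 cases vs 10 controls), hides two
methylation differences of known position and size in the case group, runs
the full pipeline (probe-wise regression -> same-sign slope runs ->
permutation-calibrated Cochran's Q -> BH-FDR), and prints the top regions.
"""

import numpy as np
import pandas as pd

import tilemeta as tm

rng = np.random.default_rng(7)
template = tm.make_template(2_000, seed=rng)
matrix = tm.simulate_null_matrix(template, 20, seed=rng)
cases = matrix.sample_ids[10:]
matrix, truth = tm.insert_hidden_dmrs(
    matrix, cases, [tm.DMRSpec(400, 409, effect=1.0), tm.DMRSpec(1200, 1206, effect=0.5)]
)
annot = tm.SampleTable(
    pd.DataFrame({"group": [0] * 10 + [1] * 10},
                 index=pd.Index(matrix.sample_ids, name="sample_id"))
)

ders = tm.call_ders(matrix, annot, "group", B=1000, seed=1)
table = tm.scored_to_frame(ders)

print(f"{len(ders)} candidate regions (maximal same-sign slope runs of >=3 probes)")
print("\nTop 5 by permutation p (ties broken by Q, higher = stronger):")
print(table.head(5).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nHidden truth for comparison:")
for t in truth:
    print(f"  {t.chrom}:{t.start}-{t.end}  {t.n_probes} probes, effect {t.effect}")
print(
    "\nmean_diff/max_diff are case-minus-control group differences in matrix"
    " (M-value) units; p is the add-one permutation p-value of the region's"
    " Q statistic and q_fdr its BH-adjusted value. The two hidden regions"
    " should head the table at the smallest attainable p = 1/(B+1)."
)
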