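"""Score an alignment with the weighted sum-of-pairs fitness (WSPM).

Shows the two ingredients of the fitness: per-column substitution scores
(PAM250, weighted by CLUSTAL W-style pair weights) and affine gap-run
penalties G = g + n*x collected from every row pair's projection.
"""

import numpy as np

from vdga import (
    GapModel,
    build_guide_tree,
    clustalw_weights,
    distance_matrix_dp,
    generate_family,
    load_matrix,
    progressive_align,
    wspm,
)

family = generate_family(seed=2, n=5, length=80)
matrix = load_matrix("pam250")
gaps = GapModel()

tree = build_guide_tree(distance_matrix_dp(family.descendants, matrix, gaps))
weights = clustalw_weights(tree)
alignment = progressive_align(family.descendants, tree, matrix, gaps)
breakdown = wspm(alignment, weights, matrix, gaps)

print(f"sequence weights (mean 1): {np.round(weights.w, 3)}")
print(f"alignment: {alignment.N} rows x {alignment.L} columns")
print(f"substitution part: {breakdown.per_column.sum():.2f} "
      f"(sum of {alignment.L} column scores)")
print(f"gap penalties:     {breakdown.gap_total:.2f}")
print(f"WSPM total:        {breakdown.total:.2f}  "
      "(positive = similarity outweighs the gaps)")
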