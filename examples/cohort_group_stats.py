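"""Group comparison of node-wise c1 maps with familywise correction.

Draws a two-group cohort of per-node features with a known group offset at
five designated nodes, runs the two-tailed pseudo t-test with
maximum-statistics permutation correction, and shows that exactly the
injected nodes are recovered while the rest stay null.
"""

import numpy as np

from critmf import maxstat_permutation, simulate_feature_cohort

effect_nodes = [5, 15, 25, 35, 45]
X, groups = simulate_feature_cohort(
    n_per_group=25, n_nodes=50, effect_nodes=effect_nodes,
    effect_size=0.15, noise_sd=0.1, seed=7,
)
res = maxstat_permutation(X, groups, n_perm=1000, alpha=0.05, seed=7)

flagged = np.where(res.mask)[0]
print(f"injected +0.15 c1 offset at nodes {effect_nodes}")
print(f"familywise |t| threshold (alpha=0.05): {res.threshold:.2f}")
print(f"significant nodes: {flagged.tolist()}")
print(f"their corrected p: {np.round(res.p_corrected[flagged], 4).tolist()}")
print("Max-statistics correction controls the chance of any false positive "
      "across all 50 nodes, so the flagged set can be read as a map.")
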