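"""Cluster-based permutation test on 2D spatial maps.

Builds 20-vs-20 sets of 30 x 30 standard-normal maps with a +1.5 SD effect
in a 6 x 6 block of group 2 (the kind of per-subject space-covered map the
assessment task produces), then runs the two-sample cluster permutation
test: pointwise pooled t, cluster forming at p = 0.01 with >= 2 adjacent
cells, and a max-cluster-mass null from 1000 label shufflings.
"""

from fatiguekit import MapGenConfig, gen_spatial_maps
from fatiguekit.cluster import permutation_test

cfg = MapGenConfig(
    height=30, width=30, n_per_group=20,
    effect_rows=(12, 18), effect_cols=(12, 18), effect_size=1.5,
)
mset = gen_spatial_maps(cfg, seed=4)
result = permutation_test(mset, n_perm=1000, seed=5)

print(f"permutations: {result.n_permutations}   clusters found: {len(result.clusters)}")
for c in result.clusters:
    tag = "positive" if c.sign > 0 else "negative"
    print(f"  {tag} cluster: {c.size:3d} cells, mass {c.mass:7.1f}, p = {c.p_value:.4f}")
# A significant cluster overlapping the injected block (rows/cols 12-17)
# shows the test localises the group difference while controlling the
# family-wise error over all 900 cells.
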