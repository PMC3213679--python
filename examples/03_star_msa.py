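"""Build the per-cluster star multiple alignment.

The pairwise alignments of members against their representative fall out
of the threshold search; reconciling their gaps yields a rectangular
alignment in which no two rows differ by more than twice the cluster
radius.
"""

import itertools

from otuclust import (
    CloudConfig,
    ClusterParams,
    build_star_msa,
    column_distance,
    generate_clouds,
    greedy_cluster,
)

reads, _ = generate_clouds(
    CloudConfig(n_centers=3, cloud_size=6, length_range=(60, 80),
                similarity=0.95, mutation_rate=0.02, seed=11)
)
clustering = greedy_cluster(reads, ClusterParams(similarity=0.95))
cluster = max(clustering.clusters, key=lambda c: len(c.members))
msa = build_star_msa(cluster, reads)

print(f"cluster of {len(msa.rows)} reads, radius bound {cluster.radius_bound}")
print(f"alignment width: {msa.width} columns")
for rid, row in zip(msa.ids, msa.rows):
    print(f"{rid:>12}  {row[:70]}{'...' if msa.width > 70 else ''}")

worst = max(
    column_distance(a, b) for a, b in itertools.combinations(msa.rows, 2)
)
print(f"largest pairwise column distance: {worst} "
      f"(guaranteed <= {2 * cluster.radius_bound})")
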