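"""Assess collection redundancy by greedy centroid clustering.

Sequences join the best existing centroid at or above the identity threshold
or found a new cluster.  The centroid set is a reduced representative
collection; cluster counts at 98%/99% quantify near-duplicate redundancy.
"""

from corediv import SimParams, calls_to_bases, centroid_cluster, cluster_stats, simulate

sim = simulate(SimParams(seed=17))
b = calls_to_bases(sim.genotypes)
for threshold in (0.99, 0.98):
    clusters = centroid_cluster(b, threshold)
    stats = cluster_stats(clusters)
    top = ", ".join(str(s) for s in stats["sizes"][:4])
    print(f"threshold {threshold:.0%}: {stats['n_clusters']} clusters, "
          f"{stats['n_singletons']} singletons, largest sizes [{top}]")
# Fewer clusters at a lower threshold: the representative (centroid) set is
# the smallest subset that still spans the collection at that identity level.
clusters = centroid_cluster(b, 0.99)
clades = {sim.truth.accession_clade[c.centroid_sample_id.rsplit('_', 1)[0]]
          for c in clusters}
print(f"clades represented among 99% centroids: {sorted(clades)}")
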