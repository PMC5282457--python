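"""Cluster a tabulated unique-sequence count table.

Published per-round pool tables list each unique sequence with its counts
(and often percentages) per round; the pipeline accepts these directly,
skipping the read-level stages.  Here a tiny table is built in-memory: one
dominant family (a centroid plus two 1-2-mismatch satellites) and one
distant minor sequence.
"""

from aptapool import UniqueSequence, abundance_trajectory, cluster_pool
from aptapool.clustering import ClusterParams, cluster_table

dominant = "TGGTAGGTAGGTTGGGGTTGGGTTGGTTGGTAGGTAGGTA"
satellite1 = dominant[:5] + "A" + dominant[6:]           # 1 mismatch
satellite2 = "C" + dominant[1:30] + "A" + dominant[31:]  # 2 mismatches
minor = "ACACACACACACACACACACACACACACACACACACACAC"

uniques = [
    UniqueSequence.from_counts(dominant, {"R1": 600, "R2": 1900}),
    UniqueSequence.from_counts(satellite1, {"R1": 30, "R2": 60}),
    UniqueSequence.from_counts(satellite2, {"R1": 10, "R2": 20}),
    UniqueSequence.from_counts(minor, {"R1": 360, "R2": 20}),
]

result = cluster_pool(uniques, ClusterParams(radius=4))
traj = abundance_trajectory(result)

print("cluster assignment (role, distance to centroid, counts):")
print(cluster_table(result).to_string(index=False))
print("\ncluster-inclusive abundance % (centroid + members):")
print(traj.cluster_percent.round(1).to_string())
print("\ncentroid-exact abundance % (centroid's own reads only):")
print(traj.centroid_percent.round(1).to_string())
print(
    "\nThe two satellites fall inside the 4-mismatch radius of the dominant "
    "sequence, so cluster 0 aggregates their reads; the distant minor "
    "sequence founds its own cluster and collapses between rounds."
)
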