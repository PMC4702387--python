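"""Label one cluster by two-level hit filtering and LCA, step by step.

Five core reads returned hit lists over four reference genomes. With a 60 %
occurrence threshold, a taxon must appear in at least 0.6 x 5 = 3 of the
lists to survive the cluster-level filter; here only taxon 102 (present in
four lists) does, so the cluster is labeled with it directly.
"""

from corebin import assignment
from corebin.model import Hit, HitList

G1, G2, G3, G4 = 101, 102, 103, 104


def hitlist(read_id, taxa):
    return HitList(read_id, [Hit(read_id, f"ref{t}", t, 80.0) for t in taxa])


L = [
    hitlist("r1", [G1, G2, G3]),
    hitlist("r2", [G1, G4]),
    hitlist("r3", [G2, G3]),
    hitlist("r4", [G2, G4]),
    hitlist("r5", [G2]),
]

print("occurrence counts f(t):", assignment._occurrences(L))
out = assignment.cluster_level_filter(L, o_max=60)
for before, after in zip(L, out):
    print(f"{before.read_id}: {sorted(before.taxa())} -> {sorted(after.taxa())}")

surviving = set().union(*(hl.taxa() for hl in out))
print(f"surviving taxa: {sorted(surviving)} -> cluster label = LCA = {surviving.pop()}")
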