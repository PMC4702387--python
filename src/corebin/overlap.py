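"""Read-overlap detection by shared l-mers, overlap grouping, and cluster cores.

Two reads overlap when they share at least ``m`` distinct l-mers (``l``
large, default 30) — a cheap proxy for originating from overlapping genome
positions that avoids any assembly. Connected components of the overlap
graph are the initial read groups; after clustering, each cluster is
represented by a *core*: a greedy maximal independent set of its overlap
graph, i.e. a subset of pairwise non-overlapping reads that still tiles most
of the cluster's genomic span. Only core reads are submitted to similarity
search, which is where the method's query reduction comes from.

The graph is built with an inverted l-mer index (l-mer -> read ids), so only
reads co-listed under at least one l-mer are ever compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .model import Core, Read, ReadGroup

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OverlapParams:
    """l-mer length, minimum shared count, and strand handling.

    ``canonical=True`` matches l-mers up to reverse complement, which is what
    the full pipeline needs because shotgun reads come from both strands;
    small hand-built fixtures usually switch it off.
    """

    l: int = 30
    m: int = 5
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.l < 1 or self.m < 1:
            raise ValueError("l and m must be positive")


def lmer_set(sequence: str, l: int, canonical: bool = False) -> set[str]:
    """Distinct l-mers of a sequence; windows containing N are never indexed."""
    if len(sequence) < l:
        return set()
    out: set[str] = set()
    for i in range(len(sequence) - l + 1):
        window = sequence[i : i + l]
        if "N" in window:
            continue
        if canonical:
            window = min(window, reverse_complement(window))
        out.add(window)
    return out


def shared_lmer_count(r: Read, s: Read, l: int, canonical: bool = False) -> int:
    """Number of distinct l-mers occurring in both reads (0 if either is short)."""
    return len(lmer_set(r.sequence, l, canonical) & lmer_set(s.sequence, l, canonical))


def overlaps(r: Read, s: Read, params: OverlapParams) -> bool:
    return shared_lmer_count(r, s, params.l, params.canonical) >= params.m


def build_overlap_graph(
    reads: list[Read], params: OverlapParams
) -> dict[str, set[str]]:
    """Adjacency of the overlap graph (no self edges).

    Candidate pairs come from the inverted l-mer index; each candidate is
    verified by the exact distinct-shared-l-mer count, so index bucketing
    never changes the result, only the work done.
    """
    index: dict[str, list[int]] = defaultdict(list)
    sets: list[set[str]] = []
    for i, read in enumerate(reads):
        lm = lmer_set(read.sequence, params.l, params.canonical)
        sets.append(lm)
        for w in lm:
            index[w].append(i)

    # count shared l-mers per candidate pair straight off the index buckets:
    # a pair is co-listed under exactly its number of shared l-mers, because
    # per-read l-mer sets are distinct
    pair_counts: dict[tuple[int, int], int] = defaultdict(int)
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for a in range(len(bucket)):
            for b in range(a + 1, len(bucket)):
                pair_counts[(bucket[a], bucket[b])] += 1

    adj: dict[str, set[str]] = {read.read_id: set() for read in reads}
    for (i, j), count in pair_counts.items():
        if count >= params.m:
            adj[reads[i].read_id].add(reads[j].read_id)
            adj[reads[j].read_id].add(reads[i].read_id)
    return adj


def build_groups(
    reads: list[Read],
    params: OverlapParams,
    adjacency: dict[str, set[str]] | None = None,
) -> list[ReadGroup]:
    """Connected components of the overlap graph, numbered by smallest member id."""
    if not reads:
        return []
    if adjacency is None:
        adjacency = build_overlap_graph(reads, params)
    ids = [r.read_id for r in reads]
    pos = {rid: i for i, rid in enumerate(ids)}
    rows, cols = [], []
    for rid, neighbours in adjacency.items():
        for nid in neighbours:
            rows.append(pos[rid])
            cols.append(pos[nid])
    graph = csr_matrix(
        ([1] * len(rows), (rows, cols)), shape=(len(ids), len(ids)), dtype=bool
    )
    n_comp, labels = connected_components(graph, directed=False)
    members: dict[int, set[str]] = defaultdict(set)
    for rid, lab in zip(ids, labels):
        members[lab].add(rid)
    ordered = sorted(members.values(), key=min)
    return [ReadGroup(group_id=i, read_ids=m) for i, m in enumerate(ordered)]


def greedy_core(
    cluster_read_ids: set[str],
    adjacency: dict[str, set[str]],
    cluster_id: int = 0,
) -> Core:
    """Greedy maximal independent set over the cluster's overlap subgraph.

    Reads are visited in ascending id order and kept whenever no already-kept
    read overlaps them — stable and deterministic regardless of how the
    adjacency was built.
    """
    if not cluster_read_ids:
        raise ValueError("cannot build a core for an empty cluster")
    core: set[str] = set()
    for rid in sorted(cluster_read_ids):
        neighbours = adjacency.get(rid, set())
        if not (neighbours & core):
            core.add(rid)
    return Core(cluster_id=cluster_id, read_ids=core)


def tiny_group_passthrough(
    groups: list[ReadGroup], min_size: int = 3
) -> tuple[list[ReadGroup], list[ReadGroup]]:
    """Split off groups too small to yield a reliable composition vector.

    Tiny groups (typically reads of very low-abundance genomes) skip the
    merging stage and go straight to labeling as standalone clusters whose
    core is the whole group.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [g for g in groups if len(g.read_ids) >= min_size]
    tiny = [g for g in groups if len(g.read_ids) < min_size]
    return kept, tiny
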