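"""Cluster labeling by two-level hit filtering and LCA, plus post-processing.

A cluster is labeled from the similarity hits of its *core* reads only.
Filtering happens at two levels before the LCA:

* read level — hits below the bit-score floor ``s_min`` are discarded, then
  only hits within ``p_top`` percent of that read's best remaining bit-score
  are kept (the MEGAN-style relative cutoff);
* cluster level — across the core's hit lists L, a subject taxon t survives
  only if it occurs in at least ``o_max`` percent of the lists (counted at
  most once per list). If that empties every list, the threshold is halved
  exactly once and the filter re-applied; if the lists are still empty the
  cluster stays unlabeled.

The label is the LCA of all surviving taxa. Post-processing merges clusters
that received the same label and declares reads of unlabeled clusters, or of
clusters labeled at the taxonomy root, unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import Assignment, Cluster, ClusterLabel, Hit, HitList
from .taxonomy import TaxonomyTree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the two-level filter.

    Defaults (35 bits, 10 %, 50 %) are the values the method is normally run
    with; ``o_max`` is the fraction of core hit lists a taxon must appear in.
    """

    s_min: float = 35.0
    p_top: float = 10.0
    o_max: float = 50.0

    def __post_init__(self) -> None:
        if self.s_min < 0:
            raise ValueError("s_min must be >= 0")
        if not 0 <= self.p_top <= 100:
            raise ValueError("p_top must be in [0, 100]")
        if not 0 < self.o_max <= 100:
            raise ValueError("o_max must be in (0, 100]")


def dedupe_hits(raw_hits: list[Hit], read_id: str = "") -> HitList:
    """Collapse a read's hits to one per subject taxon, keeping the max bit-score."""
    if not raw_hits:
        return HitList(read_id=read_id, hits=[])
    read_id = raw_hits[0].query_id
    best: dict[int, Hit] = {}
    order: list[int] = []
    for h in raw_hits:
        if h.query_id != read_id:
            raise ValueError(f"mixed query ids: {read_id!r} vs {h.query_id!r}")
        if h.taxon not in best:
            best[h.taxon] = h
            order.append(h.taxon)
        elif h.bit_score > best[h.taxon].bit_score:
            best[h.taxon] = h
    return HitList(read_id=read_id, hits=[best[t] for t in order])


def read_level_filter(h: HitList, s_min: float, p_top: float) -> HitList:
    """Keep hits >= s_min, then hits within p_top percent of the best survivor."""
    survivors = [hit for hit in h.hits if hit.bit_score >= s_min]
    if not survivors:
        return HitList(read_id=h.read_id, hits=[])
    cutoff = (1.0 - p_top / 100.0) * max(hit.bit_score for hit in survivors)
    return HitList(
        read_id=h.read_id, hits=[hit for hit in survivors if hit.bit_score >= cutoff]
    )


def _occurrences(L: list[HitList]) -> dict[int, int]:
    """f(t): number of lists in L containing taxon t (at most once per list)."""
    f: dict[int, int] = {}
    for hl in L:
        for t in hl.taxa():
            f[t] = f.get(t, 0) + 1
    return f


def _retain(L: list[HitList], o_max: float) -> list[HitList]:
    f = _occurrences(L)
    threshold = (o_max / 100.0) * len(L)  # exact real arithmetic, no rounding
    keep = {t for t, n in f.items() if n >= threshold}
    return [
        HitList(read_id=hl.read_id, hits=[h for h in hl.hits if h.taxon in keep])
        for hl in L
    ]


def cluster_level_filter(L: list[HitList], o_max: float) -> list[HitList]:
    """Retain hits occurring in >= o_max percent of the lists.

    If the threshold empties every list while there were hits to begin with,
    o_max is halved exactly once and the filter recomputed on the original L.
    """
    if not L:
        raise ValueError("cluster_level_filter needs a non-empty list of hit lists")
    filtered = _retain(L, o_max)
    had_hits = any(hl.hits for hl in L)
    if had_hits and not any(hl.hits for hl in filtered):
        filtered = _retain(L, o_max / 2.0)
    return filtered


def label_cluster(
    cluster_id: int,
    core_hitlists: list[HitList],
    params: FilterParams,
    tree: TaxonomyTree,
) -> ClusterLabel:
    """Two-level filter then LCA of surviving taxa.

    ``core_hitlists`` holds one (deduped) list per core read that returned at
    least one raw hit — reads with no similarity signal carry no information
    about hit consensus and are excluded from the denominator |L|.
    """
    if not core_hitlists:
        return ClusterLabel(cluster_id=cluster_id, taxid=None, n_core_reads_with_hits=0)
    L = [read_level_filter(hl, params.s_min, params.p_top) for hl in core_hitlists]
    L = cluster_level_filter(L, params.o_max)
    survivors: set[int] = set()
    for hl in L:
        survivors |= hl.taxa()
    taxid = tree.lca(survivors) if survivors else None
    log.debug(
        "cluster %d: |L|=%d, %d surviving taxa, label=%s",
        cluster_id, len(core_hitlists), len(survivors), taxid,
    )
    return ClusterLabel(
        cluster_id=cluster_id, taxid=taxid, n_core_reads_with_hits=len(core_hitlists)
    )


def post_process(
    labels: list[ClusterLabel],
    clusters: list[Cluster],
    tree: TaxonomyTree,
) -> list[Assignment]:
    """Merge same-label clusters; root-labeled and unlabeled reads are unassigned.

    The surviving id of a merged cluster is the smallest constituent id, and
    the output is sorted by read id, so identical inputs give byte-identical
    files downstream.
    """
    label_by_cluster = {lab.cluster_id: lab.taxid for lab in labels}
    merged_id: dict[int, int] = {}
    first_with_label: dict[int, int] = {}
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        taxid = label_by_cluster.get(c.cluster_id)
        if taxid is None:
            merged_id[c.cluster_id] = c.cluster_id
        else:
            merged_id[c.cluster_id] = first_with_label.setdefault(taxid, c.cluster_id)

    out: list[Assignment] = []
    for c in clusters:
        taxid = label_by_cluster.get(c.cluster_id)
        assigned = taxid if (taxid is not None and taxid != tree.root) else None
        for rid in c.read_ids:
            out.append(
                Assignment(read_id=rid, cluster_id=merged_id[c.cluster_id], taxid=assigned)
            )
    out.sort(key=lambda a: a.read_id)
    return out
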