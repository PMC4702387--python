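"""End-to-end orchestration: cluster -> core extraction -> label -> evaluate.

Stage outputs are plain files (cluster TSV, core-read FASTA, assignment TSV)
so each stage can be run, inspected and re-run independently; the similarity
search between the two steps is external — the core FASTA is exactly the
query set a user submits to the aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import clustering, overlap
from .assignment import FilterParams, dedupe_hits, label_cluster, post_process
from .model import Assignment, Cluster, Core, Hit, Read, ReadGroup
from .overlap import OverlapParams
from .taxonomy import TaxonomyTree

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    overlap: OverlapParams = field(default_factory=OverlapParams)
    filters: FilterParams = field(default_factory=FilterParams)
    word_size: int = 4
    canonical_words: bool = True
    min_group_size: int = 3
    k: int | None = None  # override; None = automatic via f(k)
    k_max: int = 10
    k_detect_min_reads: int = 10  # only groups this large vote on k
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        overlap_keys = {"l", "m", "canonical"}
        filter_keys = {"s_min", "p_top", "o_max"}
        op = OverlapParams(**{k: v for k, v in raw.items() if k in overlap_keys})
        fp = FilterParams(**{k: v for k, v in raw.items() if k in filter_keys})
        rest = {
            k: v for k, v in raw.items() if k not in overlap_keys | filter_keys
        }
        return cls(overlap=op, filters=fp, **rest)

    def to_yaml(self, path: str | Path) -> None:
        flat = {**asdict(self.overlap), **asdict(self.filters)}
        for k, v in asdict(self).items():
            if k not in ("overlap", "filters"):
                flat[k] = v
        with open(path, "w") as fh:
            yaml.safe_dump(flat, fh)


@dataclass
class ClusterResult:
    clusters: list[Cluster]           # every cluster carries its core
    groups: list[ReadGroup]
    chosen_k: int
    adjacency: dict[str, set[str]]

    @property
    def core_read_ids(self) -> set[str]:
        ids: set[str] = set()
        for c in self.clusters:
            assert c.core is not None
            ids |= c.core.read_ids
        return ids


def run_cluster(reads: list[Read], config: PipelineConfig) -> ClusterResult:
    """Group by overlap, merge by composition k-means, build cores."""
    adjacency = overlap.build_overlap_graph(reads, config.overlap)
    groups = overlap.build_groups(reads, config.overlap, adjacency)
    kept, tiny = overlap.tiny_group_passthrough(groups, config.min_group_size)
    reads_by_id = {r.read_id: r for r in reads}

    clusters: list[Cluster] = []
    if kept:
        vectors = [
            clustering.composition_vector(
                g, reads_by_id, config.word_size, config.canonical_words
            )
            for g in kept
        ]
        if config.k is not None:
            k = config.k
        else:
            # k is detected from composition-reliable groups only: vectors of
            # small groups are noisy enough to flatten the f(k) curve, while
            # large groups carry the genome-level signal. Weighting by read
            # count keeps the distortion on the scale of reads represented.
            reliable = [
                (v, len(g.read_ids))
                for v, g in zip(vectors, kept)
                if len(g.read_ids) >= config.k_detect_min_reads
            ]
            if len(reliable) >= 2:
                k = clustering.choose_k(
                    [v for v, _ in reliable],
                    config.k_max,
                    config.seed,
                    weights=[float(n) for _, n in reliable],
                )
            else:
                k = clustering.choose_k(vectors, config.k_max, config.seed)
            k = min(k, len(vectors))
        mapping = clustering.kmeans_partition(vectors, k, config.seed)
        clusters = clustering.merge_groups(kept, mapping)
    else:
        k = 0

    next_id = len(clusters)
    for g in tiny:
        # tiny groups pass straight through: the cluster is its own core
        c = Cluster(cluster_id=next_id, group_ids=[g.group_id], read_ids=set(g.read_ids))
        c.core = Core(cluster_id=next_id, read_ids=set(g.read_ids))
        clusters.append(c)
        next_id += 1

    for c in clusters:
        if c.core is None:
            c.core = overlap.greedy_core(c.read_ids, adjacency, c.cluster_id)

    n_core = sum(len(c.core.read_ids) for c in clusters if c.core)
    log.info(
        "clustering: %d reads -> %d groups (%d tiny) -> %d clusters; "
        "core reads %d/%d (query reduction ratio %.3f)",
        len(reads), len(groups), len(tiny), len(clusters),
        n_core, len(reads), n_core / len(reads) if reads else 0.0,
    )
    return ClusterResult(clusters=clusters, groups=groups, chosen_k=k, adjacency=adjacency)


def core_reads(result: ClusterResult, reads: list[Read]) -> list[Read]:
    """The query set for similarity search: core reads only, input order."""
    ids = result.core_read_ids
    return [r for r in reads if r.read_id in ids]


def run_assign(
    result: ClusterResult,
    hits: list[Hit],
    tree: TaxonomyTree,
    params: FilterParams,
) -> list[Assignment]:
    """Label every cluster from its core hits, then post-process per read."""
    core_ids = result.core_read_ids
    by_read: dict[str, list[Hit]] = {}
    skipped = 0
    for h in hits:
        if h.query_id in core_ids:
            by_read.setdefault(h.query_id, []).append(h)
        else:
            skipped += 1
    if skipped:
        log.warning("ignoring %d hits for non-core reads", skipped)

    labels = []
    for c in result.clusters:
        assert c.core is not None
        hitlists = [
            dedupe_hits(by_read[rid])
            for rid in sorted(c.core.read_ids)
            if rid in by_read
        ]
        labels.append(label_cluster(c.cluster_id, hitlists, params, tree))

    assignments = post_process(labels, result.clusters, tree)
    n_assigned = sum(1 for a in assignments if a.taxid is not None)
    log.info("assignment: %d/%d reads assigned", n_assigned, len(assignments))
    return assignments


def write_cluster_tables(
    result: ClusterResult, reads: list[Read], out_dir: str | Path
) -> tuple[Path, Path]:
    """Emit cluster membership TSV and the core-read query FASTA."""
    from . import io  # local import keeps module load light

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    members_path = out / "clusters.tsv"
    core_path = out / "core_reads.fasta"
    core_ids = result.core_read_ids
    with open(members_path, "w") as fh:
        fh.write("read_id\tcluster_id\tis_core\n")
        for c in sorted(result.clusters, key=lambda c: c.cluster_id):
            for rid in sorted(c.read_ids):
                fh.write(f"{rid}\t{c.cluster_id}\t{int(rid in core_ids)}\n")
    io.write_fasta(core_reads(result, reads), core_path)
    return members_path, core_path
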