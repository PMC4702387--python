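"""Core data records shared across the pipeline stages.

These are deliberately plain dataclasses: every stage reads and writes them,
and keeping them free of behaviour avoids import cycles between the stage
modules (overlap -> clustering -> assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Read:
    """A sequence record; ``true_taxon`` is carried only for evaluation."""

    read_id: str
    sequence: str
    true_taxon: int | None = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: sequence must be non-empty")


@dataclass(frozen=True)
class Hit:
    """One similarity-search match, reduced to (subject taxon, bit-score)."""

    query_id: str
    subject_id: str
    taxon: int
    bit_score: float

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError(
                f"hit {self.query_id!r}->{self.subject_id!r}: bit-score must be >= 0"
            )


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str = ""


@dataclass
class ReadGroup:
    """A connected component of the read-overlap graph."""

    group_id: int
    read_ids: set[str]


@dataclass
class Core:
    """Maximal independent set of a cluster's overlap graph.

    Only these reads are submitted to similarity search; the rest of the
    cluster inherits the label derived from them.
    """

    cluster_id: int
    read_ids: set[str]


@dataclass
class Cluster:
    cluster_id: int
    group_ids: list[int]
    read_ids: set[str]
    core: Core | None = None


@dataclass
class HitList:
    """Distinct hits for one read: one entry per subject taxon, max bit-score."""

    read_id: str
    hits: list[Hit] = field(default_factory=list)

    def taxa(self) -> set[int]:
        return {h.taxon for h in self.hits}

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class ClusterLabel:
    cluster_id: int
    taxid: int | None
    n_core_reads_with_hits: int = 0


@dataclass(frozen=True)
class Assignment:
    """Final per-read call; ``taxid`` is None for unassigned reads."""

    read_id: str
    cluster_id: int
    taxid: int | None
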