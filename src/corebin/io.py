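"""Readers and writers for every external format the pipeline touches.

FASTA/FASTQ go through Bio.SeqIO. The tabular hit format is the common
tab-separated alignment dialect (12 standard columns with a subject taxid
appended by ``-outfmt '6 std staxids'`` or equivalent); column positions are
remappable because taxid column placement varies across tool versions.
Taxonomy is the NCBI dump dialect (pipe-delimited nodes/names files).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .model import Assignment, Hit, Read, TaxNode
from .taxonomy import TaxonomyTree

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- sequences


def read_sequences(path: str | Path, format: str = "fasta") -> list[Read]:
    """Load reads from FASTA/FASTQ; ids are headers up to first whitespace."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    reads: list[Read] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), format))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed {format}: {exc}") from exc
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate read id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for read {rec.id!r}")
        reads.append(Read(read_id=rec.id, sequence=seq))
    return reads


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


# --------------------------------------------------------------------- hits


@dataclass(frozen=True)
class HitTableDialect:
    """1-based column positions in the tab-separated hit table."""

    query: int = 1
    subject: int = 2
    bit_score: int = 12
    taxid: int = 13

    def max_column(self) -> int:
        return max(self.query, self.subject, self.bit_score, self.taxid)


def read_hits(
    path: str | Path,
    dialect: HitTableDialect = HitTableDialect(),
    taxonomy: TaxonomyTree | None = None,
) -> list[Hit]:
    """Parse a tabular alignment file into Hits, preserving line order.

    Comment lines (leading '#') are skipped. When a taxonomy is supplied,
    hits whose taxid it does not contain are dropped with a warning rather
    than raised — reference databases routinely outpace taxonomy dumps.
    """
    hits: list[Hit] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < dialect.max_column():
                raise ParseError(
                    f"{path}:{lineno}: expected >= {dialect.max_column()} columns, "
                    f"got {len(fields)}; if the taxid lives in a different column, "
                    f"remap it via HitTableDialect(taxid=<1-based column>)"
                )
            try:
                score = float(fields[dialect.bit_score - 1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric bit-score "
                    f"{fields[dialect.bit_score - 1]!r}"
                ) from exc
            try:
                taxid = int(fields[dialect.taxid - 1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer taxid {fields[dialect.taxid - 1]!r}; "
                    f"configure HitTableDialect if the taxid column differs"
                ) from exc
            if taxonomy is not None and taxid not in taxonomy:
                dropped += 1
                continue
            hits.append(
                Hit(
                    query_id=fields[dialect.query - 1],
                    subject_id=fields[dialect.subject - 1],
                    taxon=taxid,
                    bit_score=score,
                )
            )
    if dropped:
        log.warning("%s: dropped %d hits with taxids absent from the taxonomy", path, dropped)
    return hits


def write_hits(hits: Iterable[Hit], path: str | Path) -> None:
    """Write the 12+1-column tabular dialect (unused middle columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            mid = "\t".join(["0"] * 9)  # identity .. evalue placeholders
            fh.write(f"{h.query_id}\t{h.subject_id}\t{mid}\t{h.bit_score:.1f}\t{h.taxon}\n")


# ----------------------------------------------------------------- taxonomy


def _split_dmp(line: str) -> list[str]:
    # NCBI dump rows end with "\t|"; cells are delimited by "\t|\t"
    return [cell.strip() for cell in line.rstrip("\n").rstrip("|\t ").split("|")]


def read_taxonomy(nodes_path: str | Path, names_path: str | Path | None = None) -> TaxonomyTree:
    """Build a TaxonomyTree from NCBI-dump-style nodes/names files."""
    names: dict[int, str] = {}
    if names_path is not None:
        with open(names_path) as fh:
            for line in fh:
                cells = _split_dmp(line)
                if len(cells) < 2:
                    continue
                # prefer scientific names; first name wins otherwise
                taxid = int(cells[0])
                name_class = cells[3] if len(cells) > 3 else ""
                if name_class == "scientific name" or taxid not in names:
                    names[taxid] = cells[1]

    nodes: list[TaxNode] = []
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cells = _split_dmp(line)
            if len(cells) < 3:
                raise ParseError(f"{nodes_path}:{lineno}: expected 'taxid | parent | rank'")
            taxid, parent = int(cells[0]), int(cells[1])
            nodes.append(
                TaxNode(taxid=taxid, parent=parent, rank=cells[2], name=names.get(taxid, ""))
            )
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path) -> None:
    with open(nodes_path, "w") as fh:
        for node in tree.nodes.values():
            fh.write(f"{node.taxid}\t|\t{node.parent}\t|\t{node.rank}\t|\n")
    with open(names_path, "w") as fh:
        for node in tree.nodes.values():
            fh.write(f"{node.taxid}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n")


# -------------------------------------------------------------- assignments

_ASSIGN_HEADER = "read_id\tcluster_id\ttaxid\trank\tname"


def write_assignments(
    results: Sequence[Assignment], path: str | Path, tree: TaxonomyTree | None = None
) -> None:
    """Emit the final per-read TSV; unassigned reads get taxid 'NA'."""
    with open(path, "w") as fh:
        fh.write(_ASSIGN_HEADER + "\n")
        for a in results:
            if a.taxid is None:
                fh.write(f"{a.read_id}\t{a.cluster_id}\tNA\tNA\tNA\n")
            else:
                rank = tree.rank(a.taxid) if tree else "NA"
                name = tree.name(a.taxid) if tree else "NA"
                fh.write(f"{a.read_id}\t{a.cluster_id}\t{a.taxid}\t{rank}\t{name}\n")


def read_assignments(path: str | Path) -> list[Assignment]:
    out: list[Assignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _ASSIGN_HEADER:
            raise ParseError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, 2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            taxid = None if fields[2] == "NA" else int(fields[2])
            out.append(Assignment(read_id=fields[0], cluster_id=int(fields[1]), taxid=taxid))
    return out


# -------------------------------------------------------------------- truth


def write_truth(
    rows: Iterable[tuple[str, int, str]], path: str | Path
) -> None:
    """Truth TSV: read_id, true taxid, evidence level (lowest rank in reference)."""
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_taxid\tevidence_level\n")
        for read_id, taxid, level in rows:
            fh.write(f"{read_id}\t{taxid}\t{level}\n")


def read_truth(path: str | Path) -> dict[str, tuple[int, str]]:
    out: dict[str, tuple[int, str]] = {}
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            out[fields[0]] = (int(fields[1]), fields[2])
    return out
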