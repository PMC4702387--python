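"""Self-contained fixtures: genomes, reads, a toy taxonomy, and mock hit tables.

The generator emulates the data regime the method targets — short (80–100 bp)
shotgun reads at moderate coverage with ~1 % substitution error, drawn from a
handful of genomes with genome-specific composition bias — plus a mock
similarity-search table whose signal/noise structure is controllable, so the
whole pipeline is testable without reference databases or an aligner.

Each genome is sampled from its own order-k Markov chain with Dirichlet(1)
transition rows, which gives genomes distinct word-frequency signatures the
way real genomes differ in tetranucleotide usage. The toy taxonomy gives
every genome a full root/class/order/family/genus/species lineage; all
genomes share the class node, so the LCA of hits to different genomes lands
at class level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from .model import Hit, Read, TaxNode
from .overlap import reverse_complement
from .taxonomy import TaxonomyTree
from . import io

BASES = "ACGT"

ROOT_TAXID = 1
CLASS_TAXID = 2


@dataclass
class SimConfig:
    n_genomes: int = 3
    genome_length: int = 10_000
    markov_order: int = 2
    coverage: float = 5.0
    read_length: int = 100
    error_rate: float = 0.01
    hit_signal: float = 0.7          # P(a mock hit points to the true species)
    mean_hits: float = 3.0           # mean hits per read (given any)
    zero_hit_prob: float = 0.05      # P(a read returns no hits at all)
    signal_score_mean: float = 80.0  # bit-score distributions, truncated at 0
    signal_score_sd: float = 10.0
    noise_score_mean: float = 45.0
    noise_score_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0 <= self.hit_signal <= 1:
            raise ValueError("hit_signal must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")


def species_taxid(genome_index: int) -> int:
    """Taxid of the species node of the i-th genome (0-based)."""
    return CLASS_TAXID + 1 + genome_index * 4 + 3


def toy_taxonomy(n_genomes: int) -> TaxonomyTree:
    """Root and one shared class; each genome gets its own order/family/genus/species."""
    nodes = [
        TaxNode(ROOT_TAXID, ROOT_TAXID, "root", "root"),
        TaxNode(CLASS_TAXID, ROOT_TAXID, "class", "SimClass"),
    ]
    for g in range(n_genomes):
        base = CLASS_TAXID + 1 + g * 4
        nodes.append(TaxNode(base, CLASS_TAXID, "order", f"SimOrder{g}"))
        nodes.append(TaxNode(base + 1, base, "family", f"SimFamily{g}"))
        nodes.append(TaxNode(base + 2, base + 1, "genus", f"SimGenus{g}"))
        nodes.append(TaxNode(base + 3, base + 2, "species", f"SimSpecies{g}"))
    return TaxonomyTree(nodes)


def _markov_genome(length: int, order: int, rng: np.random.Generator) -> str:
    states = ["".join(p) for p in product(BASES, repeat=order)]
    transitions = {s: rng.dirichlet(np.ones(4)) for s in states}
    seq = list(rng.choice(list(BASES), size=order))
    for _ in range(length - order):
        state = "".join(seq[-order:])
        seq.append(BASES[rng.choice(4, p=transitions[state])])
    return "".join(seq)


def simulate_genomes(config: SimConfig) -> tuple[list[tuple[int, str]], TaxonomyTree]:
    """One compositionally distinct genome per species of the toy taxonomy."""
    rng = np.random.default_rng(config.seed)
    tree = toy_taxonomy(config.n_genomes)
    genomes = [
        (species_taxid(g), _markov_genome(config.genome_length, config.markov_order, rng))
        for g in range(config.n_genomes)
    ]
    return genomes, tree


def simulate_reads(
    genomes: list[tuple[int, str]],
    config: SimConfig,
    return_layout: bool = False,
) -> list[Read] | tuple[list[Read], list[tuple[int, int, str]]]:
    """Uniform-start, both-strand reads with per-base substitution errors.

    Read count per genome is coverage * genome_length / read_length (rounded),
    so the expected depth matches the configured coverage. With
    ``return_layout`` the per-read (genome index, start, strand) triples are
    returned too, which evaluation-style checks need to locate each read's
    template.
    """
    rng = np.random.default_rng(config.seed + 1)
    reads: list[Read] = []
    layout: list[tuple[int, int, str]] = []
    idx = 0
    for g_idx, (taxid, genome) in enumerate(genomes):
        n_reads = int(round(config.coverage * len(genome) / config.read_length))
        for _ in range(n_reads):
            start = int(rng.integers(0, len(genome) - config.read_length + 1))
            seq = genome[start : start + config.read_length]
            strand = "+"
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
                strand = "-"
            if config.error_rate > 0:
                bases = list(seq)
                errors = np.nonzero(rng.random(len(bases)) < config.error_rate)[0]
                for pos in errors:
                    choices = [b for b in BASES if b != bases[pos]]
                    bases[pos] = choices[int(rng.integers(3))]
                seq = "".join(bases)
            reads.append(Read(read_id=f"r{idx:06d}", sequence=seq, true_taxon=taxid))
            layout.append((g_idx, start, strand))
            idx += 1
    if return_layout:
        return reads, layout
    return reads


def simulate_hits(
    reads: list[Read], tree: TaxonomyTree, config: SimConfig
) -> list[Hit]:
    """Mock similarity table: signal hits to the true species, noise elsewhere.

    Per read: no hits with probability ``zero_hit_prob``; otherwise
    1 + Poisson(mean_hits - 1) hits, each pointing at the read's true species
    with probability ``hit_signal`` and at a uniformly random species
    otherwise. Signal and noise bit-scores come from separate normal
    distributions truncated at zero.
    """
    rng = np.random.default_rng(config.seed + 2)
    species = sorted(
        t for t, node in tree.nodes.items() if node.rank == "species"
    )
    hits: list[Hit] = []
    for read in reads:
        if rng.random() < config.zero_hit_prob:
            continue
        n_hits = 1 + int(rng.poisson(max(config.mean_hits - 1.0, 0.0)))
        for _ in range(n_hits):
            if read.true_taxon is not None and rng.random() < config.hit_signal:
                taxon = read.true_taxon
                score = rng.normal(config.signal_score_mean, config.signal_score_sd)
            else:
                taxon = int(species[int(rng.integers(len(species)))])
                score = rng.normal(config.noise_score_mean, config.noise_score_sd)
            hits.append(
                Hit(
                    query_id=read.read_id,
                    subject_id=f"ref|{taxon}",
                    taxon=taxon,
                    bit_score=max(0.0, float(score)),
                )
            )
    return hits


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a complete fixture set; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, tree = simulate_genomes(config)
    reads = simulate_reads(genomes, config)
    hits = simulate_hits(reads, tree, config)

    paths = {
        "reads": out / "reads.fasta",
        "hits": out / "hits.tsv",
        "nodes": out / "nodes.dmp",
        "names": out / "names.dmp",
        "truth": out / "truth.tsv",
    }
    io.write_fasta(reads, paths["reads"])
    io.write_hits(hits, paths["hits"])
    io.write_taxonomy(tree, paths["nodes"], paths["names"])
    io.write_truth(
        ((r.read_id, r.true_taxon, "species") for r in reads if r.true_taxon is not None),
        paths["truth"],
    )
    return paths
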