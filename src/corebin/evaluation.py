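"""Rank-level classification metrics against known truth labels.

For a taxonomic level i, an assignment is *exact* when it equals the truth
lineage's node at that level and *under* when it sits strictly below that
node (e.g. truth genus-level node, assignment the right species). Writing
E_i and U_i for the exact / under counts, N for total reads and A for
assigned reads:

    sensitivity_A(i) = (E_i + U_i) / N        precision_A(i) = (E_i + U_i) / A
    F_A(i) = harmonic mean of the two

The B variants measure discovery of organisms absent from the reference:
only assignments exactly at the lowest level the reference evidence supports
count, anything below that level is counted as incorrect:

    sensitivity_B = sum_{i in T} E_i / N      precision_B = sum_{i in T} E_i / A

where T is the set of evidence-supported levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Assignment
from .taxonomy import TaxonomyTree

LEVELS = ("species", "genus", "family", "order", "class")


@dataclass
class EvalCounts:
    N: int
    A: int
    E: dict[str, int] = field(default_factory=dict)  # exact at level
    U: dict[str, int] = field(default_factory=dict)  # under level


def classify_at_level(
    true_taxid: int, assigned_taxid: int, level: str, tree: TaxonomyTree
) -> str:
    """'exact', 'under' or 'neither' for one assignment at one level."""
    target = tree.rank_at_or_above(true_taxid, level)
    if target is None:
        return "neither"
    if assigned_taxid == target:
        return "exact"
    if target in tree.ancestors(assigned_taxid)[1:]:
        return "under"
    return "neither"


def tally(
    assignments: list[Assignment],
    truth: dict[str, tuple[int, str]],
    tree: TaxonomyTree,
    levels: tuple[str, ...] = LEVELS,
) -> EvalCounts:
    """Count E_i / U_i over all assigned reads with known truth."""
    counts = EvalCounts(
        N=len(assignments),
        A=sum(1 for a in assignments if a.taxid is not None),
        E={lvl: 0 for lvl in levels},
        U={lvl: 0 for lvl in levels},
    )
    for a in assignments:
        if a.taxid is None or a.read_id not in truth:
            continue
        true_taxid, _ = truth[a.read_id]
        for lvl in levels:
            verdict = classify_at_level(true_taxid, a.taxid, lvl, tree)
            if verdict == "exact":
                counts.E[lvl] += 1
            elif verdict == "under":
                counts.U[lvl] += 1
    return counts


def tally_evidence_exact(
    assignments: list[Assignment],
    truth: dict[str, tuple[int, str]],
    tree: TaxonomyTree,
) -> EvalCounts:
    """E_i restricted to reads whose evidence level is i (for the B metrics).

    Each read can contribute only at its own evidence level — the lowest rank
    of its true lineage present in the reference — so summing E over levels
    counts reads assigned exactly where the evidence allows.
    """
    counts = EvalCounts(
        N=len(assignments),
        A=sum(1 for a in assignments if a.taxid is not None),
        E={lvl: 0 for lvl in LEVELS},
        U={lvl: 0 for lvl in LEVELS},
    )
    for a in assignments:
        if a.taxid is None or a.read_id not in truth:
            continue
        true_taxid, level = truth[a.read_id]
        if level in counts.E and classify_at_level(true_taxid, a.taxid, level, tree) == "exact":
            counts.E[level] += 1
    return counts


def metrics_A(
    counts: EvalCounts, level: str
) -> tuple[float, float | None, float | None]:
    """(sensitivity_A, precision_A, F_A) at one level; None when A = 0."""
    if counts.N <= 0:
        raise ValueError("N must be positive")
    correct = counts.E.get(level, 0) + counts.U.get(level, 0)
    sensitivity = correct / counts.N
    if counts.A == 0:
        return sensitivity, None, None
    precision = correct / counts.A
    if precision + sensitivity == 0:
        return sensitivity, precision, 0.0
    f_measure = 2.0 / (1.0 / precision + 1.0 / sensitivity) if correct else 0.0
    return sensitivity, precision, f_measure


def metrics_B(counts: EvalCounts, T: set[str]) -> tuple[float, float | None]:
    """(sensitivity_B, precision_B) over the evidence-supported levels T."""
    if not T:
        raise ValueError("T must be non-empty")
    if counts.N <= 0:
        raise ValueError("N must be positive")
    exact = sum(counts.E.get(lvl, 0) for lvl in T)
    sensitivity = exact / counts.N
    precision = exact / counts.A if counts.A > 0 else None
    return sensitivity, precision
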