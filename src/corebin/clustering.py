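"""Merge overlap groups into genome-level clusters by composition k-means.

Each group is featurised by its pooled word (short l-mer) frequency vector —
tetranucleotides by default, with reverse-complement canonical merging so
the signature is strand-invariant. Groups are then merged with k-means,
and the number of clusters is chosen automatically with the f(k) cluster
evaluation function of Pham, Dimov & Nguyen (2005): f(k) compares the
distortion at k against the distortion expected from the k-1 solution under
a uniformity correction, and values well below 1 indicate genuine structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .model import Cluster, Read, ReadGroup
from .overlap import reverse_complement

F_K_THRESHOLD = 0.85  # values below indicate cluster structure at that k


@dataclass
class CompositionVector:
    group_id: int
    counts: np.ndarray  # normalised frequencies, sums to 1


def _word_index(word_size: int, canonical: bool) -> dict[str, int]:
    """Map each word to a feature column; canonical merges w with its revcomp."""
    words = ["".join(p) for p in product("ACGT", repeat=word_size)]
    index: dict[str, int] = {}
    col = 0
    for w in words:
        if w in index:
            continue
        index[w] = col
        if canonical:
            index[reverse_complement(w)] = col
        col += 1
    return index


def composition_vector(
    group: ReadGroup,
    reads_by_id: dict[str, Read],
    word_size: int = 4,
    canonical: bool = True,
) -> CompositionVector:
    """Pooled, normalised word frequencies over all reads of a group.

    Words are counted within each read (no windows across read boundaries);
    windows containing N are skipped.
    """
    if not group.read_ids:
        raise ValueError("cannot featurise an empty group")
    index = _word_index(word_size, canonical)
    n_features = max(index.values()) + 1
    counts = np.zeros(n_features, dtype=float)
    for rid in group.read_ids:
        seq = reads_by_id[rid].sequence
        for i in range(len(seq) - word_size + 1):
            w = seq[i : i + word_size]
            col = index.get(w)
            if col is not None:  # words with N are never indexed
                counts[col] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"group {group.group_id}: no countable words of size {word_size}")
    return CompositionVector(group_id=group.group_id, counts=counts / total)


def _distortion(
    matrix: np.ndarray, k: int, seed: int, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed)
    with warnings.catch_warnings():
        # duplicate vectors legitimately yield fewer distinct clusters than k
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = km.fit_predict(matrix, sample_weight=weights)
    return float(km.inertia_), labels


def kmeans_partition(
    vectors: list[CompositionVector], k: int, seed: int = 0
) -> dict[int, int]:
    """k-means over group vectors; returns group_id -> cluster_id.

    Cluster ids are relabeled so cluster 0 contains the smallest group id —
    the raw k-means label order depends on initialisation and would otherwise
    leak the seed into downstream output.
    """
    if not 1 <= k <= len(vectors):
        raise ValueError(f"k={k} must be in [1, {len(vectors)}]")
    matrix = np.vstack([v.counts for v in vectors])
    _, labels = _distortion(matrix, k, seed)
    order: dict[int, int] = {}
    for v, lab in sorted(zip(vectors, labels), key=lambda t: t[0].group_id):
        if lab not in order:
            order[lab] = len(order)
    return {v.group_id: order[lab] for v, lab in zip(vectors, labels)}


def f_k_curve(
    matrix: np.ndarray,
    k_max: int,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> list[float]:
    """f(k) for k = 1..k_max (Pham–Dimov–Nguyen evaluation function).

    f(1) = 1 by definition; f(k) = S_k / (alpha_k * S_{k-1}) with S_k the
    k-means distortion, alpha_2 = 1 - 3/(4 d) for d feature dimensions and
    alpha_k = alpha_{k-1} + (1 - alpha_{k-1})/6 thereafter. When S_{k-1} is
    zero the data are already perfectly explained and f is defined as 1.
    """
    d = matrix.shape[1]
    values = [1.0]
    s_prev = _distortion(matrix, 1, seed, weights)[0]
    alpha = 1.0 - 3.0 / (4.0 * d)
    for k in range(2, k_max + 1):
        s_k = _distortion(matrix, k, seed, weights)[0]
        values.append(1.0 if s_prev <= 0 else s_k / (alpha * s_prev))
        s_prev = s_k
        alpha = alpha + (1.0 - alpha) / 6.0
    return values


def choose_k(
    vectors: list[CompositionVector],
    k_max: int = 10,
    seed: int = 0,
    weights: list[float] | None = None,
) -> int:
    """Number of clusters minimising f(k) among k with f(k) below threshold.

    If no k in [2, k_max] shows structure (all f(k) >= 0.85), the data are
    treated as a single cluster. Optional per-vector weights let callers
    emphasise vectors estimated from more sequence (larger groups), whose
    composition signature is less noisy.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if len(vectors) < 2:
        return 1
    matrix = np.vstack([v.counts for v in vectors])
    upper = min(k_max, len(vectors))
    w = None if weights is None else np.asarray(weights, dtype=float)
    values = f_k_curve(matrix, upper, seed, w)
    candidates = [(f, k) for k, f in enumerate(values, start=1) if f < F_K_THRESHOLD]
    if not candidates:
        return 1
    _, best_k = min(candidates)  # ties resolve to the smaller f, then smaller k
    return best_k


def merge_groups(
    groups: list[ReadGroup],
    assignment: dict[int, int],
) -> list[Cluster]:
    """Materialise clusters from a group -> cluster mapping."""
    by_cluster: dict[int, list[ReadGroup]] = {}
    for g in groups:
        by_cluster.setdefault(assignment[g.group_id], []).append(g)
    clusters = []
    for cid in sorted(by_cluster):
        members = by_cluster[cid]
        read_ids: set[str] = set()
        for g in members:
            read_ids |= g.read_ids
        clusters.append(
            Cluster(
                cluster_id=cid,
                group_ids=sorted(g.group_id for g in members),
                read_ids=read_ids,
            )
        )
    return clusters
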