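"""Profile clustering and model-versus-data comparison.

Gene enrichment profiles (lower CI bounds) are compared pairwise with
dynamic time warping; the clipped cost matrix feeds Ward hierarchical
clustering, whose two-way cut separates a high-affinity cluster A from
a lower-affinity cluster B.  Model predictions are compared to
SeRP-derived profiles by the normalized cross-correlation at zero lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "dtw_distance",
    "distance_matrix",
    "cluster_AB",
    "ncc",
    "interactor_overlap",
]


@dataclass
class DistanceMatrix:
    gene_ids: list[str]
    matrix: np.ndarray
    clip: float = 500.0


@dataclass
class ClusterAssignment:
    labels: dict[str, str]  # gene -> "A" | "B"
    linkage: np.ndarray


def dtw_distance(x: np.ndarray, y: np.ndarray, metric: str = "abs") -> float:
    """Unconstrained dynamic-time-warping cost between two series.

    Classic DP over {match, insert, delete} steps.  With
    ``metric="abs"`` (default) the local cost is |x_i - y_j| and the
    returned value is the accumulated path cost; ``metric="sqeuclidean"``
    accumulates squared differences and returns the square root of the
    optimum (the tslearn-style convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty series")
    if metric == "abs":
        local = np.abs(x[:, None] - y[None, :])
    elif metric == "sqeuclidean":
        local = (x[:, None] - y[None, :]) ** 2
    else:
        raise ValueError("metric must be 'abs' or 'sqeuclidean'")
    n, m = local.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        row = acc[i]
        prev = acc[i - 1]
        li = local[i - 1]
        for j in range(1, m + 1):
            row[j] = li[j - 1] + min(prev[j - 1], prev[j], row[j - 1])
    cost = acc[n, m]
    return float(np.sqrt(cost)) if metric == "sqeuclidean" else float(cost)


def distance_matrix(
    profiles: dict[str, np.ndarray],
    min_len: int = 50,
    head_trim: int = 30,
    tail_trim: int = 10,
    clip: float = 500.0,
    metric: str = "abs",
) -> DistanceMatrix:
    """Pairwise DTW costs of trimmed gene profiles, clipped at ``clip``.

    Genes shorter than ``min_len`` codons are excluded; the first
    ``head_trim`` and last ``tail_trim`` codons of each profile are
    ignored before warping.
    """
    kept = {g: np.asarray(p, float) for g, p in profiles.items() if len(p) >= min_len}
    if len(kept) < 2:
        raise ValueError("need at least two genes after length filtering")
    ids = sorted(kept)
    trimmed = [kept[g][head_trim : len(kept[g]) - tail_trim] for g in ids]
    n = len(ids)
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = min(dtw_distance(trimmed[a], trimmed[b], metric), clip)
            mat[a, b] = mat[b, a] = d
    return DistanceMatrix(ids, mat, clip)


def cluster_AB(
    dm: DistanceMatrix, engagement_scores: dict[str, float]
) -> ClusterAssignment:
    """Two-way Ward cut of the DTW cost matrix.

    Ward linkage is applied to the clipped cost matrix treated as a
    distance matrix (a pragmatic, non-Euclidean use of Ward).  The
    cluster with the higher median engagement score is labelled A.
    """
    if len(dm.gene_ids) < 2:
        raise ValueError("need at least two genes to cluster")
    condensed = squareform(dm.matrix, checks=False)
    Z = linkage(condensed, method="ward")
    cut = fcluster(Z, 2, criterion="maxclust")
    medians = {}
    for k in np.unique(cut):
        genes = [g for g, c in zip(dm.gene_ids, cut) if c == k]
        medians[k] = float(np.median([engagement_scores.get(g, 0.0) for g in genes]))
    order = sorted(medians, key=lambda k: (-medians[k], k))
    name = {order[0]: "A"}
    for k in order[1:]:
        name[k] = "B"
    labels = {g: name[c] for g, c in zip(dm.gene_ids, cut)}
    return ClusterAssignment(labels, Z)


def ncc(model_profile: np.ndarray, serp_profile: np.ndarray) -> float:
    """Normalized cross-correlation at zero lag (Pearson form).

    Both signals are mean-subtracted and unit-normalized; a constant
    signal yields 0 by convention.  Invariant to affine rescaling of
    either input.
    """
    a = np.asarray(model_profile, dtype=float)
    b = np.asarray(serp_profile, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def interactor_overlap(sets: dict[str, set]) -> dict[str, int]:
    """Exclusive region counts of the Venn partition of the given sets.

    Keys are '&'-joined sorted set names (e.g. ``"TF"``, ``"DnaK&TF"``);
    each count is the number of elements belonging to exactly that
    combination of sets.
    """
    names = sorted(sets)
    universe = set().union(*sets.values()) if sets else set()
    counts: dict[str, int] = {}
    for k in range(1, 2 ** len(names)):
        members = [names[b] for b in range(len(names)) if k >> b & 1]
        counts["&".join(members)] = 0
    for el in universe:
        members = [n for n in names if el in sets[n]]
        counts["&".join(members)] += 1
    return counts
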