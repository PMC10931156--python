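"""Independent brute-force oracles used by the test suite."""

from __future__ import annotations

import numpy as np


def brute_force_ward(X: np.ndarray):
    """Naive Ward agglomeration from the minimum-variance definition.

    At each step the pair of clusters whose merge least increases the total
    within-cluster sum of squares is joined; the merge cost is computed
    directly from cluster members, ΔSSE = |A||B|/(|A|+|B|) · ||μA − μB||².
    Returns the partition (set of frozensets) after every merge and the
    SciPy-convention merge heights sqrt(2 · ΔSSE) in merge order.
    """
    clusters = [[i] for i in range(len(X))]
    partitions, heights = [], []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                na, nb = len(clusters[a]), len(clusters[b])
                mu_a = X[clusters[a]].mean(axis=0)
                mu_b = X[clusters[b]].mean(axis=0)
                cost = na * nb / (na + nb) * float(((mu_a - mu_b) ** 2).sum())
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        cost, a, b = best
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        partitions.append(frozenset(frozenset(c) for c in clusters))
        heights.append(np.sqrt(2.0 * cost))
    return partitions, np.array(heights)


def scipy_ward_partitions(Z: np.ndarray, n: int):
    """Partitions after each merge of a SciPy linkage, same layout as the
    brute-force oracle."""
    from scipy.cluster.hierarchy import cut_tree

    partitions = []
    for m in range(1, n):
        flat = cut_tree(Z, n_clusters=n - m).ravel()
        partitions.append(frozenset(
            frozenset(np.flatnonzero(flat == c).tolist()) for c in np.unique(flat)
        ))
    return partitions
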