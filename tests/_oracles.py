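"""Independent brute-force oracles used to cross-check the implementation.

These recompute results from first principles (cluster distances from the
original coordinates, sample keys as binary integers) rather than through
the package's recurrences, so agreement is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np


def naive_agglomerate(points: np.ndarray, linkage: str):
    """O(n^3) agglomeration computing every inter-cluster dissimilarity from
    scratch off the original coordinates.

    single/complete/average: min/max/mean of pairwise Euclidean distances
    between members. ward.d2: sqrt(2|A||B|/(|A|+|B|)) * ||centroid_A -
    centroid_B||. Ties: merge the pair with the lowest (first, second) node
    ids. Returns merge rows (left, right, height) with the same node-id and
    left-child conventions as the package (leaves 0..n-1, merge i -> n+i,
    left = child containing the lowest leaf index).
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    n = x.shape[0]
    pair_d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))

    def cluster_distance(a: list[int], b: list[int]) -> float:
        if linkage == "ward.d2":
            mu_a, mu_b = x[a].mean(axis=0), x[b].mean(axis=0)
            w = 2 * len(a) * len(b) / (len(a) + len(b))
            return float(np.sqrt(w) * np.linalg.norm(mu_a - mu_b))
        d = pair_d[np.ix_(a, b)]
        if linkage == "single":
            return float(d.min())
        if linkage == "complete":
            return float(d.max())
        if linkage == "average":
            return float(d.mean())
        raise ValueError(linkage)

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        ids = sorted(clusters)
        best, best_pair = None, None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                u, v = ids[i], ids[j]
                d = cluster_distance(clusters[u], clusters[v])
                if best is None or d < best or (d == best and (u, v) < best_pair):
                    best, best_pair = d, (u, v)
        u, v = best_pair
        left, right = (u, v) if min(clusters[u]) <= min(clusters[v]) else (v, u)
        merges.append((left, right, best))
        clusters[n + step] = clusters[left] + clusters[right]
        del clusters[u], clusters[v]
    return merges


def waterfall_order_by_binary_keys(binary: np.ndarray) -> list[int]:
    """Oncoprint sample ordering recomputed through integer keys: rank genes
    by count descending (ties by input index), read each sample's alteration
    vector in that order as a binary number, sort samples by that number
    descending (stable)."""
    b = (np.asarray(binary) != 0).astype(int)
    n_samples, n_genes = b.shape
    gene_rank = sorted(range(n_genes), key=lambda j: (-int(b[:, j].sum()), j))
    keys = []
    for i in range(n_samples):
        value = 0
        for j in gene_rank:
            value = (value << 1) | int(b[i, j])
        keys.append(value)
    return sorted(range(n_samples), key=lambda i: (-keys[i], i))


def best_two_partition_by_ss(points: np.ndarray):
    """Exhaustive minimum within-cluster sum of squares over all 2-partitions."""
    x = np.atleast_2d(np.asarray(points, float))
    n = x.shape[0]
    best, best_mask = None, None
    for mask in range(1, 2 ** (n - 1)):
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        ss = 0.0
        for part in (x[sel], x[~sel]):
            if len(part) == 0:
                break
            ss += ((part - part.mean(axis=0)) ** 2).sum()
        else:
            if best is None or ss < best:
                best, best_mask = ss, sel
    return best_mask, best
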