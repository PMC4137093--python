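"""Independent reference implementations used only to check results.

Each oracle recomputes a quantity from first principles with none of the
incremental bookkeeping of the library code: the agglomerator re-derives
every cluster consensus and every pairwise distance from the member
profiles at every step; the aligner is a plain O(mn) Gotoh dynamic
program; centrality comes from a dense eigendecomposition.
"""

from __future__ import annotations

import numpy as np


def brute_force_linkage(profiles, weight_vec):
    """From-scratch consensus agglomeration.

    ``profiles`` is a list of (subject_id, bits) pairs.  Returns the merge
    list [(height, member_ids_left, member_ids_right), ...] in merge order.
    Clusters are plain member lists; at every step the consensus of every
    cluster and the distance of every cluster pair are recomputed from the
    raw member profiles.  Ties break on the lexicographically smallest pair
    of cluster representatives (smallest member id).
    """
    bits = {sid: np.asarray(b, dtype=np.int8) for sid, b in profiles}
    clusters = [[sid] for sid, _ in profiles]
    merges = []

    def consensus(members):
        out = bits[members[0]].copy()
        for sid in members[1:]:
            out &= bits[sid]
        return out

    def dist(ca, cb):
        a, b = consensus(ca), consensus(cb)
        inter = float(np.dot(weight_vec, a & b))
        union = float(np.dot(weight_vec, a | b))
        s = 0.0 if union == 0.0 else inter / union
        return 1.0 - s

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                pair = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                key = (d, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _), i, j = best
        merges.append((d, sorted(clusters[i]), sorted(clusters[j])))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def gotoh_score(a: str, b: str, matrix, gap_open: int = 11,
                gap_extend: int = 1) -> float:
    """Naive affine-gap Smith-Waterman best score.

    A gap of length k costs gap_open + k*gap_extend (the BLAST
    convention).  Three-state Gotoh recurrences, O(mn) time.
    """
    m, n = len(a), len(b)
    neg = float("-inf")
    open_cost = gap_open + gap_extend
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), neg)  # gap in a (horizontal)
    F = np.full((m + 1, n + 1), neg)  # gap in b (vertical)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - open_cost,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost,
                          F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def dense_eig_scores(adjacency: np.ndarray) -> np.ndarray:
    """Principal eigenvector of a symmetric non-negative matrix,
    non-negative orientation, unit Euclidean norm."""
    vals, vecs = np.linalg.eigh(adjacency)
    v = vecs[:, np.argmax(vals)]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)
    return v / np.linalg.norm(v)
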