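"""Alignment-pattern clustering: weighted profile similarity, consensus
linkage, and climbing-rate dendrogram cutting.

Binary conservation profiles of all hits are compared with a residue-weighted
Jaccard similarity (rare residues of the query count more), agglomerated
with a modified average-linkage scheme in which a cluster is represented by
the conserved consensus (elementwise AND) of its members, and the resulting
tree is cut where the exponential growth of sorted merge heights turns from
flat to steep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .alignments import AMINO_ACIDS, BinaryProfile, SequenceRecord

#: Robinson & Robinson background amino-acid frequencies, the standard
#: composition model of protein database searching.
ROBINSON_FREQUENCIES: dict[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

_EPS_HEIGHT = 1e-9


@dataclass(frozen=True)
class ResidueWeights:
    """Positive per-residue weights emphasising rare amino acids."""

    w: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.w)
        if missing:
            raise ValueError(f"weights missing residues {sorted(missing)}")
        if any(v <= 0 for v in self.w.values()):
            raise ValueError("all residue weights must be positive")

    def for_query(self, query: SequenceRecord) -> np.ndarray:
        """Per-position weight vector for the query sequence; unknown
        residues ('X') carry zero weight."""
        return np.array([self.w.get(c, 0.0) for c in query.residues])


def log_rarity_weights(
    frequencies: dict[str, float] | None = None,
) -> ResidueWeights:
    """w(a) = -log2 f(a): the rarer the residue, the larger its weight."""
    freqs = ROBINSON_FREQUENCIES if frequencies is None else frequencies
    return ResidueWeights({a: -math.log2(freqs[a]) for a in AMINO_ACIDS})


def optima_weights(path: str | Path | None = None) -> ResidueWeights:
    """Diagonal weights of the OPTIMA substitution matrix.

    Loaded from a two-column TSV (residue, weight), either user-supplied or
    packaged under ``remort/data/optima_weights.tsv``.
    """
    if path is None:
        ref = resources.files("remort").joinpath("data/optima_weights.tsv")
        if not ref.is_file():
            raise FileNotFoundError("weights table not found")
        text = ref.read_text()
    else:
        p = Path(path)
        if not p.is_file():
            raise FileNotFoundError("weights table not found")
        text = p.read_text()
    w = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        residue, value = line.split("\t")
        w[residue] = float(value)
    return ResidueWeights(w)


def residue_weights(query: SequenceRecord, scheme: str = "log_rarity",
                    **kwargs) -> ResidueWeights:
    """Weight table for a query under a named scheme."""
    if scheme == "log_rarity":
        return log_rarity_weights(**kwargs)
    if scheme == "optima":
        return optima_weights(**kwargs)
    raise ValueError(f"unknown weighting scheme {scheme!r}")


# ---------------------------------------------------------------------------
# similarity


def similarity(
    bits_i: np.ndarray,
    bits_j: np.ndarray,
    position_weights: np.ndarray,
) -> float:
    """Weighted Jaccard similarity of two conservation profiles.

    S = sum_p w_p * (i_p AND j_p) / sum_p w_p * (i_p OR j_p), with S = 0 for
    an empty union.  Bounded in [0, 1]; 1 iff the supports coincide.
    """
    if len(bits_i) != len(bits_j) or len(bits_i) != len(position_weights):
        raise ValueError("profile/weight length mismatch")
    inter = float(np.dot(position_weights, bits_i & bits_j))
    union = float(np.dot(position_weights, bits_i | bits_j))
    if union == 0.0:
        return 0.0
    return inter / union


def profile_similarity(p_i: BinaryProfile, p_j: BinaryProfile,
                       query: SequenceRecord,
                       weights: ResidueWeights) -> float:
    return similarity(p_i.bits, p_j.bits, weights.for_query(query))


# ---------------------------------------------------------------------------
# consensus linkage


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    consensus: np.ndarray


@dataclass
class Dendrogram:
    """Agglomeration tree over profiles.

    Nodes 0..n-1 are the leaves (in ``leaves`` order); merge k creates node
    n+k.  Each merge records its height (1 - similarity of the two
    consensus vectors) and the AND-consensus of the new cluster.
    """

    leaves: list[str]
    merges: list[Merge]

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def members(self, node: int) -> set[int]:
        """Leaf indices under a node."""
        n = len(self.leaves)
        if node < n:
            return {node}
        m = self.merges[node - n]
        return self.members(m.left) | self.members(m.right)


@dataclass
class ClusterSet:
    """A flat partition of the leaves obtained by cutting the tree."""

    clusters: list[frozenset[str]]
    cut_height: float

    def cluster_of(self, subject_id: str) -> frozenset[str]:
        for c in self.clusters:
            if subject_id in c:
                return c
        raise KeyError(f"{subject_id} not in any cluster")


def consensus_linkage(
    profiles: list[BinaryProfile],
    query: SequenceRecord,
    weights: ResidueWeights,
) -> Dendrogram:
    """Agglomerate profiles on the conserved consensus of each cluster.

    Classical average linkage compares a new profile with the *average* of a
    cluster's members, which dilutes the family-wide conservation pattern.
    Here a cluster is represented by the elementwise AND of its members'
    bits, and inter-cluster distance is d = 1 - S between the two consensus
    vectors.  Ties in the minimum distance are broken by the
    lexicographically smallest pair of cluster representative ids
    (representative = smallest member id), making runs bit-reproducible.
    """
    n = len(profiles)
    if n < 2:
        raise ValueError("need at least two profiles to cluster")
    wvec = weights.for_query(query)
    leaves = [p.subject_id for p in profiles]

    # active cluster state, keyed by node index
    consensus: dict[int, np.ndarray] = {
        i: profiles[i].bits.astype(np.int8) for i in range(n)
    }
    rep: dict[int, str] = {i: leaves[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = 1.0 - similarity(consensus[i], consensus[j], wvec)

    merges: list[Merge] = []
    active = set(range(n))
    next_node = n
    while len(active) > 1:
        best = None
        for (i, j), d in dist.items():
            pair = tuple(sorted((rep[i], rep[j])))
            key = (d, pair)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = dist[(i, j)] if (i, j) in dist else dist[(j, i)]
        new_cons = consensus[i] & consensus[j]
        merges.append(Merge(i, j, h, new_cons))
        active -= {i, j}
        dist = {k: v for k, v in dist.items()
                if i not in k and j not in k}
        consensus[next_node] = new_cons
        rep[next_node] = min(rep[i], rep[j])
        for k in sorted(active):
            dist[(k, next_node)] = 1.0 - similarity(
                consensus[k], new_cons, wvec)
        active.add(next_node)
        next_node += 1
    return Dendrogram(leaves, merges)


# ---------------------------------------------------------------------------
# cluster cutting


def fit_exponential(heights: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of y = a*exp(b*x) on log-transformed heights,
    x = 1..m; non-positive heights are clamped to a tiny epsilon."""
    m = len(heights)
    x = np.arange(1, m + 1, dtype=float)
    y = np.clip(heights.astype(float), _EPS_HEIGHT, None)
    b, loga = np.polyfit(x, np.log(y), 1)
    return math.exp(loga), b


def knee_cut_height(heights: np.ndarray) -> float | None:
    """Cut height from the climbing rate of the fitted exponential.

    Merge heights are sorted ascending; the fitted curve's instantaneous
    slope a*b*exp(b*x) is compared with the mean slope
    (y_m - y_1)/(m - 1), and the cut is placed at the fitted value of the
    first rank where the curve turns steeper than its mean trend.  Returns
    ``None`` when no cut is defined (flat distribution or non-increasing
    fit): the tree then stays one cluster.
    """
    y = np.sort(np.asarray(heights, dtype=float))
    m = len(y)
    if m < 3 or y[-1] == y[0]:
        return None
    a, b = fit_exponential(y)
    if b <= 0:
        return None
    mean_slope = (y[-1] - y[0]) / (m - 1)
    # slope of the fit is a*b*exp(b*x) = b*y, so it crosses the mean slope
    # exactly at the fitted height mean_slope/b
    cut = mean_slope / b
    if cut >= y[-1]:
        return None
    return cut


def cut_dendrogram(dend: Dendrogram) -> ClusterSet:
    """Cut the tree at the knee of its height distribution.

    Clusters are the connected components formed by all merges strictly
    below the cut height; with no defined cut, all leaves form one cluster.
    """
    n = len(dend.leaves)
    cut = knee_cut_height(dend.heights) if len(dend.merges) >= 3 else None
    if cut is None:
        return ClusterSet([frozenset(dend.leaves)],
                          cut_height=float("inf"))
    # union-find over leaves via the merge list
    parent = list(range(n + len(dend.merges)))

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for k, mrg in enumerate(dend.merges):
        node = n + k
        if mrg.height < cut:
            parent[find(mrg.left)] = node
            parent[find(mrg.right)] = node

    groups: dict[int, set[str]] = {}
    for i, leaf in enumerate(dend.leaves):
        groups.setdefault(find(i), set()).add(leaf)
    clusters = sorted((frozenset(g) for g in groups.values()),
                      key=lambda c: min(c))
    return ClusterSet(clusters, cut_height=cut)


def dump_merges_tsv(dend: Dendrogram, path) -> None:
    """Diagnostic TSV of the merge list: left, right, height."""
    n = len(dend.leaves)

    def label(node: int) -> str:
        if node < n:
            return dend.leaves[node]
        return f"cluster{node - n}"

    with open(path, "w") as fh:
        for mrg in dend.merges:
            fh.write(f"{label(mrg.left)}\t{label(mrg.right)}\t"
                     f"{mrg.height:.10g}\n")
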