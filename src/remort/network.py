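"""Typed orthology network and eigenvector-centrality scoring.

Verified orthologs plus the query form an undirected graph whose edges
encode the mutual reciprocal-search relations between two nodes:
best-best (bb), best-acceptable (ba), acceptable-acceptable (aa), and the
one-sided classes best (b) and acceptable (a).  Edge weights descend
geometrically (bb=1 ... a=0.0625), and each node's network score is its
entry in the principal eigenvector of the weighted adjacency matrix of its
connected component — a measure of how embedded the node is in the family,
independent of any search E-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignments import HitTable, SequenceRecord
from .engine import ACCEPTABLE, BEST, EngineParams, rank_relation

EDGE_WEIGHTS: dict[str, float] = {
    "bb": 1.0,
    "ba": 0.5,
    "aa": 0.25,
    "b": 0.125,
    "a": 0.0625,
}

_POWER_TOL = 1e-10
_POWER_MAX_ITER = 1000


@dataclass(frozen=True)
class OrthologyEdge:
    node_a: str
    node_b: str
    etype: str

    @property
    def weight(self) -> float:
        return EDGE_WEIGHTS[self.etype]


@dataclass
class NodeInfo:
    species: str
    e_value: float | None
    network_score: float = 0.0


@dataclass
class OrthologyNetwork:
    """Undirected simple graph of the query and its verified orthologs."""

    nodes: dict[str, NodeInfo] = field(default_factory=dict)
    edges: list[OrthologyEdge] = field(default_factory=list)

    def adjacency(self, order: list[str]) -> np.ndarray:
        idx = {n: i for i, n in enumerate(order)}
        A = np.zeros((len(order), len(order)))
        for e in self.edges:
            if e.node_a in idx and e.node_b in idx:
                i, j = idx[e.node_a], idx[e.node_b]
                A[i, j] = A[j, i] = e.weight
        return A

    def components(self) -> list[list[str]]:
        ids = sorted(self.nodes)
        neigh: dict[str, set[str]] = {n: set() for n in ids}
        for e in self.edges:
            neigh[e.node_a].add(e.node_b)
            neigh[e.node_b].add(e.node_a)
        seen: set[str] = set()
        comps = []
        for start in ids:
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                v = stack.pop()
                comp.append(v)
                for u in neigh[v]:
                    if u not in seen:
                        seen.add(u)
                        stack.append(u)
            comps.append(sorted(comp))
        return comps


def classify_edge(rel_ab: str | None, rel_ba: str | None) -> str | None:
    """Edge class from the two directed relations (best/acceptable/None)."""
    rels = {rel_ab, rel_ba}
    if rel_ab in (BEST, ACCEPTABLE) and rel_ba in (BEST, ACCEPTABLE):
        if rels == {BEST}:
            return "bb"
        if rels == {BEST, ACCEPTABLE}:
            return "ba"
        return "aa"
    one_sided = rel_ab if rel_ab in (BEST, ACCEPTABLE) else rel_ba
    if one_sided == BEST:
        return "b"
    if one_sided == ACCEPTABLE:
        return "a"
    return None


def directed_relation(
    table: HitTable,
    searcher_id: str,
    target: SequenceRecord,
    params: EngineParams,
) -> str | None:
    """Relation of the searcher towards ``target``: rank of the target among
    the searcher's hits within the target's species."""
    rank = table.best_per_subject().rank_in_species(
        target.id, target.species, exclude=searcher_id)
    rel = rank_relation(rank, params)
    return rel if rel in (BEST, ACCEPTABLE) else None


def build_network(
    query: SequenceRecord,
    verified: list[str],
    records: dict[str, SequenceRecord],
    searches: dict[str, HitTable],
    params: EngineParams | None = None,
) -> OrthologyNetwork:
    """Assemble the typed network from the cached reciprocal searches."""
    params = params or EngineParams()
    net = OrthologyNetwork()
    members = [query.id] + [v for v in verified if v != query.id]
    e_values = {aln.subject_id: aln.e_value
                for aln in searches[query.id].best_per_subject()}
    for sid in members:
        rec = records[sid]
        net.nodes[sid] = NodeInfo(rec.species, e_values.get(sid))
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            rel_ab = directed_relation(searches[a], a, records[b], params) \
                if a in searches else None
            rel_ba = directed_relation(searches[b], b, records[a], params) \
                if b in searches else None
            etype = classify_edge(rel_ab, rel_ba)
            if etype is not None:
                na, nb = sorted((a, b))
                net.edges.append(OrthologyEdge(na, nb, etype))
    net.edges.sort(key=lambda e: (e.node_a, e.node_b))
    return net


def centrality(net: OrthologyNetwork) -> dict[str, float]:
    """Eigenvector centrality per connected component.

    Power iteration with the standard +I shift (the behaviour of the
    commonly used graph-library implementation): x <- (A + I) x, L2
    normalised, from a uniform positive start.  The shift leaves the
    principal eigenvector unchanged while guaranteeing convergence on
    bipartite components.  Scores are L2-normalised within each component;
    an isolated node scores 1 by the unit-norm convention.
    """
    if not net.nodes:
        raise ValueError("empty network")
    scores: dict[str, float] = {}
    for comp in net.components():
        if len(comp) == 1:
            scores[comp[0]] = 1.0
            continue
        A = net.adjacency(comp)
        x = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
        for _ in range(_POWER_MAX_ITER):
            x_new = x + A @ x
            x_new /= np.linalg.norm(x_new)
            if np.max(np.abs(x_new - x)) < _POWER_TOL:
                x = x_new
                break
            x = x_new
        else:
            raise RuntimeError(
                f"centrality failed to converge on component {comp}")
        x = np.abs(x)
        for node, s in zip(comp, x):
            scores[node] = float(s)
    for node, s in scores.items():
        net.nodes[node].network_score = s
    return scores


# ---------------------------------------------------------------------------
# export


def export_sif(net: OrthologyNetwork, path_sif: str | Path,
               path_attr: str | Path) -> None:
    """Cytoscape SIF plus node-attribute TSV, deterministically sorted."""
    with open(path_sif, "w") as fh:
        for e in sorted(net.edges, key=lambda e: (e.node_a, e.node_b)):
            fh.write(f"{e.node_a}\t{e.etype}\t{e.node_b}\n")
        connected = {e.node_a for e in net.edges} | \
                    {e.node_b for e in net.edges}
        for node in sorted(set(net.nodes) - connected):
            fh.write(f"{node}\n")
    with open(path_attr, "w") as fh:
        fh.write("id\tspecies\te_value\tnetwork_score\n")
        for node in sorted(net.nodes):
            info = net.nodes[node]
            ev = "" if info.e_value is None else f"{info.e_value:.6g}"
            fh.write(f"{node}\t{info.species}\t{ev}\t"
                     f"{info.network_score:.10f}\n")


def read_sif(path_sif: str | Path, path_attr: str | Path
             ) -> OrthologyNetwork:
    """Rebuild a scored network from its exported pair of files."""
    net = OrthologyNetwork()
    for line in Path(path_attr).read_text().splitlines()[1:]:
        sid, species, ev, score = line.split("\t")
        net.nodes[sid] = NodeInfo(species,
                                  float(ev) if ev else None,
                                  float(score))
    for line in Path(path_sif).read_text().splitlines():
        parts = line.split("\t")
        if len(parts) == 3:
            net.edges.append(OrthologyEdge(parts[0], parts[2], parts[1]))
    return net


def rank_results(net: OrthologyNetwork) -> list[dict]:
    """Result table: descending network score, ties by ascending E-value
    then id."""
    rows = [
        {"id": sid, "species": info.species,
         "network_score": info.network_score, "e_value": info.e_value}
        for sid, info in net.nodes.items()
    ]
    rows.sort(key=lambda r: (-r["network_score"],
                             r["e_value"] if r["e_value"] is not None
                             else float("inf"),
                             r["id"]))
    return rows
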