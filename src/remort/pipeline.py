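"""End-to-end orchestration: search, binarize, cluster, verify, score.

``run`` wires the stages together and writes a reproducible result bundle
(ranked hit table, Cytoscape network files, audit log, manifest);
``evaluate`` computes recall/precision/accuracy/F1 against a known truth
set, as produced by the synthetic-family generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignments import HitTable, SequenceRecord, binarize, load_matrix
from .clustering import (
    ClusterSet,
    Dendrogram,
    consensus_linkage,
    cut_dendrogram,
    dump_merges_tsv,
    residue_weights,
)
from .engine import EngineParams, EngineResult, run_engine
from .network import (
    OrthologyNetwork,
    build_network,
    centrality,
    export_sif,
    rank_results,
)
from .search import SearchBackend, SearchConfig


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one run depends on; defaults are the method's standard
    operating point (relaxed E-threshold 100, strict RBH below 1e-5,
    one-third rejection vote, 80% identity auto-selection)."""

    backend: str = "internal"
    search: SearchConfig = field(default_factory=SearchConfig)
    engine: EngineParams = field(default_factory=EngineParams)
    weight_scheme: str = "log_rarity"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "backend": self.backend,
            "search": vars(self.search).copy(),
            "engine": vars(self.engine).copy(),
            "weight_scheme": self.weight_scheme,
            "seed": self.seed,
        }


@dataclass
class RunResult:
    query: SequenceRecord
    hits: HitTable
    dendrogram: Dendrogram
    clusters: ClusterSet
    engine: EngineResult
    network: OrthologyNetwork
    scores: dict[str, float]
    table: list[dict]
    manifest: dict


def run(
    query: SequenceRecord,
    backend: SearchBackend,
    db_id: str,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> RunResult:
    """Execute the full pipeline for one query.

    Stages: relaxed search -> per-subject profile binarization ->
    consensus-linkage clustering and knee cut -> iterative reciprocal
    verification -> network construction and centrality scoring.  With
    ``outdir`` set, writes results.tsv, network.sif, attributes.tsv,
    audit.jsonl, merges.tsv and manifest.json.
    """
    config = config or RunConfig()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    hits = stage("search",
                 lambda: backend.search(query, db_id, config.search))
    if hits.oversized:
        raise StageError("search", RuntimeError(
            "more than the configured maximum of hits found; the family "
            "is a candidate for phylogenetic methods instead"))
    deduped = hits.best_per_subject()

    matrix = load_matrix(config.search.matrix)
    profiles = stage("binarize", lambda: [
        binarize(aln, len(query), matrix) for aln in deduped])

    weights = residue_weights(query, config.weight_scheme)
    dend = stage("cluster",
                 lambda: consensus_linkage(profiles, query, weights))
    clusters = stage("cut", lambda: cut_dendrogram(dend))

    engine_result = stage("verify", lambda: run_engine(
        query, deduped, clusters, backend, db_id, config.search,
        config.engine))

    records = {query.id: query}
    for sid in engine_result.verified:
        records[sid] = backend.sequence(db_id, sid)
    net = stage("network", lambda: build_network(
        query, engine_result.verified, records, engine_result.searches,
        config.engine))
    scores = stage("score", lambda: centrality(net))
    table = rank_results(net)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "query": query.id,
        "db_id": db_id,
        "counts": {
            "hits": len(hits),
            "profiles": len(profiles),
            "clusters": len(clusters.clusters),
            "reciprocal_searches": len(engine_result.searches) - 1,
            "verified": len(engine_result.verified),
            "dropped_query_only": len(engine_result.dropped_query_only),
            "rounds": engine_result.rounds,
        },
    }

    result = RunResult(query, deduped, dend, clusters, engine_result, net,
                       scores, table, manifest)
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def write_bundle(result: RunResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "results.tsv", "w") as fh:
        fh.write("id\tspecies\tnetwork_score\te_value\n")
        for row in result.table:
            ev = "" if row["e_value"] is None else f"{row['e_value']:.6g}"
            fh.write(f"{row['id']}\t{row['species']}\t"
                     f"{row['network_score']:.10f}\t{ev}\n")
    export_sif(result.network, outdir / "network.sif",
               outdir / "attributes.tsv")
    with open(outdir / "audit.jsonl", "w") as fh:
        for entry in result.engine.audit:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    dump_merges_tsv(result.dendrogram, outdir / "merges.tsv")
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True))


def evaluate(predicted: set[str], truth: set[str],
             initial_hits: set[str] | None = None,
             query_id: str | None = None) -> dict:
    """Recall, precision, accuracy and F1 of a prediction set.

    ``initial_hits`` (the relaxed-search universe) supplies the true
    negatives: non-truth hits that were not reported.  A run with no true
    positives reports precision/recall 0 with a ``degenerate`` flag.
    """
    if not truth:
        raise ValueError("empty truth set")
    predicted = set(predicted)
    truth = set(truth)
    if query_id is not None:
        predicted.discard(query_id)
        truth.discard(query_id)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = 0
    if initial_hits is not None:
        universe = set(initial_hits)
        if query_id is not None:
            universe.discard(query_id)
        tn = len((universe - truth) - predicted)
    degenerate = tp == 0
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    accuracy = ((tp + tn) / (tp + tn + fp + fn)
                if tp + tn + fp + fn else 0.0)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "recall": recall, "precision": precision,
        "accuracy": accuracy, "f1": f1,
        "degenerate": degenerate,
    }
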