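"""Iterative reciprocal-best-hit orthology verification.

Starting from the relaxed search results and the alignment-pattern
clusters, candidates are selected (high identity to the query, or
co-membership in the query's cluster), submitted to reciprocal searches,
and judged: statistically reliable candidates (E < 1e-5 to the query) must
satisfy the strict reciprocal-best-hit rule against the query; weaker
candidates survive unless more than a third of the current bona fide
orthologs reject them.  Verified orthologs recruit further candidates
(their cluster co-members, and anything found as an RBH by more than two of
them) until no new candidates appear.  Hits supported by the query alone
are dropped from the final output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .alignments import HitTable, SequenceRecord
from .clustering import ClusterSet
from .search import SearchBackend, SearchConfig

BEST = "best"
ACCEPTABLE = "acceptable"
REJECTED = "rejected"


@dataclass(frozen=True)
class EngineParams:
    """Decision thresholds of the verification stage.

    Defaults are the method's standard operating point: candidates above 80%
    identity to the query are auto-selected; E < 1e-5 triggers the strict
    RBH rule; weak candidates are excluded when rejected by more than a
    third of the bona fide orthologs; a reciprocal rank of 2-3 within a
    species still counts as acceptable support; subjects found as RBH by
    more than two verified orthologs are recruited.
    """

    identity_select: float = 80.0
    strict_e: float = 1e-5
    reject_fraction: float = 1.0 / 3.0
    max_acceptable_rank: int = 3
    min_supporters_beyond_query: int = 1
    multi_support_select: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.reject_fraction < 1:
            raise ValueError("reject_fraction must be in (0, 1)")
        if min(self.identity_select, self.strict_e) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ReciprocalReport:
    """Outcome of one candidate's reciprocal search against the current
    bona fide orthologs: per ortholog, its rank among the candidate's hits
    restricted to the ortholog's species, and the derived relation."""

    candidate_id: str
    ranks: dict[str, int | None] = field(default_factory=dict)
    relations: dict[str, str] = field(default_factory=dict)

    @property
    def rejectors(self) -> set[str]:
        return {o for o, r in self.relations.items() if r == REJECTED}

    @property
    def supporters(self) -> set[str]:
        return {o for o, r in self.relations.items()
                if r in (BEST, ACCEPTABLE)}


@dataclass
class EngineResult:
    """Verified orthologs plus full provenance of every decision."""

    verified: list[str]
    reports: dict[str, ReciprocalReport]
    supporters: dict[str, set[str]]
    audit: list[dict]
    searches: dict[str, HitTable]
    dropped_query_only: list[str]
    rounds: int


def rank_relation(rank: int | None, params: EngineParams) -> str:
    if rank == 1:
        return BEST
    if rank is not None and 2 <= rank <= params.max_acceptable_rank:
        return ACCEPTABLE
    return REJECTED


def initial_candidates(
    hits: HitTable,
    clusters: ClusterSet,
    query_id: str,
    params: EngineParams,
) -> set[str]:
    """Seed candidates: >80% identity to the query, plus every member of
    the cluster that contains the query's own (all-match) profile."""
    query_cluster = clusters.cluster_of(query_id)
    selected = {aln.subject_id for aln in hits
                if aln.percent_identity > params.identity_select}
    selected |= set(query_cluster)
    selected.discard(query_id)
    return selected


def expand_candidates(
    selected: set[str],
    clusters: ClusterSet,
    rbh_counts: dict[str, int],
    params: EngineParams,
) -> set[str]:
    """Candidate recruitment: cluster co-members of anything selected, and
    subjects found as an RBH by more than ``multi_support_select`` verified
    orthologs."""
    expanded = set(selected)
    for sid in selected:
        try:
            expanded |= set(clusters.cluster_of(sid))
        except KeyError:
            pass  # recruited subject absent from the clustered hit set
    expanded |= {sid for sid, n in rbh_counts.items()
                 if n > params.multi_support_select}
    return expanded


def reciprocal_report(
    candidate: SequenceRecord,
    verified: dict[str, SequenceRecord],
    search: Callable[[SequenceRecord], HitTable],
    params: EngineParams,
) -> ReciprocalReport:
    """Rank each bona fide ortholog among the candidate's reciprocal hits
    within that ortholog's species (the candidate's own self-hit is
    ignored when ranking)."""
    table = search(candidate).best_per_subject()
    report = ReciprocalReport(candidate.id)
    for oid, orec in verified.items():
        rank = table.rank_in_species(oid, orec.species,
                                     exclude=candidate.id)
        report.ranks[oid] = rank
        report.relations[oid] = rank_relation(rank, params)
    return report


def decide(
    report: ReciprocalReport,
    e_value_to_query: float | None,
    query_id: str,
    n_verified: int,
    params: EngineParams,
) -> tuple[bool, str]:
    """Accept or reject one candidate; returns (verified?, rule fired).

    E < 1e-5 to the query: strict RBH — the candidate's top reciprocal hit
    in the query's species must be the query.  Otherwise the candidate is
    rejected only when more than ``reject_fraction`` of the current bona
    fide orthologs reject it.
    """
    if n_verified < 1:
        raise ValueError("decision requires at least one bona fide ortholog")
    if e_value_to_query is not None and e_value_to_query < params.strict_e:
        ok = report.relations.get(query_id) == BEST
        return ok, "strict_rbh"
    frac = len(report.rejectors) / n_verified
    if frac > params.reject_fraction:
        return False, "reject_fraction"
    return True, "reject_fraction"


def run_engine(
    query: SequenceRecord,
    hits: HitTable,
    clusters: ClusterSet,
    backend: SearchBackend,
    db_id: str,
    config: SearchConfig,
    params: EngineParams | None = None,
) -> EngineResult:
    """Run selection / reciprocal search / decision / expansion to a fixed
    point, then apply the query-alone exclusion.

    The candidate set grows monotonically and is bounded by the database,
    so the loop terminates.  Iteration order (ascending E-value to the
    query, then id) and cached searches make runs deterministic.
    """
    params = params or EngineParams()
    if hits.oversized:
        raise RuntimeError(
            "initial search exceeded the hit cap: the family is likely "
            "multi-branching with enough similarity for phylogenetic "
            "methods; not suited to this pipeline")

    hits = hits.best_per_subject()
    e_to_query = {aln.subject_id: aln.e_value for aln in hits}

    search_cache: dict[str, HitTable] = {query.id: hits}

    def cached_search(rec: SequenceRecord) -> HitTable:
        if rec.id not in search_cache:
            search_cache[rec.id] = backend.search(rec, db_id, config)
        return search_cache[rec.id]

    def record(sid: str) -> SequenceRecord:
        return query if sid == query.id else backend.sequence(db_id, sid)

    audit: list[dict] = []
    selected = initial_candidates(hits, clusters, query.id, params)
    audit.append({"event": "initial_selection",
                  "candidates": sorted(selected)})

    decided: dict[str, bool] = {}
    reports: dict[str, ReciprocalReport] = {}
    verified: list[str] = []
    rounds = 0

    def sort_key(sid: str):
        return (e_to_query.get(sid, float("inf")), sid)

    while True:
        rounds += 1
        bona_fide = {query.id: query}
        bona_fide.update({v: record(v) for v in verified})
        pending = sorted((s for s in selected if s not in decided),
                         key=sort_key)
        newly_verified = []
        for sid in pending:
            try:
                rep = reciprocal_report(record(sid), bona_fide,
                                        cached_search, params)
            except Exception as exc:  # search failure: stays pending
                audit.append({"event": "search_failed", "candidate": sid,
                              "error": str(exc)})
                continue
            reports[sid] = rep
            ok, rule = decide(rep, e_to_query.get(sid), query.id,
                              len(bona_fide), params)
            decided[sid] = ok
            if ok:
                newly_verified.append(sid)
            audit.append({
                "event": "decision", "candidate": sid, "rule": rule,
                "verified": ok,
                "e_value_to_query": e_to_query.get(sid),
                "supporters": sorted(rep.supporters),
                "rejectors": sorted(rep.rejectors),
                "n_bona_fide": len(bona_fide),
            })
        verified.extend(newly_verified)

        # the query counts among the bona fide RBH finders
        rbh_counts = _rbh_counts([query.id] + verified, record,
                                 cached_search, db_id)
        expanded = expand_candidates(selected, clusters, rbh_counts, params)
        expanded.discard(query.id)
        new = expanded - selected
        if not new and not pending:
            break
        if new:
            audit.append({"event": "expansion", "added": sorted(new),
                          "rbh_counts": {k: v for k, v in
                                         sorted(rbh_counts.items())
                                         if v > params.multi_support_select}})
        selected = expanded

    # final pass: recompute support against the full verified set and drop
    # hits the query alone vouches for
    final_bona_fide = {query.id: query}
    final_bona_fide.update({v: record(v) for v in verified})
    supporters: dict[str, set[str]] = {}
    kept, dropped = [], []
    for sid in verified:
        others = {k: v for k, v in final_bona_fide.items() if k != sid}
        rep = reciprocal_report(record(sid), others, cached_search, params)
        reports[sid] = rep
        supporters[sid] = rep.supporters
        if rep.supporters - {query.id}:
            kept.append(sid)
        else:
            dropped.append(sid)
            audit.append({"event": "query_only_exclusion", "candidate": sid,
                          "supporters": sorted(rep.supporters)})

    return EngineResult(
        verified=sorted(kept, key=sort_key),
        reports=reports,
        supporters=supporters,
        audit=audit,
        searches=search_cache,
        dropped_query_only=sorted(dropped),
        rounds=rounds,
    )


def _rbh_counts(
    verified: list[str],
    record: Callable[[str], SequenceRecord],
    cached_search: Callable[[SequenceRecord], HitTable],
    db_id: str,
) -> dict[str, int]:
    """For every subject, count the bona fide orthologs (query included)
    whose searches find it as a reciprocal best hit (mutual rank 1 within
    species)."""
    counts: dict[str, int] = {}
    for vid in verified:
        vrec = record(vid)
        table = cached_search(vrec).best_per_subject()
        tops: dict[str, str] = {}
        for aln in table:
            sp = aln.subject_species
            if aln.subject_id != vid and sp not in tops:
                tops[sp] = aln.subject_id
        for sid in tops.values():
            try:
                srec = record(sid)
            except KeyError:
                continue
            back = cached_search(srec).best_per_subject()
            if back.rank_in_species(vid, vrec.species, exclude=sid) == 1:
                counts[sid] = counts.get(sid, 0) + 1
    return counts
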