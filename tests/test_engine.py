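"""Verification-rule tests on hand-built reciprocal-search scenarios.

Each scenario encodes one decision rule in isolation inside a canned
FixtureBackend world, and the expected outcome is derived by hand from the
rule statement.
"""

import pytest

from remort.alignments import HitTable, PairwiseAlignment, SequenceRecord
from remort.clustering import ClusterSet
from remort.engine import (
    ACCEPTABLE,
    BEST,
    REJECTED,
    EngineParams,
    ReciprocalReport,
    decide,
    expand_candidates,
    initial_candidates,
    rank_relation,
    reciprocal_report,
    run_engine,
)
from remort.search import FixtureBackend, SearchConfig

PARAMS = EngineParams()
QUERY = SequenceRecord("q", "sp_q", "MKVLWAALLV")


def aln(sid, species, e_value, pident=50.0):
    return PairwiseAlignment("q", sid, species, e_value, pident, 1, 3,
                             "MKV", "MRV")


def row(sid, species, e_value, pident=50.0):
    return {"subject_id": sid, "subject_species": species,
            "e_value": e_value, "percent_identity": pident,
            "query_start": 1, "query_end": 3,
            "aligned_query": "MKV", "aligned_subject": "MRV"}


def world(results, sequences):
    """FixtureBackend over db 'd'; sequences maps id -> species."""
    seqs = {sid: [sp, "MKVLWAALLV"] for sid, sp in sequences.items()}
    return FixtureBackend({"version": 1,
                           "results": {"d": results},
                           "sequences": {"d": seqs}})


class TestRankRelation:
    @pytest.mark.parametrize("rank,relation", [
        (1, BEST), (2, ACCEPTABLE), (3, ACCEPTABLE),
        (4, REJECTED), (None, REJECTED),
    ])
    def test_rank_to_relation(self, rank, relation):
        assert rank_relation(rank, PARAMS) == relation


class TestInitialCandidates:
    def clusters(self):
        return ClusterSet([frozenset({"q", "in_cluster"}),
                           frozenset({"far", "high_id", "boundary"})], 0.5)

    def test_identity_boundary_is_strict(self):
        hits = HitTable("q", [aln("high_id", "s1", 1.0, 80.1),
                              aln("boundary", "s2", 1.0, 80.0),
                              aln("in_cluster", "s3", 5.0, 12.0)])
        got = initial_candidates(hits, self.clusters(), "q", PARAMS)
        assert "high_id" in got       # >80% identity
        assert "boundary" not in got  # exactly 80% is not selected
        assert "in_cluster" in got    # query-cluster membership suffices

    def test_missing_query_cluster_is_an_error(self):
        hits = HitTable("q", [])
        with pytest.raises(KeyError):
            initial_candidates(hits, ClusterSet([frozenset({"x"})], 0.5),
                               "q", PARAMS)


class TestExpandCandidates:
    def test_rbh_count_boundary_is_strict(self):
        clusters = ClusterSet([frozenset({"a"})], 0.5)
        got = expand_candidates({"a"}, clusters,
                                {"three": 3, "two": 2}, PARAMS)
        assert "three" in got   # found as RBH by more than two
        assert "two" not in got

    def test_cluster_co_members_are_recruited(self):
        clusters = ClusterSet([frozenset({"a", "b", "c", "d", "e"})], 0.5)
        got = expand_candidates({"a"}, clusters, {}, PARAMS)
        assert got >= {"a", "b", "c", "d", "e"}


class TestDecide:
    def report(self, relations):
        rep = ReciprocalReport("cand")
        rep.relations = dict(relations)
        return rep

    def test_two_of_six_rejectors_is_retained(self):
        rels = {f"o{i}": BEST for i in range(4)}
        rels.update({"o4": REJECTED, "o5": REJECTED})
        ok, rule = decide(self.report(rels), 1.0, "q", 6, PARAMS)
        assert ok and rule == "reject_fraction"  # 2/6 is not > 1/3

    def test_three_of_six_rejectors_is_rejected(self):
        rels = {f"o{i}": BEST for i in range(3)}
        rels.update({f"o{i}": REJECTED for i in range(3, 6)})
        ok, _ = decide(self.report(rels), 1.0, "q", 6, PARAMS)
        assert not ok  # 3/6 exceeds 1/3

    def test_strict_rbh_rejects_non_best_at_low_evalue(self):
        ok, rule = decide(self.report({"q": ACCEPTABLE}), 1e-8, "q", 1,
                          PARAMS)
        assert not ok and rule == "strict_rbh"
        ok, _ = decide(self.report({"q": BEST}), 1e-8, "q", 1, PARAMS)
        assert ok

    def test_weak_evalue_escapes_strict_rule(self):
        # same non-best relation, but statistically unreliable E-value:
        # the 33% vote applies and a single supporter is no rejection
        ok, rule = decide(self.report({"q": ACCEPTABLE}), 1.0, "q", 1,
                          PARAMS)
        assert ok and rule == "reject_fraction"

    def test_adding_a_rejector_never_flips_to_verified(self):
        rels = {f"o{i}": BEST for i in range(6)}
        previous = True
        for i in range(6):
            rels[f"o{i}"] = REJECTED
            ok, _ = decide(self.report(rels), 1.0, "q", 6, PARAMS)
            assert not (ok and not previous)
            previous = ok
        assert not previous

    def test_empty_bona_fide_set_is_an_error(self):
        with pytest.raises(ValueError):
            decide(self.report({}), 1.0, "q", 0, PARAMS)


class TestReciprocalReport:
    def test_ranks_are_per_species_and_self_excluded(self):
        backend = world(
            {"cand": [row("cand", "sp_c", 1e-40), row("o1", "sp_1", 0.01),
                      row("x1", "sp_1", 0.5), row("x2", "sp_1", 0.6),
                      row("o2", "sp_2", 2.0)]},
            {"cand": "sp_c", "o1": "sp_1", "o2": "sp_2"})
        cand = backend.sequence("d", "cand")
        verified = {"o1": SequenceRecord("o1", "sp_1", "MKV"),
                    "o2": SequenceRecord("o2", "sp_2", "MKV"),
                    "missing": SequenceRecord("missing", "sp_3", "MKV")}
        rep = reciprocal_report(
            cand, verified,
            lambda rec: backend.search(rec, "d", SearchConfig()), PARAMS)
        assert rep.ranks["o1"] == 1 and rep.relations["o1"] == BEST
        assert rep.ranks["o2"] == 1  # own species, self-hit ignored
        assert rep.ranks["missing"] is None
        assert rep.relations["missing"] == REJECTED


class TestRunEngine:
    """End-to-end engine runs on small canned worlds."""

    def two_ortholog_world(self):
        # c1, c2 weakly similar to q; each finds q best in sp_q and the
        # other best in its species -> both verified, mutual support
        results = {
            "q": [row("q", "sp_q", 1e-60, 100.0), row("c1", "sp_1", 1.0),
                  row("c2", "sp_2", 2.0)],
            "c1": [row("c1", "sp_1", 1e-60), row("q", "sp_q", 1.0),
                   row("c2", "sp_2", 1.5)],
            "c2": [row("c2", "sp_2", 1e-60), row("q", "sp_q", 2.0),
                   row("c1", "sp_1", 1.0)],
        }
        sequences = {"q": "sp_q", "c1": "sp_1", "c2": "sp_2"}
        clusters = ClusterSet([frozenset({"q", "c1", "c2"})], 0.9)
        return world(results, sequences), clusters

    def test_mutually_supported_orthologs_are_verified(self):
        backend, clusters = self.two_ortholog_world()
        hits = backend.search(QUERY, "d", SearchConfig())
        res = run_engine(QUERY, hits, clusters, backend, "d",
                         SearchConfig(), PARAMS)
        assert res.verified == ["c1", "c2"]
        assert res.supporters["c1"] >= {"q", "c2"}

    def test_query_alone_supported_hit_is_dropped(self):
        # c1 finds only q reciprocally; no other ortholog ever accepts it
        results = {
            "q": [row("q", "sp_q", 1e-60, 100.0), row("c1", "sp_1", 1.0)],
            "c1": [row("c1", "sp_1", 1e-60), row("q", "sp_q", 1.0)],
        }
        backend = world(results, {"q": "sp_q", "c1": "sp_1"})
        clusters = ClusterSet([frozenset({"q", "c1"})], 0.9)
        hits = backend.search(QUERY, "d", SearchConfig())
        res = run_engine(QUERY, hits, clusters, backend, "d",
                         SearchConfig(), PARAMS)
        assert res.verified == []
        assert res.dropped_query_only == ["c1"]

    def test_strict_rbh_rejection_inside_engine(self):
        # cand has E=1e-8 to q but its top reciprocal hit in sp_q is a
        # paralog of q, so the strict rule rejects it
        results = {
            "q": [row("q", "sp_q", 1e-60, 100.0), row("cand", "sp_1", 1e-8)],
            "cand": [row("cand", "sp_1", 1e-60), row("para", "sp_q", 1e-9),
                     row("q", "sp_q", 1e-8)],
        }
        backend = world(results, {"q": "sp_q", "cand": "sp_1",
                                  "para": "sp_q"})
        clusters = ClusterSet([frozenset({"q", "cand"})], 0.9)
        hits = backend.search(QUERY, "d", SearchConfig())
        res = run_engine(QUERY, hits, clusters, backend, "d",
                         SearchConfig(), PARAMS)
        assert res.verified == []
        decisions = [e for e in res.audit if e.get("candidate") == "cand"
                     and e["event"] == "decision"]
        assert decisions[0]["rule"] == "strict_rbh"

    def test_no_candidates_terminates_after_one_round(self):
        results = {"q": [row("q", "sp_q", 1e-60, 100.0)]}
        backend = world(results, {"q": "sp_q"})
        clusters = ClusterSet([frozenset({"q"})], 0.9)
        hits = backend.search(QUERY, "d", SearchConfig())
        res = run_engine(QUERY, hits, clusters, backend, "d",
                         SearchConfig(), PARAMS)
        assert res.verified == []
        assert res.rounds == 1

    def test_permuted_hit_order_gives_identical_outcome(self):
        backend, clusters = self.two_ortholog_world()
        hits = backend.search(QUERY, "d", SearchConfig())
        permuted = HitTable("q", list(reversed(hits.hits)))
        r1 = run_engine(QUERY, hits, clusters, backend, "d",
                        SearchConfig(), PARAMS)
        r2 = run_engine(QUERY, permuted, clusters, backend, "d",
                        SearchConfig(), PARAMS)
        assert r1.verified == r2.verified
        assert r1.supporters == r2.supporters

    def test_oversized_hit_table_aborts_with_recommendation(self):
        backend, clusters = self.two_ortholog_world()
        hits = backend.search(QUERY, "d", SearchConfig())
        hits.oversized = True
        with pytest.raises(RuntimeError, match="phylogenetic"):
            run_engine(QUERY, hits, clusters, backend, "d",
                       SearchConfig(), PARAMS)


def test_engine_recovers_planted_family_from_generator_truth():
    """Full synthetic world: every planted ortholog is verified and at
    most the occasional composition-matched paralog sneaks in."""
    from remort.pipeline import run
    from remort.search import InternalBackend
    from remort.synthetic import FamilySpec, generate

    world_ = generate(FamilySpec(seed=11, n_species=12, n_decoys=25))
    be = InternalBackend()
    be.register("db", world_.database)
    res = run(world_.query, be, "db")
    verified = set(res.engine.verified)
    truth = world_.truth - {world_.query.id}
    assert truth <= verified
    assert len(verified - truth) <= 1
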