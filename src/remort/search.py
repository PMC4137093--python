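"""Sequence-search backends behind a single deterministic contract.

Three interchangeable implementations produce :class:`HitTable` objects:

* ``InternalBackend`` — affine-gap Smith–Waterman local alignment over an
  in-memory FASTA database, with a Karlin–Altschul-shaped E-value proxy.
  No external binary needed; every downstream decision depends only on
  E-value order and two absolute cutoffs, which the proxy preserves.
* ``BlastBackend`` — thin adapter around the ``blastp`` executable, using
  the canonical tabular dialect of :mod:`remort.alignments`.
* ``FixtureBackend`` — canned JSON results for tests.

All backends are deterministic: identical inputs give identical tables.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import Align

from .alignments import (
    BLAST_OUTFMT_COLUMNS,
    HitTable,
    PairwiseAlignment,
    SequenceRecord,
    load_matrix,
    read_blast_tabular,
    write_fasta,
)

#: bits-per-score-unit scaling of the internal E-value proxy
LAMBDA_BITS = 0.267


@dataclass(frozen=True)
class SearchConfig:
    """Search-stage parameters.

    ``e_threshold`` defaults to the relaxed cutoff of 100 used to sample a
    large sequence space around remote homologs; ``max_hits`` caps runs on
    multi-branching families (searches exceeding it are flagged oversized
    and should be handed to phylogenetic methods instead).
    """

    e_threshold: float = 100.0
    max_hits: int = 1500
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be positive")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


def _aligner(config: SearchConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_matrix(config.matrix)
    # BLAST convention: a gap of length k costs gap_open + k*gap_extend
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def e_value_proxy(score: float, m: int, n: int) -> float:
    """Monotone Karlin–Altschul-shaped transform of a raw local score:
    E = m*n*2^(-lambda'*s).  Preserves E-value order for fixed lengths."""
    return m * n * 2.0 ** (-LAMBDA_BITS * score)


def sw_align(a: SequenceRecord, b: SequenceRecord,
             config: SearchConfig | None = None,
             aligner: Align.PairwiseAligner | None = None,
             ) -> PairwiseAlignment | None:
    """Best affine-gap local alignment of ``b`` (subject) against ``a``
    (query), or ``None`` when no positive-scoring alignment exists."""
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    config = config or SearchConfig()
    if aligner is None:
        aligner = _aligner(config)
    score = aligner.score(a.residues, b.residues)
    if score <= 0:
        return None
    aln = aligner.align(a.residues, b.residues)[0]
    aq, asub = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(aq, asub) if x == y and x != "-")
    qstart = int(aln.coordinates[0][0]) + 1
    qend = int(aln.coordinates[0][-1])
    return PairwiseAlignment(
        query_id=a.id,
        subject_id=b.id,
        subject_species=b.species,
        e_value=e_value_proxy(score, len(a), len(b)),
        percent_identity=100.0 * matches / len(aq),
        query_start=qstart,
        query_end=qend,
        aligned_query=aq,
        aligned_subject=asub,
    )


class SearchBackend:
    """Contract: ``search(query, db_id, config) -> HitTable``."""

    def search(self, query: SequenceRecord, db_id: str,
               config: SearchConfig) -> HitTable:
        raise NotImplementedError

    def sequence(self, db_id: str, subject_id: str) -> SequenceRecord:
        raise NotImplementedError


class InternalBackend(SearchBackend):
    """Deterministic in-process search over registered FASTA databases."""

    def __init__(self) -> None:
        self._dbs: dict[str, dict[str, SequenceRecord]] = {}

    def register(self, db_id: str, records: list[SequenceRecord]) -> None:
        by_id: dict[str, SequenceRecord] = {}
        for rec in records:
            if rec.id in by_id:
                raise ValueError(f"duplicate id {rec.id} in database {db_id}")
            by_id[rec.id] = rec
        self._dbs[db_id] = by_id

    @property
    def databases(self) -> set[str]:
        return set(self._dbs)

    def sequence(self, db_id: str, subject_id: str) -> SequenceRecord:
        return self._dbs[db_id][subject_id]

    def search(self, query: SequenceRecord, db_id: str,
               config: SearchConfig | None = None) -> HitTable:
        if db_id not in self._dbs:
            raise KeyError(f"unknown database {db_id!r}")
        config = config or SearchConfig()
        aligner = _aligner(config)
        hits = []
        for sid in sorted(self._dbs[db_id]):  # order-independent results
            aln = sw_align(query, self._dbs[db_id][sid], config, aligner)
            if aln is not None and aln.e_value <= config.e_threshold:
                hits.append(aln)
        oversized = len(hits) > config.max_hits
        table = HitTable(query.id, hits, oversized=oversized)
        if oversized:
            table.hits = table.hits[: config.max_hits]
        return table


class BlastBackend(SearchBackend):
    """Adapter around NCBI ``blastp`` for pre-formatted databases.

    Registered databases point at a BLAST database path plus a species map
    for the subjects.  Raises a clear error when the executable is absent.
    """

    def __init__(self, executable: str = "blastp") -> None:
        self.executable = executable
        self._dbs: dict[str, tuple[str, dict[str, str]]] = {}

    def register(self, db_id: str, db_path: str,
                 species_map: dict[str, str]) -> None:
        self._dbs[db_id] = (db_path, species_map)

    def sequence(self, db_id: str, subject_id: str) -> SequenceRecord:
        db_path, species_map = self._dbs[db_id]
        out = subprocess.run(
            ["blastdbcmd", "-db", db_path, "-entry", subject_id,
             "-outfmt", "%s"],
            capture_output=True, text=True, check=True)
        return SequenceRecord(subject_id, species_map[subject_id],
                              out.stdout.strip())

    def command(self, query_path: str, db_path: str,
                config: SearchConfig) -> list[str]:
        outfmt = "6 " + " ".join(BLAST_OUTFMT_COLUMNS)
        return [
            self.executable, "-query", query_path, "-db", db_path,
            "-evalue", str(config.e_threshold),
            "-outfmt", outfmt,
            "-max_target_seqs", str(config.max_hits + 1),
        ]

    def search(self, query: SequenceRecord, db_id: str,
               config: SearchConfig | None = None) -> HitTable:
        if shutil.which(self.executable) is None:
            raise RuntimeError(
                f"{self.executable} not found; use backend=internal")
        if db_id not in self._dbs:
            raise KeyError(f"unknown database {db_id!r}")
        config = config or SearchConfig()
        db_path, species_map = self._dbs[db_id]
        with tempfile.TemporaryDirectory() as tmp:
            qpath = Path(tmp) / "query.fa"
            write_fasta([query], qpath)
            out = subprocess.run(
                self.command(str(qpath), db_path, config),
                capture_output=True, text=True, check=True)
            raw = Path(tmp) / "hits.tsv"
            raw.write_text(out.stdout)
            table = read_blast_tabular(raw, query, species_map)
        oversized = len(table) > config.max_hits
        table.oversized = oversized
        if oversized:
            table.hits = table.hits[: config.max_hits]
        return table


class FixtureBackend(SearchBackend):
    """Canned results from a versioned JSON file, for tests.

    Schema: ``{"version": 1, "results": {db_id: {query_id: [row, ...]}},
    "sequences": {db_id: {id: [species, residues]}}}`` where each row holds
    the fields of :class:`PairwiseAlignment` minus the query id.
    """

    def __init__(self, payload: dict) -> None:
        if payload.get("version") != 1:
            raise ValueError("unsupported fixture version")
        self._payload = payload

    @classmethod
    def from_file(cls, path: str | Path) -> "FixtureBackend":
        return cls(json.loads(Path(path).read_text()))

    def sequence(self, db_id: str, subject_id: str) -> SequenceRecord:
        species, residues = self._payload["sequences"][db_id][subject_id]
        return SequenceRecord(subject_id, species, residues)

    def search(self, query: SequenceRecord, db_id: str,
               config: SearchConfig | None = None) -> HitTable:
        rows = self._payload["results"][db_id].get(query.id, [])
        hits = [
            PairwiseAlignment(
                query_id=query.id,
                subject_id=r["subject_id"],
                subject_species=r["subject_species"],
                e_value=r["e_value"],
                percent_identity=r["percent_identity"],
                query_start=r["query_start"],
                query_end=r["query_end"],
                aligned_query=r["aligned_query"],
                aligned_subject=r["aligned_subject"],
            )
            for r in rows
        ]
        return HitTable(query.id, hits)
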