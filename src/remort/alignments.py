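"""Sequences, pairwise local alignments, and binary conservation profiles.

The central objects of the pipeline's first stage: a query protein is
compared against a database with relaxed significance thresholds, and every
resulting local alignment is reduced to a per-query-position binary profile
marking identical-or-conserved columns.  Downstream stages (clustering,
reciprocal verification, network scoring) operate on these profiles and on
the ranked hit table.

Coordinates are 1-based inclusive in files (the BLAST tabular convention)
and converted only at the read/write boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: canonical BLAST+ tabular dialect consumed by :func:`read_blast_tabular`
BLAST_OUTFMT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "evalue",
    "qstart",
    "qend",
    "qseq",
    "sseq",
    "staxids",
)


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


def load_matrix(name: str = "BLOSUM62"):
    """Load a symmetric amino-acid substitution matrix by name."""
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with its accession and species of origin."""

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    """One local alignment of a database subject against the query.

    ``query_start``/``query_end`` are 1-based inclusive positions on the
    unaligned query; ``aligned_query``/``aligned_subject`` are the gapped
    alignment strings of equal length.
    """

    query_id: str
    subject_id: str
    subject_species: str
    e_value: float
    percent_identity: float
    query_start: int
    query_end: int
    aligned_query: str
    aligned_subject: str

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError(
                f"aligned strings differ in length for {self.subject_id}"
            )
        if self.e_value < 0:
            raise ValueError(f"negative E-value for {self.subject_id}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity out of range for {self.subject_id}"
            )

    @property
    def ungapped_query(self) -> str:
        return self.aligned_query.replace(GAP, "")

    def validate_against_query(self, query_residues: str) -> None:
        """Check the aligned query string matches the query's residues."""
        span = query_residues[self.query_start - 1 : self.query_end]
        if self.ungapped_query != span:
            raise FormatError(
                f"alignment of {self.subject_id} inconsistent with query: "
                f"ungapped qseq {self.ungapped_query!r} != query"
                f"[{self.query_start}..{self.query_end}] {span!r}"
            )


@dataclass(frozen=True)
class BinaryProfile:
    """Per-query-position conservation vector of one alignment.

    ``bits[p]`` is 1 when query position ``p`` (0-based here) is aligned to
    an identical or conserved subject residue, else 0.  All profiles of one
    run share the full query length.
    """

    subject_id: str
    bits: np.ndarray

    @property
    def support(self) -> frozenset[int]:
        return frozenset(int(i) for i in np.flatnonzero(self.bits))

    def __len__(self) -> int:
        return len(self.bits)


def _hit_sort_key(aln: PairwiseAlignment):
    return (aln.e_value, -aln.percent_identity, aln.subject_id)


@dataclass
class HitTable:
    """Ranked search results for one query.

    Hits are kept sorted by ascending E-value, ties broken by descending
    percent identity then subject id; ``oversized`` marks a search that
    exceeded the configured hit cap before truncation.
    """

    query_id: str
    hits: list[PairwiseAlignment] = field(default_factory=list)
    oversized: bool = False

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=_hit_sort_key)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def best_per_subject(self) -> "HitTable":
        """Keep only the lowest-E-value alignment of each subject."""
        seen: dict[str, PairwiseAlignment] = {}
        for aln in self.hits:  # already sorted, first wins
            seen.setdefault(aln.subject_id, aln)
        return HitTable(self.query_id, list(seen.values()),
                        oversized=self.oversized)

    def rank_in_species(self, subject_id: str, species: str,
                        exclude: str | None = None) -> int | None:
        """1-based rank of ``subject_id`` among this table's hits from
        ``species``; ``None`` if absent.  ``exclude`` drops one subject
        (typically the searcher itself) before ranking."""
        rank = 0
        for aln in self.hits:
            if aln.subject_species != species or aln.subject_id == exclude:
                continue
            rank += 1
            if aln.subject_id == subject_id:
                return rank
        return None


# ---------------------------------------------------------------------------
# readers


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a sidecar TSV ``accession<TAB>species[<TAB>phylum]``."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"species map line lacks a species: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def read_fasta(
    path: str | Path,
    species_map: Mapping[str, str] | None = None,
    species_token: int = 1,
) -> list[SequenceRecord]:
    """Read protein sequences with species resolution.

    Species are taken from ``species_map`` when given, otherwise from
    whitespace token ``species_token`` of the FASTA header.  Residues are
    upper-cased and trailing ``*`` stop codons stripped.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        if species_map is not None:
            species = species_map.get(rec.id)
        else:
            tokens = rec.description.split()
            species = tokens[species_token] if len(tokens) > species_token else None
        if not species:
            raise FormatError(f"species unresolved for record {rec.id}")
        residues = str(rec.seq).upper().rstrip("*")
        records.append(SequenceRecord(rec.id, species, residues))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.species}\n{rec.residues}\n")


def read_blast_tabular(
    path: str | Path,
    query: SequenceRecord,
    species_map: Mapping[str, str] | None = None,
    columns: Sequence[str] = BLAST_OUTFMT_COLUMNS,
) -> HitTable:
    """Parse BLAST+ tabular output into a :class:`HitTable`.

    The format must carry the aligned strings (``qseq``/``sseq``); subject
    species come from ``species_map`` or, failing that, the ``staxids``
    column.
    """
    import pandas as pd

    for required in ("qseq", "sseq"):
        if required not in columns:
            raise FormatError(
                "BLAST tabular input must include aligned strings; rerun with "
                '-outfmt "6 ' + " ".join(BLAST_OUTFMT_COLUMNS) + '"'
            )
    df = pd.read_csv(path, sep="\t", names=list(columns), comment="#",
                     dtype=str)
    hits = []
    for row in df.itertuples(index=False):
        sid = row.sseqid
        if species_map is not None and sid in species_map:
            species = species_map[sid]
        elif "staxids" in columns and isinstance(row.staxids, str):
            species = row.staxids
        else:
            raise FormatError(f"species unresolved for subject {sid}")
        aln = PairwiseAlignment(
            query_id=row.qseqid,
            subject_id=sid,
            subject_species=species,
            e_value=float(row.evalue),
            percent_identity=float(row.pident),
            query_start=int(row.qstart),
            query_end=int(row.qend),
            aligned_query=row.qseq,
            aligned_subject=row.sseq,
        )
        aln.validate_against_query(query.residues)
        hits.append(aln)
    return HitTable(query.id, hits)


# ---------------------------------------------------------------------------
# binarization


def binarize(aln: PairwiseAlignment, query_len: int, matrix=None) -> BinaryProfile:
    """Collapse an alignment to its identical-or-conserved positions.

    A query position scores 1 when aligned (no gap on either side) to a
    residue that is identical or has a positive substitution-matrix score;
    'X' never counts.  Gap columns in the aligned query consume no query
    position, so every profile of a run has the full query length.
    """
    if matrix is None:
        matrix = load_matrix()
    if query_len < aln.query_end:
        raise ValueError(
            f"query length {query_len} shorter than alignment end "
            f"{aln.query_end}"
        )
    bits = np.zeros(query_len, dtype=np.int8)
    qpos = aln.query_start - 1  # 0-based cursor on the query
    for qc, sc in zip(aln.aligned_query, aln.aligned_subject):
        if qc == GAP:
            continue
        if sc != GAP and qc != "X" and sc != "X":
            if qc == sc or matrix[qc, sc] > 0:
                bits[qpos] = 1
        qpos += 1
    return BinaryProfile(aln.subject_id, bits)
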