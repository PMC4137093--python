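"""Seeded generator of ground-truth protein-family worlds.

Emulates the regime the pipeline targets: an orthologous family whose
members share only a short conserved motif embedded at variable positions
in otherwise unrelated sequence, accompanied by per-species paralogs
(composition-matched impostors carrying a scrambled copy of the motif) and
unrelated decoys that still attain weak high-E-value alignments to the
query.  Ground truth is exact, so precision and recall of any run are
unambiguous.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .alignments import AMINO_ACIDS, SequenceRecord, write_fasta
from .clustering import ROBINSON_FREQUENCIES

_RESIDUES = list(AMINO_ACIDS)
_FREQS = [ROBINSON_FREQUENCIES[a] for a in _RESIDUES]

#: default conserved pattern: 30 residues, drawn once from background
#: frequencies (rare residues included) and fixed for reproducibility
DEFAULT_MOTIF = "WLRECHPDNKYGIFMSTVAQWERLCHDKYG"


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family world.

    ``motif_identity`` is the per-position probability that a family member
    retains the motif residue; ``background_len`` is the total sequence
    length into which the motif is written.
    """

    n_species: int = 20
    motif: str = DEFAULT_MOTIF
    motif_identity: float = 0.8
    background_len: int = 120
    n_paralogs_per_species: int = 3
    n_decoys: int = 50
    n_close_species: int = 2
    close_identity: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if not 0.0 <= self.motif_identity <= 1.0:
            raise ValueError("motif_identity must be in [0, 1]")
        if min(self.n_species, self.n_paralogs_per_species,
               self.n_decoys) < 0:
            raise ValueError("counts must be non-negative")
        if len(self.motif) > self.background_len:
            raise ValueError("motif longer than background_len")
        if not 0.0 <= self.close_identity <= 1.0:
            raise ValueError("close_identity must be in [0, 1]")
        if self.n_close_species >= max(self.n_species, 1):
            raise ValueError("n_close_species must be < n_species")


@dataclass
class FamilyWorld:
    """One generated world: database, exact truth, and bookkeeping."""

    spec: FamilySpec
    database: list[SequenceRecord]
    truth: set[str]
    species_map: dict[str, str]
    motif_positions: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def query(self) -> SequenceRecord:
        """The designated query: the family member of the first species."""
        return next(r for r in self.database if r.id == "orth_s00")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.database, outdir / "database.fa")
        with open(outdir / "species.tsv", "w") as fh:
            for sid in sorted(self.species_map):
                fh.write(f"{sid}\t{self.species_map[sid]}\n")
        (outdir / "truth.json").write_text(json.dumps(
            {"truth": sorted(self.truth),
             "query": self.query.id,
             "motif_positions": {k: list(v)
                                 for k, v in self.motif_positions.items()}},
            indent=1))


def _background(rng: random.Random, length: int) -> list[str]:
    return rng.choices(_RESIDUES, weights=_FREQS, k=length)


def _mutate_motif(rng: random.Random, motif: str, identity: float) -> str:
    out = []
    for c in motif:
        if rng.random() < identity:
            out.append(c)
        else:
            out.append(rng.choice(_RESIDUES))
    return "".join(out)


def generate(spec: FamilySpec) -> FamilyWorld:
    """Build a family world deterministically from its spec.

    Orthologs are background sequences with a per-position-mutated copy of
    the motif written at a random offset; paralogs are the same
    construction with the motif's residue order scrambled (family-like
    composition, no pattern); decoys are pure background.  The first
    ``n_close_species`` species after the query's own are recent relatives:
    whole-sequence copies of the query mutated at ``close_identity``
    per-position retention, the divergence gradient every real sequence
    database shows around a query.
    """
    rng = random.Random(spec.seed)
    database: list[SequenceRecord] = []
    truth: set[str] = set()
    species_map: dict[str, str] = {}
    motif_positions: dict[str, tuple[int, int]] = {}
    L, ml = spec.background_len, len(spec.motif)

    def embed(seq: list[str], pattern: str) -> tuple[int, int]:
        start = rng.randrange(0, L - ml + 1)
        seq[start : start + ml] = list(pattern)
        return start + 1, start + ml  # 1-based inclusive

    species = [f"species_{i:02d}" for i in range(spec.n_species)]
    query_seq: str | None = None
    for i, sp in enumerate(species):
        sid = f"orth_s{i:02d}"
        if 1 <= i <= spec.n_close_species and query_seq is not None:
            # recent relative: the query mutated uniformly along its length
            seq = list(_mutate_motif(rng, query_seq, spec.close_identity))
            motif_positions[sid] = motif_positions["orth_s00"]
        else:
            seq = _background(rng, L)
            mutated = _mutate_motif(rng, spec.motif, spec.motif_identity)
            motif_positions[sid] = embed(seq, mutated)
        if i == 0:
            query_seq = "".join(seq)
        database.append(SequenceRecord(sid, sp, "".join(seq)))
        truth.add(sid)
        species_map[sid] = sp

    for i, sp in enumerate(species):
        for j in range(spec.n_paralogs_per_species):
            sid = f"para_s{i:02d}_{j}"
            seq = _background(rng, L)
            scrambled = list(
                _mutate_motif(rng, spec.motif, spec.motif_identity))
            rng.shuffle(scrambled)
            embed(seq, "".join(scrambled))
            database.append(SequenceRecord(sid, sp, "".join(seq)))
            species_map[sid] = sp

    for k in range(spec.n_decoys):
        sid = f"decoy_{k:03d}"
        sp = species[k % max(spec.n_species, 1)] if species else "species_00"
        database.append(
            SequenceRecord(sid, sp, "".join(_background(rng, L))))
        species_map[sid] = sp

    return FamilyWorld(spec, database, truth, species_map, motif_positions)


def planted_profiles(
    n_clusters: int = 3,
    length: int = 90,
    min_block: int = 8,
    dropout: int = 0,
    seed: int = 0,
) -> tuple[list[tuple[str, list[int]]], dict[str, int]]:
    """Binary profiles with a planted flat clustering.

    Each cluster owns a random disjoint block of positions (width >=
    ``min_block``) and 2-6 members carrying that block, so clusters share
    no support while members coincide — the cleanly separated regime the
    knee cut is meant to resolve.  ``dropout`` > 0 flips off that many
    block positions per member, adding within-cluster jitter at the cost of
    the separation guarantee.  Returns (profiles, labels) with profiles as
    (id, bits) pairs.
    """
    rng = random.Random(seed)
    while True:
        cuts = sorted(rng.sample(range(min_block, length - min_block),
                                 n_clusters - 1))
        bounds = [0] + cuts + [length]
        if min(b - a for a, b in zip(bounds, bounds[1:])) >= min_block:
            break
    profiles: list[tuple[str, list[int]]] = []
    labels: dict[str, int] = {}
    for c in range(n_clusters):
        block = list(range(bounds[c], bounds[c + 1]))
        for k in range(rng.randint(2, 6)):
            keep = set(block) - set(rng.sample(block, dropout))
            bits = [1 if p in keep else 0 for p in range(length)]
            sid = f"c{c}_m{k}"
            profiles.append((sid, bits))
            labels[sid] = c
    return profiles, labels


def expected_profile(world: FamilyWorld, query_id: str) -> frozenset[int]:
    """0-based query positions of the embedded motif — the support the
    clustering stage should recover for the family."""
    if query_id not in world.motif_positions:
        raise KeyError(f"unknown query {query_id!r}")
    start, end = world.motif_positions[query_id]
    return frozenset(range(start - 1, end))
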