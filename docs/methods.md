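# Methods

This note records the model behind `remort`, the parameter choices that
matter, what the synthetic benchmark does and does not show, and the
numerical conventions that make runs reproducible.

## The problem and the model

Orthology is classically certified by the reciprocal-best-hit (RBH)
criterion: two proteins from different species that each rank the other
first in mutual similarity searches. For remotely conserved families the
criterion is unusable directly — true orthologs appear with E-values of
1 or 100, ranked among decades of spurious hits. `remort` assumes only
that family members retain a *shared conservation pattern* relative to
the query: the same query positions keep matching, whoever the subject
is. The pipeline therefore (a) finds that pattern by clustering binarized
alignments, (b) promotes pattern-cluster members to candidate orthologs,
(c) replaces the single RBH test by an iterative, population-level vote
among already-verified orthologs, and (d) summarizes the final evidence
as eigenvector centrality in a typed orthology network, deliberately
independent of any E-value.

## Stage conventions and tunable parameters

### Binarization

A query position scores 1 iff it is aligned (no gap on either side) to an
identical residue or one with a positive substitution score; BLOSUM62 by
default. "Conserved = positive matrix score" is the standard convention;
the matrix is configurable. `X` never matches. One profile per subject
(the lowest-E-value alignment) keeps the cluster consensus well defined.
Coordinates are 1-based inclusive in files (BLAST convention), 0-based
half-open internally; conversion happens only in readers/writers.

### Residue weights

The similarity weights up-weight rare residues: a shared tryptophan is
stronger evidence than a shared alanine. The default scheme is
w(a) = −log₂ f(a) with Robinson–Robinson background frequencies, giving
weights from 3.5 bits (Leu) to 6.2 bits (Trp). A per-residue weight table
from the OPTIMA substitution matrix can be supplied as a TSV and selected
with `scheme="optima"`; it is not bundled because no verified copy of
those values was available, and the log-rarity scheme preserves the same
intent in closed form.

### Consensus linkage

Classical average linkage compares a newcomer with the *average* of a
cluster, which lets a cluster accrete members that match different
subsets of its positions. Representing a cluster by its conserved
consensus (elementwise AND) forces newcomers to match what every member
conserves. Distance is d = 1 − S between consensus vectors. When all
members of every cluster are identical the two linkages coincide
(tested); once clusters mix, consensus shrink makes the modified linkage
strictly more conservative — that is the point. Ties in the minimum
distance are broken by the lexicographically smallest pair of cluster
representatives (smallest member id), which makes merge order
bit-reproducible.

### Knee cut

Sorted merge heights of remote-homology trees grow roughly exponentially:
a flat region of genuine pattern agreement, then a steep climb where
unrelated profiles are forced together. We fit y = a·e^{bx} by least
squares on log heights (heights ≤ 10⁻⁹ clamped to 10⁻⁹) and cut at the
height where the fitted climbing rate first exceeds the mean slope
(y_m − y_1)/(m − 1). Because the fit's slope at height y is b·y, that
crossing is y\* = mean slope / b in closed form; using the closed form
rather than scanning integer ranks keeps the rule well defined when many
heights are (near) zero and the fitted intercept a is consequently tiny.
Degenerate trees (fewer than 3 merges, all heights equal, b ≤ 0, or a
crossing above the tallest merge) stay one cluster. The cut is global —
one height for the whole tree.

### Verification rules

All thresholds sit in `EngineParams` with these defaults:

| parameter | default | role |
|---|---|---|
| `identity_select` | 80 % | hits above this identity are auto-selected (strictly >) |
| `strict_e` | 10⁻⁵ | below this E-value to the query the strict RBH rule applies |
| `reject_fraction` | 1/3 | weak candidates die when rejected by more than this fraction of bona fide orthologs |
| `max_acceptable_rank` | 3 | reciprocal rank within a species still counted as support |
| `multi_support_select` | 2 | candidates found as RBH by more than this many bona fide orthologs are recruited |

Conventions the rules need but their one-line statements do not fix:

* Reciprocal ranks are computed *per species* — the rank of an ortholog
  among the candidate's hits restricted to that ortholog's species — and
  the candidate's own self-hit is ignored when ranking.
* The rejection denominator is the bona fide set at decision time (query
  included); round 1 is always the query alone.
* The strict RBH rule is applied once, against the query; it does not
  re-enter the 33 % vote later. Candidates recruited by expansion that
  never appeared in the initial hit table have no E-value to the query
  and take the vote branch.
* Decisions are forward-only: a verified ortholog is not retracted when
  later rejectors appear (the audit log records everything).
* The query counts among the "more than two" RBH finders of the
  recruitment rule.
* Final output drops every verified ortholog whose supporters are the
  query alone, in a single pass against the full verified set — dropping
  one node does not cascade into re-evaluating others.
* Initial searches that exceed `max_hits` (default 1500) abort: such
  families are similar enough for phylogenetic methods.

### Network score

Mutual relations (both directions best/acceptable) give bb, ba, aa
edges; one-sided relations give b, a edges; weights 1, 0.5, 0.25, 0.125,
0.0625 are fixed constants, not configuration, to keep score semantics
stable. Scores are computed per connected component by power iteration
with the standard +I shift, x ← (A + I)x, L2-normalized, from a uniform
positive start; convergence when the largest per-node change falls below
10⁻¹⁰, hard cap 1000 iterations. The shift leaves the principal
eigenvector unchanged and guarantees convergence on bipartite components
(a path of one-sided edges is a perfectly normal orthology network),
matching the behaviour of the widely used graph-library implementation of
eigenvector centrality. Per-component normalization (isolated node = 1)
avoids global normalization concentrating all mass on the largest
component. Scores rank; they never gate membership.

### Internal search backend

The bundled aligner is affine-gap Smith–Waterman (BLOSUM62, gap open 11,
extend 1, BLAST cost convention: a gap of length k costs 11 + k). The
E-value proxy E = m·n·2^(−0.267·s) is a Karlin–Altschul-shaped monotone
transform of the raw score — every pipeline decision depends only on
E-value *order* plus the two absolute cutoffs (100 and 10⁻⁵), which the
proxy preserves at the sequence lengths the benchmark uses. The backend
is deterministic and database-order independent; a `blastp` adapter and a
canned-JSON fixture backend satisfy the same contract.

## The synthetic benchmark

`remort.synthetic.generate` builds worlds with exact ground truth. The
default world has 20 species; each true ortholog is a 120-residue
background sequence (Robinson–Robinson composition) with a 30-residue
motif embedded at a random position, each motif position retained with
probability `motif_identity` (default 0.8). Two species are recent
relatives of the query — whole-sequence copies mutated at 85 % retention
— reproducing the divergence gradient every real database shows around a
query; without them the >80 %-identity and query-cluster seeding rules,
which the method's bootstrap depends on, have nothing to act on. Each
species carries 3 paralogs (own background, *scrambled* motif:
family-like composition with no pattern, exercising the rejection path)
and the world holds 50 unrelated decoys that still reach weak alignments
at E ≤ 100.

What the benchmark does not emulate: indel evolution along a phylogeny,
domain architecture, length variation, compositional bias beyond global
frequencies, and multi-branching families. Passing it shows the
machinery — pattern clustering, voting, recruitment, exclusion — behaves
as designed under its stated noise model; it does not predict recovery
rates on real proteomes, which depend on database composition.

`planted_profiles` generates the cut benchmark: clusters own randomized
disjoint support blocks (width ≥ 8 of 90 positions, 2–6 identical members
each). Identical members are what "cleanly separated" requires: once
within-cluster jitter approaches the knee's resolution, compounded
consensus shrink blurs the flat-to-steep transition and no global cut can
be guaranteed.

## Problem sizes

The test suite and acceptance script run everything at desk scale by
design: 130-sequence databases (20 species × (1 ortholog + 3 paralogs) +
50 decoys), 5–20 worlds per condition, 100-seed oracle sweeps with ≤12
profiles or ≤8 network nodes. The pipeline itself is O(hits² · query
length) in clustering and O(candidates · database) in verification, and
has no per-run randomness: identical inputs give byte-identical bundles.

## Known limitations

* Everything downstream sees only the initial hit table: an ortholog the
  relaxed search misses is unrecoverable (by design; intermediate-species
  queries are the documented workaround).
* Near-identical in-species duplicates can exclude each other through the
  strict RBH rule.
* Scores are not comparable across runs, only within one network.
* The 33 % vote cannot always separate orthologs from well-behaved
  paralogs; co-orthologs are reported rather than suppressed, and the
  occasional composition-matched paralog survives verification (observed
  as the rare false positive in the benchmark).
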