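# remort — remote-orthology search from relaxed similarity searches

Standard orthology assignment fails for *sequence orphans*: proteins whose
orthologs have diverged so far that BLAST-style searches return them — if
at all — buried among hundreds of spurious hits with E-values far beyond
any significance threshold. `remort` implements a fully automated pipeline
for exactly this twilight zone. It is a library plus CLI for
bioinformaticians who suspect a protein has distant relatives that
pairwise searches alone cannot certify.

## Method

Starting from a deliberately relaxed local-alignment search (default
E ≤ 100), the pipeline exploits the one signal that survives deep
divergence: members of an orthologous family still share a *conservation
pattern* along the query.

1. **Alignment binarization.** Every hit alignment is reduced to a binary
   profile over query positions: 1 where the aligned residue is identical
   or conserved (positive BLOSUM62 score), else 0.
2. **Pattern clustering.** Profiles are compared by residue-weighted
   Jaccard similarity, S(p_i, p_j) = Σ w(q_p)·p_i[p]·p_j[p] / Σ
   w(q_p)·max(p_i[p], p_j[p]), where w(a) = −log₂ f(a) up-weights rare
   residues (Robinson–Robinson background frequencies f). Profiles are
   agglomerated with a modified average linkage: a cluster is represented
   by the conserved consensus (elementwise AND) of its members, so joining
   a cluster requires matching what *all* its members conserve.
3. **Knee cutting.** Sorted merge heights are fitted with y = a·e^{bx};
   the tree is cut where the fitted climbing rate first exceeds the mean
   slope (at height y\* = mean slope / b), splitting tight pattern
   clusters from the noise floor.
4. **Iterative reciprocal verification.** Candidates (hits >80% identical
   to the query, plus the query cluster's members) are submitted to
   reciprocal searches. Candidates with E < 10⁻⁵ must satisfy the strict
   reciprocal-best-hit rule against the query; weaker candidates survive
   unless rejected by more than a third of the current bona fide
   orthologs (reciprocal rank within their species worse than 3). Verified
   orthologs recruit further candidates — cluster co-members, and any
   sequence found as a mutual best hit by more than two bona fide
   orthologs — until a fixed point. Hits supported only by the query are
   dropped.
5. **Network scoring.** Verified orthologs form a typed graph: mutual
   relations give bb/ba/aa edges, one-sided relations b/a edges, weighted
   1, 0.5, 0.25, 0.125, 0.0625. Each node's *network score* is its entry
   in the principal eigenvector of its component's weighted adjacency
   matrix — an E-value-independent measure of how embedded the node is in
   the family. Low scores never exclude a hit; they only rank.

Searches run on an internal deterministic Smith–Waterman backend (no
external binaries), through a `blastp` adapter, or from pre-computed BLAST
tabular files.

## Worked example

Generate a synthetic family world with known ground truth (10 orthologous
species sharing a 30-residue motif, 2 paralogs per species, 20 decoys),
search with one family member as the query, and score the result:

```sh
remort synth --seed 5 --spec spec.json --out world5
head -2 world5/database.fa > query.fa
remort run --query query.fa --db world5/database.fa \
    --species world5/species.tsv --out run5
remort eval --results run5 --truth world5/truth.json
```

prints

```
verified orthologs: 9 (of 23 hits, 3 rounds)
  orth_s00	species_00	0.3162	2.07e-48
  orth_s02	species_02	0.3162	4.36e-39
  orth_s01	species_01	0.3162	3.08e-37
  orth_s08	species_08	0.3162	6.84e-06
  ...
{
 "precision": 1.0,
 "recall": 1.0,
 ...
}
```

All 9 verified orthologs plus the query form a fully mutual best-hit
clique, so every node receives the same network score 1/√10 ≈ 0.3162 —
maximal embedding in a 10-node component — even though E-values span 43
orders of magnitude. The run directory holds the ranked table
(`results.tsv`), the Cytoscape network (`network.sif` +
`attributes.tsv`), a per-decision audit log (`audit.jsonl`), and a
manifest that makes the run bit-reproducible.

The same pipeline is available as a library:

```python
from remort import FamilySpec, InternalBackend, RunConfig, generate, run

world = generate(FamilySpec(seed=5))
backend = InternalBackend()
backend.register("db", world.database)
result = run(world.query, backend, "db", RunConfig())
print(result.table[:3])
```

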