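# Methods

## The screening model

`orthoscreen` treats orthology inference across four deeply diverged
taxa as a graph problem.  All-vs-all local alignment produces a hit
table; reciprocal best hits (RBH) between species define putative
ortholog edges; recent same-species duplicates (in-paralogs) are pairs
mutually more similar than either is to anything in another species;
co-ortholog edges extend ortholog relations through one in-paralog step.
Edges are weighted by the mean of −log10(E) over the two directed hits
and normalized — ortholog and co-ortholog edges by the mean ortholog
weight of their species pair, in-paralog edges by the mean in-paralog
weight of their species (restricted to pairs anchored to the ortholog
graph) — so that species pairs at very different evolutionary distances
contribute comparably.  Markov clustering then alternates expansion
(matrix squaring) and inflation (entrywise powering + column
renormalization) until the flow matrix is stable; attractor basins are
the clusters.

Downstream, a cluster is summarized by its species-membership pattern;
absence of a gene in a target species is accepted only after a decision
tree that distinguishes *confirmed absent* (no significant similarity at
all), *confirmed unique* (the similarity is explained by a different
gene's orthology), and *divergent candidate* (significant similarity
with no orthology assignment — flagged for manual review, never silently
dropped); and absence is only inferred when shared by both dorylaim
species, because a single draft proteome may simply be missing a gene.
Under this logic absence maximally implies loss and minimally implies
divergence beyond recognition; the shared-loss combinator carries an
explicit caveat flag whenever a manual-review status contributed.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| substitution matrix | BLOSUM62 | standard for distant protein homology; `X` scored 0 against everything |
| gap open / extend | 11 / 1 | BLAST convention: gap of length k costs 11 + k |
| λ, K (Karlin–Altschul) | 0.267, 0.041 | standard gapped BLOSUM62 values; fixed (not estimated) so E-values are exactly reproducible |
| E-value report ceiling | 10 | hits worse than this are not stored |
| significance threshold | 1e-5 | pipeline-wide convention for edges and absence calls; absence uses strict `E < 1e-5` (a hit at exactly 1e-5 is not significant) |
| MCL inflation | 1.5 | inclusive granularity appropriate for deeply diverged proteomes; higher values fragment clusters |
| MCL pruning / tolerance / iterations | 1e-5 / 1e-6 / 100 | flow entries below pruning are zeroed each cycle; convergence is max entrywise change |
| min cluster size | 2 | an orthologous group has at least two members; smaller basins are reported as singletons |
| redundancy threshold | 0.99 | identity over the shorter sequence at which a proteome entry is collapsed onto a longer retained one |
| enrichment α / correction | 0.05 / none | uncorrected single-test p-values by default: the study sets are a handful of clusters against a whole proteome, so per-term counts are too small for correction to behave; Bonferroni and Benjamini–Hochberg are available |
| phylotypic window | stages 6–8 of 10 | the ventral-enclosure window; "elevated between stages 6 to 8" is read as elevated at *any* stage of the window |

## The synthetic study

The simulator generates gene families on the fixed species tree
`(((rc,ts),ce),tc)` with seven unit-length branches (four terminal, the
dorylaim stem `n2`, the nematode stem `n3`, and the root).  Each family
is born on a branch, lost independently on each branch below it, and
gains Poisson-distributed extra copies in surviving terminal lineages.
Sequences evolve from a random ancestral protein by per-site uniform
replacement over the 19 alternative residues — no rate heterogeneity,
no indels by design, because the screen tests presence/absence
detection, not phylogenetic estimation, and the indel-free uniform
chain keeps the identity calibration closed-form: expected identity
after `m` unit branches is `1/20 + (19/20)·r^m`, so the per-branch
retention `r` is solved directly from the target identity at the
maximal leaf-to-leaf distance (4 units, e.g. rc↔tc).  Duplicates
receive one extra unit branch of divergence, which makes them
recoverable as in-paralogs.

The default study — the conditions all recovery numbers refer to — is:

* 50 ordinary families born at the root, loss probability 0.1 per
  branch, duplication rate 0.05, lengths 60–100 residues, target
  ortholog identity 0.70 at full tree depth;
* 20 families with an engineered loss on the dorylaim stem `n2`
  (present in ce and tc only): the planted analogue of
  *C. elegans*-restricted developmental genes, and the positive truth
  for the absence panel;
* 10 families with an engineered loss on the `ce` branch: the
  dorylaim-specific class that the GO-enrichment analysis targets (the
  designated term `GO:9999001` is planted in these families' proteins at
  frequency 0.8 over a 0.05 background; without an engineered class the
  rc+ts-without-ce pattern would be empty under some seeds);
* 10 extreme-divergence families (target identity 0.20 at full depth,
  ≈ 0.29 between ce and either dorylaim): a stress class whose
  similarities straddle the significance threshold;
* 5 novel genes per species (i.i.d. random sequences in no family):
  taxonomically restricted genes;
* a stage-expression layer on the ce proteome: the ce members of 20
  conserved families are elevated at one stage each in 6–8 (the planted
  phylotypic set), every stage receives 3 background genes from other
  conserved families and one novel gene (the pool recycles, emulating
  expression spanning stages), so the per-stage genus-restricted
  proportion and the restricted/core split have exact planted values;
* GO background: 40 terms attached per protein independently at
  frequency 0.05.

All randomness flows from one seed through named substreams (events,
sequences, annotations, stages), so partial re-runs and full re-runs are
byte-reproducible.

What the generator does *not* emulate — and therefore what passing tests
do not show about real data: indels and alignment ambiguity, domain
shuffling and promiscuous domains, gene superfamilies (families are
mutually random, so cross-family similarity is at chance level),
composition bias, isoforms (one protein per gene), and assembly- or
annotation-driven false absences.  Recovery rates on real proteomes
will be lower than on this benchmark.

## Numerical and design choices

* **Alignment engine.**  Affine-gap Smith–Waterman is executed through
  `Bio.Align.PairwiseAligner` with the BLAST-convention gap costs; the
  test suite checks it score-for-score against an independent
  plain-Python dynamic program (500 random pairs), which is itself
  validated by exhaustive enumeration of alignment paths at tiny
  lengths.  Identity is counted over all alignment columns including
  internal gaps; coverage is the aligned span over sequence length.
* **E-values** use the pairwise closed form `K·m·n·e^(−λS)` with the
  sequence lengths, not a database length, in both the clustering and
  the verification steps, and are clamped to ≥ 1e-180 before
  logarithms.  Tie-breaks everywhere are (lower E, higher bitscore,
  lexicographic subject id).
* **MCL details.**  Self-loops are set to the node's maximum incident
  weight (1 for isolated nodes), the standard stabilization; each
  connected component is clustered independently; attractors are nodes
  with positive diagonal mass in the limit matrix, attractors with
  overlapping rows form one system, and every node joins the system
  holding most of its column mass (ties to the system with the
  lexicographically smallest member).  Non-convergence at 100
  iterations emits a warning and reads clusters from the current
  matrix.  Cluster ids are assigned by descending size, then smallest
  member, so output files are stable.
* **Degenerate inputs.**  Empty sequences, illegal residues, duplicate
  identifiers and malformed table lines raise input errors naming the
  offending record; an empty enrichment study set warns and returns no
  results; stages without elevated genes report a missing value rather
  than zero.
* **Hypergeometric tail** is computed via the survival function of
  `scipy.stats.hypergeom` (log-space internally) and is checked
  exhaustively against exact rational enumeration for all parameter
  combinations with N ≤ 12.
* **Singletons** are excluded from pattern counts (a cluster has ≥ 2
  members) and reported separately, since species-unique *clusters* and
  species-unique *proteins* are different quantities.
* **Timestamps** are deliberately absent from the manifest: provenance
  records the seed, package version and content hashes of all inputs,
  and byte-identical re-runs take precedence over wall-clock metadata.

## Known limitations

* The manual-review status replaces, but does not perform, a follow-up
  search of an external sequence database; routing a protein there is
  the end of the automated pipeline.
* Because the clustering graph and the verification step share one hit
  table, one significance convention, and symmetric pairwise E-values,
  a significant query→target hit almost always co-clusters the pair:
  the *divergent candidate* and *confirmed unique* outcomes are
  reachable (MCL can peel a weakly attached member off a cluster; a
  random competitor can break an RBH) but rare on synthetic data
  without cross-family similarity.  On this benchmark the
  extreme-divergence families therefore resolve almost entirely into
  *orthologue present* (significant, clustered) or *confirmed absent*
  (below threshold), and the measured routing rate to the cautious
  statuses is ~0%.  In a real analysis the two steps come from separate
  search runs with different databases and effective-length corrections,
  which decouples the thresholds and populates the review queue.
* E-values from the fixed Karlin–Altschul constants differ numerically
  from BLAST's (no composition-based statistics, no effective-length
  correction); all thresholds are configuration, so the 1e-5 contract —
  not any particular BLAST build — is what is reproduced.
* MCL is dense and in-memory per connected component: appropriate for
  desk-scale studies (thousands of proteins), not for all-of-UniProt.
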