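# Methods

This note documents the models, thresholds and design choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Sample curation

Metagenome sample metadata is filtered by exclusion lists over five fields:
ecosystem type (e.g. deep subsurface, volcanic), ecosystem subtype
(wetlands, sediment, fracking water, ...), title phrases, geographic
location and project type. Title matching is case-insensitive,
word-boundary phrase matching: the lists contain both `crust` and
`biocrust` as separate phrases, so a naive substring match would
double-fire; with word boundaries each phrase matches exactly itself.
Missing metadata fields never match (they are logged), and curation is
idempotent. All lists are overridable from YAML.

## Triage of viral contigs

Inputs are per-contig assessments from an upstream virus classifier and
completeness estimator: a virus score in [0, 1], the count of viral
hallmark genes (terminase, capsid, portal, ...), a real-valued virus-marker
enrichment statistic, a completeness tier, and provirus flags. Evaluation
order is fixed: provirus rejection, length floor (1 kb), then rules 1–3
(see README). Conventions chosen where wording alone is ambiguous:

* "longer than 10 kb" and "shorter than 10 kb and longer than 5 kb" are
  read strictly, with the 10 kb boundary assigned to the mid-length rule so
  no length band is undefined; a contig of exactly 5 kb can only be
  accepted via rule 1.
* "high similarity to the completeness database" is operationalized as the
  completeness tiers {complete, high, medium}.
* the "marker of at least 5.0" alternative in rule 2 is interpreted as the
  same marker-enrichment statistic used by rule 3, the only real-valued
  marker quantity in that classifier output.
* direct terminal repeats are detected as an exact, non-overlapping prefix
  recurring as a suffix at ≥ 20 bp (configurable); a precomputed DTR flag
  is also accepted. The decision is monotone in score, hallmark count and
  enrichment (property-tested).

## Pairwise identity statistics

ANI per genome pair is the mean of per-alignment identities weighted by raw
alignment lengths; aligned fractions divide the per-genome union of merged
alignment intervals by genome length, so overlapping alignments count each
base once. ANI weights deliberately use the *unmerged* lengths, matching
the reduction convention of the standard viral ANI tooling this mirrors.
The MIUViG aligned-fraction criterion is evaluated on the shorter sequence
of the pair (configurable to require both), and all threshold comparisons
are inclusive (ANI ≥ 95.0, AF ≥ 85.0), since the criterion names the values
themselves. AAI uses bidirectional best hits (best hit per query protein by
bitscore; ties by lower e-value, then subject id), with pair identity the
mean of the two directed identities; the shared-gene fraction is the
best-hit coverage of the smaller proteome. One-way best hits are available
as an option.

The internal aligner is a gapless seed-and-extend (k = 11 seeds, +1/−2
scoring, X-drop 10, minimum hit length 25, forward strand): exact for the
substitution-only homology the generator plants, and not intended as a
general aligner. External 12-column tabular alignments can be supplied in
its place at every entry point.

## Clustering

The species step runs Leiden (CPM quality) at resolution 0 on the binary
MIUViG threshold graph, which provably coincides with connected components
— the intended reading of "pairs satisfying the criteria are connected by
edges" — while keeping a community-detection engine available for weighted
variants at positive resolution. Genus and family levels cluster AAI
threshold graphs (edge weight = AAI) with an in-house MCL: self-loops at
each node's maximum incident weight, column normalization, then repeated
expansion (power 2), inflation (elementwise power 2.0, renormalize) and
pruning of entries < 1e-5, to convergence (max column change < 1e-8, cap
100 iterations; non-convergence returns the current state flagged).
Clusters are connected components of the converged matrix's nonzero
structure, merging overlapping attractor systems. The classic inflation 2.0
default is used because the clustering algorithm itself is named but not
parameterized in the surveys this follows; all parameters are exposed.

Rank nesting (species ⊂ genus ⊂ family) is not guaranteed by independent
MCL runs, so an optional repair step (on by default) moves any fine cluster
that straddles coarse clusters into the coarse cluster containing its
representative (longest member, ties lexicographic). This repair is an
extension: whether the original surveys enforced nesting is not stated.

## Host assignment

The spacer matcher finds all full-length gapless occurrences on both
strands with ≤ 1 substitution by default (pigeonhole block seeding,
verified by Hamming count) — with the downstream filter requiring < 2
mismatches and ≥ 95% spacer coverage, a substitution-only matcher is an
exactly-testable surrogate for a word-size-8 nucleotide search. Consensus
support is counted in distinct spacer ids (not raw alignments), so one
repetitive spacer cannot dominate. The > 70% rule divides by distinct
spacers with a *defined* taxon at the rank under consideration
(configurable to all spacers), since lineages can be rank-incomplete. Rank
order is species < genus < family < order < class < phylum < domain, and
"lowest" means most specific.

## AMG screening

The five flanking-context categories are this package's operationalization
(the natural enumeration of {hallmark, viral non-hallmark, none}² up to
symmetry); the category scheme is a parameter. Context is the *nearest*
viral-labelled gene on each side, unbounded by default, with an optional
gene-count window — candidate runs of several host-like genes between
viral anchors are common. AMG abundance is the raw count of retained gene
copies per sample, with no length or depth normalization.

## Atlas statistics

Rarefaction subsamples without replacement, 100 replicates by default (the
replicate count is not fixed by the surveys this mirrors). Samples below a
kind-specific richness floor (5 for viral attribute kinds, 100 for
host/microbial kinds; "fewer than" strict) are dropped before rarefaction.
Accumulation curves order samples ascending by assembled base pairs (ties
by id) and report running distinct-attribute counts. Occupancy fractions
("more than one sample", "more than five samples") are strict
inequalities, as is the more-than-five-samples prevalence filter before
Spearman correlation. Spearman uses average ranks for ties (host-count
vectors are tie-heavy); constant vectors or < 3 paired observations yield
missing values, never zero.

## Synthetic data generator

The generator emulates, at toy scale, the inputs of an atlas-scale survey:

* **Genomes.** Per planted cluster, one ancestor is drawn uniformly at the
  configured GC content; each member substitutes a fixed number of distinct
  positions equal to *half* the planned divergence, so the pairwise
  identity between any two members equals the planned within-cluster ANI
  (up to the binomial noise of coinciding positions). Substitutions only —
  no indels — so Hamming-distance oracles are exact. Substitution rates
  ≥ 0.75 are rejected as saturated. Optional DTRs append the first
  `dtr_length` bases to the 3′ end.
* **Gene tables.** Marker-labelled genes of 900 bp tile contigs with a
  100 bp intergenic gap, alternating strand, 1-based inclusive coordinates.
* **Host database.** Hosts carry full seven-rank lineages on a regular
  binary-coarsening tree (2 hosts per genus by default) with random
  spacers of 28–38 bp.
* **Protospacers.** Implanted verbatim (or reverse-complemented) with an
  exact planned number of substitutions at distinct positions; overlapping
  implants are rejected, and every implant is recorded as ground truth.
* **Occupancy.** Per-attribute geometric occupancy with p = 0.861 by
  default, so 13.9% of attributes occupy more than one sample — the
  sample-uniqueness regime reported for real soil vOTUs.

One integer seed drives everything, hierarchically split per operation, and
regeneration is byte-identical.

What the generator does **not** emulate: realistic community composition
and abundance distributions, indels and assembly artifacts, chimeras,
strain microdiversity, rank-incomplete host taxonomies, or any read-level
process. Passing tests therefore demonstrate the correctness of the
decision logic and of the statistics under the stated model — not detector
performance on real soil metagenomes, which depends on the upstream
classifiers this package deliberately treats as external inputs.

## Problem sizes

The bundled end-to-end study uses 12 samples and 40 genomes of 5–20 kb in
8 planted clusters (within-cluster ANI 97%), 8 hosts × 3 spacers, 10
contigs with implanted protospacers, and a 5,000-attribute × 200-sample
occupancy model — sizes chosen so the chain exercises every branch while a
full run completes in seconds. All sizes are parameters of
`pipeline.run_study`.

## Known limitations

* The internal aligner is forward-strand and gapless; reverse-complement
  or indel-bearing homology must come from external alignment tables.
* vOTU clustering at resolution 0 is single-linkage-like: one borderline
  pair can bridge two clusters, a known property of component-based vOTU
  definitions.
* MCL cluster extraction merges overlapping attractor systems, which can
  differ from implementations that split them.
* AMG category definitions vary between surveys; only the flanking-context
  family of schemes is supported.
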