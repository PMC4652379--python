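# Methods

## The problem

De novo transcriptome (and genome) assemblies are routinely judged by
*completeness*: the fraction of a reference set of conserved, single-copy
genes that can be recovered from the assembly. The usefulness of such a
score depends entirely on the reference set. A set containing families
with ancient paralogs overestimates completeness, because a surviving
paralog (e.g. H6PD standing in for a lost G6PD) satisfies the detection
criterion without being the ortholog. `corevert` implements the full
workflow for building a lineage-specific core set of strictly one-to-one
orthologs, turning it into profile HMMs with per-gene score and length
cutoffs, scoring assemblies against it, and computing the assembly-level
statistics used to compare assembly strategies.

## Core-set derivation

Input is a collection of precomputed ortholog groups (species → genes →
proteins, one representative isoform per gene), per-family gene trees
annotated with speciation/duplication events and the taxon at which each
event occurred, a species taxonomy, and the proteome of one species
released after the groups were built. Four filters run in a fixed order;
the derivation log records the count surviving each stage:

1. **One-to-one filter** — keep groups in which every species of the
   required panel (core + extension species) has exactly one gene.
   Multiple transcript isoforms of one gene do not violate one-to-one.
2. **Outgroup filter** — keep groups with at least one ortholog in at
   least one outgroup species. The outgroup anchors the family outside
   the lineage so that lineage-internal duplications are distinguishable
   from older ones.
3. **Reciprocal best hit (RBH)** — each late-species protein is assigned
   to the group whose representative is its best-scoring hit, provided
   that representative's best hit over the late proteome is that same
   protein. Groups gaining exactly one protein are kept. Scoring is
   Smith–Waterman local alignment under BLOSUM62 (gap open 11, extend 1),
   ranked by raw score; the scorer is a pluggable contract. A best-hit
   tie spanning two *different* groups is ambiguous and assigns nothing;
   a tie between two representatives of the *same* group is not — only
   the group identity matters, and exact raw-score ties between equally
   diverged members of one family do occur in practice.
4. **Gene-tree validation** — a group is kept iff the minimal subtree
   spanning its lineage members contains no duplication node whose taxon
   lies inside the lineage crown clade. Duplications wholly outside the
   family's own subtree (e.g. affecting only non-member paralogs or the
   outgroup) do not disqualify it; neither do duplications dated before
   the lineage (e.g. at the phylum level), even when they sit on the
   spanning subtree. Groups whose tree is missing, or whose members
   cannot all be found in the tree, are excluded with a logged warning
   rather than silently kept.

Surviving families are materialized over an ordered panel of assessment
species (representative + all transcript isoforms per species).

### Paralog audit

Given a protein predicted as an ortholog of a core gene, the audit finds
its best hit in a reference proteome (e.g. human). The prediction is a
false positive iff that best hit is an annotated paralog of the gene's
reference member *and* the paralog pair's duplication taxon is at or
above the mammal–sauropsid split — i.e. the two copies had already
separated before amniotes radiated, so cross-matching them conflates
genes that have been distinct for >300 My. A tied best hit is reported
as unresolved rather than forced to a verdict.

## Profiles and cutoffs

Each family's assessment-species representatives are aligned (MAFFT by
default; a trivial stacking engine for equal-length inputs) and compiled
into a profile HMM via pyhmmer. Two deliberate deviations from HMMER3
defaults:

* **No entropy-based effective-sequence-number weighting** (`--enone`).
  Entropy weighting flattens emissions toward a target information
  content, which compresses the score gap between conserved and
  divergent members. The cutoff criteria below rely on that gap being
  informative, as it was under the HMMER 2-era tools this assessment
  scheme was designed around.
* **Detection cutoff by leave-one-out.** Each member is scored against a
  profile rebuilt from the alignment *without* that member's row, and
  the minimum over members is the detection (profiles) cutoff. Scored
  against the full profile, every member — including the most divergent
  — scores within ~15 % of the best, because its own residues are in the
  model; the resulting "minimum member score" would be so close to a
  full-length match that no truncated or moderately diverged ortholog
  could ever reach it, contradicting both the intended permissiveness of
  the detection stage and the magnitudes of published cutoff tables
  (medians of order 10² bits, sometimes negative, against full-length
  member scores of order 10³). The plain full-profile minimum remains
  available (`detection_mode="profile"`).

The **completeness cutoff** is computed from *all* transcript isoforms:
per species the maximum bit score over that species' transcripts, then
the minimum of those per-species maxima. The within-species maximum says
that any isoform of a true ortholog is a legitimate full-length match;
the cross-species minimum guarantees by construction that every known
ortholog clears its own family's cutoff (any higher aggregation would
reject a known member, which is self-defeating). Alternative aggregations
(`median`, `min_all`) are selectable.

**Length cutoffs** are the arithmetic mean and sample (n−1) standard
deviation of member lengths; "complete by length" means within mean ±
2 SD (multiplier configurable).

Datasets export in two layouts: CEGMA-like (per-gene HMMER3 profile
files, `profiles_cutoff.tbl`, `completeness_cutoff.tbl`, length table)
and BUSCO-like (additionally the profile consensus sequences emitted from
the HMM, and per-gene gene-structure profile placeholders). Cutoffs are
serialized with full float precision and round-trip bit-exactly.

## Assembly assessment

Candidate proteins are the stop-free translations of maximal stop-to-stop
ORFs in all six frames, at least 30 aa by default (transcriptome mode;
spliced gene prediction on genomes is out of scope). All family profiles
are searched against all candidates with the same engine used for cutoff
computation, so bit scores are directly comparable. Per gene:

* **complete** — some hit has bit score ≥ completeness cutoff *and*
  merged match-state coverage strictly greater than 0.70. When the engine
  reports several domains for one candidate, their match-state spans are
  merged by union before computing coverage. The copy count is the number
  of distinct loci (subcomponents; contig id when no locus map is given)
  among complete-qualifying hits.
* **partial** — otherwise, some hit reaches the detection cutoff.
* **missing** — neither.

Comparisons are strict `>` for coverage ("more than 70 %") and `≥` for
bit scores (so a member scoring exactly its own cutoff passes). The
completeness score is the percentage of complete genes; the
partial-inclusive score adds partial genes. Length checks are available
but off by default for transcriptome assessment.

## Assembly metrics and integration

* **N50**: the largest L such that contigs of length ≥ L contain at
  least half of all assembled bases. The per-locus variant takes the
  longest contig of each subcomponent as its representative first.
* **Read-count filter**: contigs with fewer than 5 mapped reads
  (fragments; counts are inputs, not computed) are removed, together
  with subcomponents left empty.
* **Properly-paired rate**: fraction of mapped pairs with the
  properly-paired flag (SAM flag 0x2, or the TSV `proper` column).
* **Insert sizes**: mates are truncated to their first 50 nt before
  mapping so that the mates of short-insert pairs cannot overlap; the
  insert length of a pair is then the outer span from the leftmost base
  of the leftmost mate to the rightmost base of the rightmost mate. The
  fragment-size distribution is the insert distribution shifted by the
  total ligated adapter length (default 122 bp, configurable — the
  fragment/insert relation is fixed, the constant is platform-specific).
* **Merge and cluster**: stage 1 removes, scanning longest-first, any
  contig whose containment identity against a longer retained contig is
  ≥ 0.99 (word size 8 as k-mer prefilter); stage 2 joins surviving
  contigs sharing a local alignment of ≥ 0.95 identity over ≥ 50
  alignment columns (either strand) into connected components. Stage 2
  groups; it does not build consensus sequences. Locus labels are then
  reassigned by single linkage: contigs sharing a cluster or an original
  locus end up in one subcomponent (transitive closure).

## The synthetic-data generator

The generator emulates the study design end to end: a chordate taxonomy
(8 vertebrate assessment species + 2 tunicate outgroups), gene families
evolved from random ancestral proteins (150–300 aa) by species-specific
point substitution — no indels, so alignments are trivial and the profile
length equals the ancestor length — with branch depths mirroring the real
panel's asymmetry (tetrapods shallow, teleosts intermediate, cyclostome
and tunicates deep; per-site substitution probability = rate × relative
depth, default rate 0.40 giving ~2 % divergence for the human-like member
and ~40 % for the lamprey-like member). That asymmetry is not cosmetic:
it is what makes detection cutoffs permissive relative to the
best-conserved members, as in the real gene sets. Each species carries
one representative and, with probability 0.5, one extra isoform (5 %
further diverged), exercising the any-transcript completeness rule.

Defect classes are planted disjointly, one per family, each tripping
exactly one derivation stage; families failing an early stage contribute
no late-species ortholog, so defect classes cannot interact at the RBH
stage. Duplication defects place a duplication node *on the spanning
subtree* of the members (the members really descend from two copies);
a pre-lineage duplication class (dated at the phylum) must survive,
exercising the dating logic. Assemblies are built by back-translating a
member with most-frequent codons (complete), truncating it 5′ to a stated
coverage fraction in (0, 0.7) (partial), or omitting it (missing), plus
GC-matched (±2 %) random decoy contigs with low read counts. Read-pair
simulations draw fragment spans from a truncated normal (optionally a
two-mean mixture) with positions consistent with outer-span semantics.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indels and alignment uncertainty, compositional
bias and low-complexity sequence, sequencing error and coverage
variation, assembly artifacts (chimeras, collapsed paralogs), incomplete
isoform annotation, and real divergence-time structure beyond the fixed
depth profile. Results on real data additionally depend on the quality of
the external ortholog groups and gene trees consumed.

## Problem sizes and numerical choices

The standard verification runs use 100 families for derivation recovery,
a 50-gene set for completeness recovery (80/10/10 planted), 10 genes for
cutoff-oracle equivalence, 200 random length lists for N50, 100
replicates of 10 000 pairs for insert-size calibration, 8 × 40 contigs
for merge-clustering, and 50 audit cases. The insert-size bound
(|error| < 2·sd/√n) is calibrated to ~95 % theoretical coverage, so the
observed replicate rate hovers at its threshold by construction.

Determinism: all randomness flows from explicit seeds
(`numpy.random.default_rng`); the HMMER engine is seeded (default 42) for
profile construction and search; MAFFT is deterministic for fixed input.
Ties in greedy dedup are broken by (length, contig id); cluster and locus
ids are assigned in sorted order, making partitions independent of input
assembly order.

## Known limitations

* Genomic (spliced) assessment is not implemented; input is assumed to
  be transcript-like, translated in six frames.
* The built-in clustering is O(n²) in surviving contigs and meant for
  desk-scale inputs; external engine adapters can replace it.
* Best-hit ranking uses raw local-alignment scores, not E-values; at
  proteome scale an E-value-ranked scorer may rank borderline hits
  differently.
* HMMER2-format export for legacy CEGMA is not provided; profiles are
  HMMER3 text.
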