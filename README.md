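# corevert

Core vertebrate gene sets for assembly completeness assessment: derive a
lineage-specific set of strictly one-to-one orthologs, compile it into
profile HMMs with per-gene bit-score and length cutoffs, score genome or
transcriptome assemblies against it, and compute the assembly statistics
used to compare de novo assembly strategies.

**Who it is for.** Groups assembling transcriptomes (or genomes) of
species without a reference, who need a trustworthy completeness score —
and anyone building a CEGMA/BUSCO-style reference gene set for a taxon of
interest. Completeness scores are only as good as the reference set:
families harboring ancient paralogs inflate the score, because a
surviving duplicate (H6PD, say) is happily detected in place of the lost
ortholog (G6PD). `corevert` builds sets in which that cannot happen.

## The method

Starting from precomputed ortholog groups, event-annotated gene trees,
and a species taxonomy, the derivation applies four filters and logs the
count after each:

1. keep groups where every required species has **exactly one gene**;
2. keep groups with **at least one outgroup ortholog** (e.g. tunicates
   for a vertebrate set);
3. add a late-released species by **reciprocal best hit**
   (Smith–Waterman, BLOSUM62, gap 11/1) and keep groups gaining exactly
   one ortholog;
4. keep groups whose gene tree shows **no duplication node inside the
   lineage crown clade** on the paths among the family's members.

Each surviving family *f* is compiled to a profile HMM; two bit-score
cutoffs govern assessment of a candidate protein *c* with score
*S(f, c)* and profile match-state coverage *cov(f, c)*:

- detection cutoff *t_det(f)* = min over members *m* of the score of *m*
  against the profile rebuilt without *m* (leave-one-out);
- completeness cutoff *t_comp(f)* = min over species *s* of
  max over transcripts *x* of *s* of *S(f, x)* — any isoform of a true
  ortholog is a full-length match, and every known ortholog clears its
  own family's cutoff by construction.

A gene is **complete** in an assembly iff some six-frame ORF candidate
has *S ≥ t_comp* and *cov > 0.70*; otherwise **partial** iff some
candidate has *S ≥ t_det*; otherwise **missing**. The completeness score
is the percentage of complete genes. Assembly-level metrics include N50
(largest *L* with Σ{len ≥ L} ≥ Σ/2), a per-locus N50 over one
representative contig per subcomponent, read-count filtering (drop
contigs with < 5 mapped reads), properly-paired mapping rates,
insert-size inference from 50 nt-truncated mates (outer span; fragment =
insert + adapter length), and two-stage assembly integration (99 %
dedup, then 95 %/50 bp overlap clustering with single-linkage locus
reassignment).

A synthetic-data module generates every input with planted ground truth
(defective families, planted gene statuses, simulated read pairs), so the
entire pipeline is testable offline. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

Simulate eight families (one missing a required species, one lacking
tunicate orthologs, two carrying a vertebrate-lineage duplication),
derive the core set, build profiles and cutoffs, and assess an assembly:

```sh
cat > scenario.json <<'EOF'
{"n": 8,
 "defects": {"missing_species": 1, "no_outgroup": 1,
             "lineage_duplication": 2},
 "seed": 7}
EOF
corevert simulate --scenario scenario.json --out sim
corevert build-set --groups sim/groups.tsv --trees sim/trees \
    --taxonomy sim/taxonomy.nwk --panel sim/panel.json \
    --late-proteome sim/late_proteome.faa \
    --ref-proteome sim/reference_proteins.faa --out set
corevert profile --set set/core_set.json \
    --proteome sim/reference_proteins.faa \
    --proteome sim/late_proteome.faa --out dataset
corevert assess --set dataset --assembly assembly.fa \
    --locus-map loci.tsv --out report.json
```

`build-set` prints the derivation log:

```
derivation log: one_to_one=7, outgroup=6, rbh=6, tree_validated=4
```

— 8 groups enter, the missing-species family falls at stage 1, the
outgroup-less family at stage 2, and the two hidden-duplication families
at tree validation, leaving the 4 clean families. Assessing an assembly
that contains full-length coding sequences for three of the four genes
and a 50 %-truncated one for the fourth prints:

```
complete 75.0 % (partial-inclusive 100.0 %)
```

and `report.tsv` holds the per-gene detail:

```
gene_id	status	best_score	best_coverage	copies
fam0001	complete	915.15	1.0000	1
fam0002	complete	601.13	1.0000	1
fam0004	complete	581.57	1.0000	1
fam0005	partial	467.10	0.5000	0
```

`fam0005`'s best hit scores far above the detection cutoff but covers
only half the profile's match states — partial, exactly as planted.

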