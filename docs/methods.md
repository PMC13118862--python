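# Methods

This note documents the models and procedures `holotag` implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Tag model

A type IIB restriction enzyme is described by an `EnzymeSpec`: an
IUPAC recognition pattern plus left and right flank lengths. The
default is BcgI — recognition `CGANNNNNNTGC` (12 nt), flanks 10 + 10,
hence 32-nt tags. The literature quotes type IIB fragments as
"20–33 bp" depending on the enzyme and on whether terminal overhangs
are counted; we fix the BcgI tag at 32 nt (overhangs excluded) and
keep the geometry fully configurable so other enzymes can be
expressed. Because the physical tag length is a convention, absolute
tag counts are never compared against external databases.

Coordinates are 0-based, half-open, plus-strand. Soft-masked
(lowercase) input is uppercased. Site finding reports every position
where the pattern (or its reverse complement) matches, overlapping
matches included. An `N` in the sequence satisfies only a fully
degenerate (`N`) pattern position — constrained positions never match
`N` — and any tag window containing `N` is skipped and counted, with
its reason (`flank` or `ambiguous_base`), rather than expanded into
its possible resolutions: degenerate tags would inflate false matches.

All tags are keyed by their **canonical** form, the lexicographic
minimum of the window and its reverse complement, because sequencing
observes tags in unknown orientation.

## Database construction

Per genome, only tags occurring exactly once (single-copy) are marker
candidates; a tag that is multi-copy in genome A but single-copy in B
is treated as absent from A. A genome with no sites is flagged
`no_site`, one with no single-copy tags `no_unique_tag`; both are
excluded but reported.

Specificity assignment computes, per tag, the longest common prefix of
the seven-rank lineages (kingdom → species) of all genomes carrying
it; the tag is specific to the deepest rank of agreement. Tags whose
carriers disagree even at kingdom are counted as nonspecific and
excluded from the profiling map. "Unresolved" lineage labels are
ordinary strings: two genomes share a rank only if the literal labels
match, so distinct unresolved lineages remain distinct detectable
species. Species-specific tag counts per species are the *theoretical
counts* used as abundance denominators.

The host tag set is the single-copy filter applied to the host genome
(one round within the whole genome). Cross-redundancy removal then
deletes every canonical tag present on both the host and microbial
sides from **both**; species (and their genomes) left without any
species-specific tag are flagged `removed_by_deredundancy` and
excluded from theoretical counts but retained in reports. After this
step the host set and microbial map are provably disjoint (tested
exhaustively).

The database serializes as a versioned, sorted, gzip TSV with the
enzyme geometry in the header; output is byte-deterministic so builds
can be diffed.

## Read processing

Three whole-read drop rules, applied in fixed order for attribution
(a read failing any rule is dropped regardless): (a) any `N`; (b) a
homopolymer run strictly exceeding 10 bases (11 identical bases drop
the read, 10 do not); (c) strictly more than 20% of bases below Q10.
Reads are never trimmed. Rule (b)'s "exceeding" is read as a strict
inequality.

Tag extraction takes, per read, the leftmost recognition match on
either strand whose full window fits inside the read; windows
containing `N` are passed over in favour of later clean sites. One tag
per read: the physical type IIB insert is a single excised fragment,
and multiple matches indicate chimeras. Paired-end mates are
independent reads.

Two implementations exist with identical semantics: a per-read
string/regex path (the reference) and a matrix path over
`(n_reads, read_length)` uint8 arrays whose inner scans are numba
kernels (pure-numpy fallbacks included). Their equivalence is
property-tested on randomized read sets including `N`s, homopolymers
and both orientations. The matrix path is what makes 10^7-read
libraries practical on one core.

## Profiling

Observed canonical tags route exactly: host if in the host set,
microbial if in the microbial map, else unassigned (the unassigned
*counter* is retained, not just its total). Mapping rates are exact-
match fractions of site-bearing tags, so a host read whose tag carries
a SNP allele or a sequencing error counts as unassigned in the rates —
mirroring how alignment-based mapping rates are computed from a
reference the individual does not exactly match.

Species evidence accumulates over species-specific tags only:
`reads_i` (read count) and `tags_hit_i` (distinct tags with >= 1
read). Presence requires `G_i = sqrt(reads_i * tags_hit_i) >= 5`
(threshold configurable; at the default, 25 reads on one tag or 5
reads on 5 tags suffice). Abundance divides reads by the theoretical
tag count — correcting for genome size and site density — and
normalizes over detected species. Read counts, not distinct tags, feed
the numerator: read depth carries the quantitative signal, distinct
tags only the presence evidence.

Replicate concordance reports species counts, shared species, Jaccard,
and Pearson r over the union abundance vectors (absent species = 0);
r is reported as undefined for empty or constant vectors.

## Genotyping

Host-routed **plus unassigned** observations are assigned to reference
tag loci by Hamming distance <= 2, considering both orientations;
exact matches win, ties between equally distant loci discard the
observation as ambiguous (counted). Including unassigned tags is
essential: a non-reference SNP allele is by definition not in the host
set, and without it heterozygotes could never be recovered. The
implementation uses a pigeonhole segment index (three segments; any
tag within distance 2 of a reference matches at least one segment
exactly), verified identical to brute force.

Calling is a two-allele binomial likelihood contest (the codominant
hom/het decision expressed as a testable rule): with top-two counts
`n1 >= n2`, `M = n1 + n2`, call het when
`Binom(n2; M, 0.5) > Binom(n2; M, err)`, hom otherwise, ties toward
hom; `err` defaults to 0.01 and is config-exposed. Alleles beyond the
top two count toward the >= 4x depth gate but not the contest, for
robustness to rare errors. No called genotype ever has depth < 4
(asserted over all simulations).

Concordance between two call sets compares loci called in both,
stratified by the genotype class of the first; agreement is undefined
(reported as such) for empty strata. Allele-sharing distance is
`1 - mean(IBS/2)` over jointly called loci. Neighbor joining follows
the Saitou–Nei agglomeration with the standard Q-matrix, branch-length
and distance-update formulas; negative branch lengths are clamped to
zero and ties break deterministically toward the smallest index pair.
On additive inputs the tree reproduces the generating path metric to
1e-9 (tested, and cross-checked against an independent NJ
implementation). PCA mean-centers the 0/1/2 coding (copies of the
non-major allele), imputes undetermined calls to the locus mean (a
config switch drops incomplete loci instead), drops monomorphic loci,
and fixes signs so each component's largest-magnitude loading is
positive.

## Community statistics

Shannon uses the natural log by default (a `base` switch gives log2),
zero terms contribute nothing. Simpson is the Gini–Simpson form
`1 - sum p^2`. Chao1 always uses the bias-corrected form
`S_obs + F1(F1-1)/(2(F2+1))` so zero doubletons are defined — a
documented divergence from the classical `F1^2/(2 F2)`. Bray–Curtis is
`sum|x-y| / sum(x+y)`. PERMANOVA computes the pseudo-F from squared
distances (`SS_T = (1/n) sum_{i<j} d_ij^2`, within-group analogues per
group), permutes labels with a seeded generator, and estimates
`p = (1 + exceedances) / (1 + N)` so p is never zero. All five are
cross-checked in the test suite against scikit-bio/scipy
implementations rather than delegated to them, keeping the
implementation and the oracle independent.

## MAG quality filter

Retention requires completeness > 20 (exclusive), contamination < 10
(exclusive) and genome size in [1, 6] Mb (inclusive — the packaged
table contains records at exactly 1.00 and 6.00 Mb that belong to the
retained set). Summaries are arithmetic means with sample (n-1) SDs,
rounded to 2 dp in reports only. The packaged 57-MAG table is a
versioned fixture; its summaries are always recomputed, never stored.

## Synthetic data

The generator is engineered so truth tables are exact, not
approximate:

- Background sequence is rejection-sampled (scan-and-mutate) to be
  recognition-free, so a genome contains exactly its planted sites.
- Planted tags carry exactly one recognition site and no homopolymer
  run over 10 nt; read filler is sanitized the same way, so an
  error-free library passes the quality filter in full and extraction
  recovers exactly the planted tag multiset (tested as an identity).
- Host SNPs are placed strictly inside tag windows and never at
  constrained recognition bases, so every allele remains an
  extractable tag; heterozygous loci place the alternate allele on one
  haplotype, homozygous-alternate loci on both.
- Reads embed one tag at a random offset in random orientation;
  per-base substitution errors are applied afterwards at the
  configured rate; qualities follow a constant (default Q40) or
  two-tier model.
- Everything derives from a single seed through independent spawned
  streams for genomes, host and reads, so replicate read draws share
  one truth; generation is deterministic per seed.

Default study conditions: 20 species, log-normal abundances
(sigma = 1), 50 sites per 20-kb genome, a diploid host with 200 SNPs
across 250 tag loci at 50% heterozygosity, 99% host read fraction,
150-nt reads, 0.5% per-base error, Q40. These are the conditions the
validation studies run under.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: indels and realistic error spectra,
PCR/amplification bias, chimeric inserts, uneven coverage along the
genome, real taxonomies with shared ancestry in sequence space (tags
of different simulated species are unrelated random sequences, so
cross-species tag sharing is rarer than in nature), and real reference
databases' redundancy. Results on real libraries depend on database
completeness in a way no simulation can certify.

## Validation studies and sizes

`scripts/acceptance.py` (and the mirroring acceptance tests) run:

- the packaged MAG table's summaries and filter;
- digestion and specificity engines against naive reference scanners
  (100 random genomes of 1–50 kb; exhaustive LCA on toy taxonomies);
- abundance recovery at full library scale: 2 x 10^7 reads at 99% host
  contamination (~2 x 10^5 microbial tag reads), simulated and
  processed in ten 2 x 10^6-read draws to bound memory — checking
  Pearson r(true, estimated), the G-score detection guarantee for
  species with >= 25 reads, and the abundance normalization identity.
  The in-suite test uses 4 x 10^6 reads to keep the default test run
  fast; the script runs the full condition;
- replicate concordance: two independent draws of the same truth with
  2 x 10^5 microbial reads each, generated at host fraction 0.5 so the
  microbial depth matches without another full-scale host simulation
  (the 99%-host routing condition is already covered by the recovery
  study);
- genotype recovery: 200 loci at 20x across 20 replicate pairs, caller
  err 0.01 over the generator's 0.5% base-error regime; concordance is
  pooled over both comparison directions of each pair, which makes
  every discordant event count once in each stratum and the
  heterozygote-vs-homozygote agreement ordering a property of the
  strata sizes rather than of direction luck;
- NJ exactness on hand-built additive 4- and 6-taxon metrics;
- PERMANOVA against exhaustive enumeration at n = 6 and a 500-replicate
  null calibration of the type-I error at alpha = 0.05;
- the Shannon/Simpson/Chao1/Bray–Curtis closed forms.

## Known limitations

- Exact-match classification understates host mapping rates for
  individuals distant from the reference; the genotyping stream
  compensates, the reported rates do not.
- Multi-allelic loci are reduced to their top two alleles for calling.
- The G-score threshold (5) is a convention of the tag-profiling
  workflow family, not estimated from data.
- PERMANOVA assumes exchangeable samples; group-size imbalance with
  heteroscedastic dispersion can inflate its pseudo-F, as in any
  PERMANOVA.
- The NJ implementation targets cohort-scale trees (tens of taxa), not
  thousands.
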