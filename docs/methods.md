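# Methods

## The inference problem

A polymorphic paracentric inversion segregates as a pair of arrangements
(standard and inverted); each diploid carries a dose in {0, 1, 2}.
Recombination suppression in heterokaryotypes lets the two arrangements
diverge at SNPs inside the rearranged span and tightly around its
breakpoints, while gene flux (double crossover, gene conversion) slowly
erodes that association. The package exploits this divergence three ways:
it reads dose off the leading axis of a local PCA; it distills the signal
into small panels of individually diagnostic tag SNPs; and it examines
arrangement history on distance trees built from breakpoint-flanking SNPs.

## Local-PCA karyotyping

Genotypes at biallelic in-span SNPs are converted to alternate-allele
counts. Sites are filtered on minor-allele count (default ≥ 3) and
alternate-allele frequency (default ≥ 0.15; lowered per inversion when a
rearrangement is rare), and sites inside exclusion spans are dropped — the
mechanism used when one inversion nests inside another and only SNPs
proximal to the nested span are informative for the outer one.

PCA uses per-site mean imputation of missing cells and centering only. No
variance standardisation is applied by default (a flag enables it): with
centering only, a matrix whose columns are multiples of the dose vector
maps to exactly three PC1 values with the heterokaryotype at the midpoint,
and we prefer keeping that geometry exact over an unverifiable guess at
what scaling other pipelines use. Eigenvector sign is fixed by forcing
PC1 to correlate positively with per-sample mean alternate-allele count
(and, for later PCs, the largest-magnitude coordinate positive), removing
the arbitrary sign of SVD output from all downstream behaviour.

Stripe assignment is deliberately algorithmic where a human would eyeball
a scatter plot: 1-D 3-means on PC1, initialised deterministically at the
minimum, median and maximum. The silhouette score on PC1 is the
separation diagnostic; below a floor (default 0.6) clustering is declared
failed and no doses are emitted. The floor operationalises "stripes not
discernable"; 0.6 sits between the near-1 silhouettes of clean cohorts
and the ≲0.4 values seen when an admixed population blurs the stripes.
The leave-one-population-out diagnostic reruns the PCA without each
population and reports the silhouette gain; it is advisory only —
excluding a population is an analyst's decision.

Stripe→dose polarity comes from cytogenetically karyotyped anchors when
available: of the two candidate flank polarities, the one contradicted by
the fewest anchors wins, and a conflict is declared (flank stripes left
unassigned) when more than 5% of anchors disagree with the winner. The 5%
tolerance absorbs the known error rate of cytogenetic scoring (a few
percent) without letting a mislabelled batch flip polarity silently. With
no anchors, polarity falls back to the reference convention — the
reference assembly is homozygous standard, so the stripe with the lower
mean alternate-allele count is dose 0 — and is flagged as such.

## Tag discovery

Karyotyped samples are split 75/25 (training/validation), stratified by
dose with largest-remainder rounding so both the per-class and overall
train fractions match. "Bootstrap replicates" of the training set are ten
stratified 75% subsamples drawn *without* replacement — following the
procedure's own description as sub-samples — not classical resampling;
the term is kept in output metadata for traceability.

Within each replicate, every in-span biallelic SNP with in-replicate minor
allele frequency ≥ 5% is scored. Concordance for dose class *k* is the
fraction of class-*k* samples, among those with a non-missing genotype,
whose alternate-allele count equals *k*; the call rate is the non-missing
fraction. The denominator choice (non-missing members only) keeps the two
statistics independent, as they are reported. A site is *evaluated* in a
replicate when it passes the in-replicate MAF filter and every class has
at least one called member; recomputing MAF per subsample is what allows
a site to miss some replicates. Class means are taken over evaluated
replicates only, and the summary statistic is the minimum of the three
class means — conservative under class imbalance, because a tag that only
works for the majority class cannot hide behind a pooled average.

Selection keeps sites with n_reps ≥ 8, every class call rate > 0.90 and
every class concordance > the per-inversion threshold (default 0.80);
both rate thresholds are strict inequalities, matching the criteria's
"greater than" wording. Genotypes with GQ < 20 are masked before any
statistic is computed.

Discovery can be partitioned (typically by taxon) and panels from
different partitions are never merged: when arrangement-allele association
differs between taxa — as with inversions in near-perfect linkage with
taxon-structured haplotype backgrounds — pooled discovery finds almost
nothing, while per-taxon discovery recovers taxon-private panels. The
pooled-failure mode is reproduced in the test suite with a simulation in
which tag polarity is inverted in one taxon.

## Scoring

A sample's computational karyotype score is the mean alternate-allele
count over panel tags with a non-missing, GQ-passing genotype, matched by
chromosome, position *and* alleles (an allele mismatch at a tag position
excludes the tag: polarity is the tag's entire information content). The
assigned dose is the nearest integer, with ties at 0.5 and 1.5 resolved
toward the heterozygote — conservative under the low-coverage artifact
that converts true heterozygotes into random homozygotes. The
supporting-tag fraction is the share of scored tags equal to the
*assigned (rounded) dose*: agreement with a fractional mean would be
ill-defined for integer genotypes, so the rounded reading is the
documented interpretation. Heterospecific application of a
taxon-partitioned panel is flagged (`taxon_mismatch`), not blocked, as is
a call resting on fewer than 10 tags (`low_tag_count`; panels of 10–12
ascertained tags have been sufficient in practice, but the flag surfaces
the risk).

The low-coverage signature falls out of the arithmetic: with heterozygote
dropout *h* resolving to either homozygote with probability ½, a true
heterozygote's expected score stays 1 (the score is unbiased) while its
expected supporting fraction is 1 − *h*; at *h* = 0.7 the dose call
survives in ≥ 95% of samples with ≥ 200 tags but mean support drops to
≈ 0.30.

## Breakpoint trees

Sites within a flank (default 5 kb, per-inversion override) of either
breakpoint with minor allele frequency ≥ 0.01 are selected; distances are
Euclidean on alternate-allele counts with per-site mean imputation — the
same missing-data policy as the PCA stage, chosen over pairwise-complete
distances to keep one policy everywhere and guarantee a symmetric matrix.

Neighbor-joining is the canonical Saitou–Nei agglomeration, implemented
with a deterministic tie-break (first minimum of the Q matrix in row-major
order, i.e. the lowest-index pair) so runs are exactly reproducible;
negative branch lengths are clamped to zero and counted. The
implementation is cross-checked in the tests against random additive
trees (topology recovery up to 12 taxa), a brute-force least-squares
topology oracle (≤ 6 taxa), and an independent NJ oracle on the printed
four-taxon instance.

Bootstrap trees resample sites (columns) with replacement — the standard
phylogenetic bootstrap — and support is the transfer bootstrap estimate:
for a reference edge with lighter side p, each replicate contributes
1 − δ/(p − 1), where the transfer distance δ is the minimum Hamming
distance (up to complement) between the edge's bipartition and any edge
of the bootstrap tree, trivial edges included. δ is computed exactly by
scanning all bipartitions of each bootstrap tree with bitmask arithmetic;
this exact scan is used at every tree size handled here, since it stays
comfortably fast for cohorts of a few hundred samples. TBE is reported
alongside the classical proportion (δ = 0); TBE ≥ classical always, and
the two coincide on perfectly supported edges.

## The simulator

The generator is allele-frequency based with per-site independence — not a
coalescent — because the inference stages consume only (i) the three-class
mixture geometry, (ii) arrangement–allele association and its erosion, and
(iii) class imbalance, missingness and GQ structure, all of which this
model produces with analytically checkable expectations. It does **not**
produce background linkage disequilibrium, allele-frequency spectra
shaped by demography, or sequencing-depth-driven error correlation, so
green tests certify algorithmic correctness on the assumed structure, not
performance on any particular natural cohort.

Per sample, dose is Binomial(2, p) with p the population's inversion
frequency (Hardy–Weinberg). Diagnostic sites are fixed-different between
arrangements, with the alternate allele on the inverted arrangement
(mirroring a homozygous-standard reference assembly); each haplotype leaks
to the other arrangement's allele with probability `gene_flux`. Neutral
site frequencies are Uniform(0.05, 0.95), optionally redrawn per taxon for
a `frac_taxon_diff` share of sites. Breakpoint-flank sites may also be
arrangement-linked (`frac_fixed_diff_flank`, defaulting to the in-span
fraction) — breakpoint-proximal SNPs are the most arrangement-associated
in real data, and this is what gives the flank trees their two-arrangement
clades. Artifacts apply in a fixed order — genotype error (replacement by
a uniform draw), heterozygote dropout (1 → 0 or 2 with equal probability,
mean-preserving), missingness — then GQ is drawn Normal(45, 10), rounded
and clipped to [0, 99], independent of the error mechanism by default so
GQ-masking tests are controlled (`gq_correlated` couples them). A
`cyt_fraction` of samples (default 0.25, roughly the share of
cytogenetically karyotyped specimens in the cohorts this emulates) carry
truth-valued cytogenetic labels to exercise anchoring.

Default study conditions: one population of 600 diploids at inversion
frequency 0.4, 2,000 in-span sites with 5% fixed differences, artifacts
off. The test-suite and acceptance-script problem sizes (600–10,000
sites, 100–600 samples, 200 bootstraps) were chosen as the smallest
instances at which every statistical check has comfortable margin.

## Numerical and degenerate-input conventions

- Missing sentinel: a single reserved value (−1) distinct from all valid
  alt-counts and GQs; GT and GQ missingness are independent.
- Coordinates are 1-based inclusive everywhere (VCF convention).
- Multiallelic and indel records are skipped, never decomposed: allele
  counting semantics are only defined for biallelic SNPs.
- MAF has a recorded mode switch: alternate-allele frequency at the PCA
  stage, minor-allele frequency at the tag and tree stages, matching the
  stage-specific definitions; the minor-allele *count* filter is always
  on the minor allele.
- GQ masking is strictly-below (`GQ < 20` masked, 20 kept); cells with
  missing GQ are not masked (no evidence either way).
- Sample-exclusion boundary: more than 50,000 missing 2R genotypes
  excludes; exactly 50,000 is retained.
- Zero-variance PCA input, < 2 surviving sites, < 3 samples, empty
  bipartitions and all-missing score vectors are explicit errors or
  flagged no-calls, never silent zeros.

## Known limitations

- The three-stripe model assumes one biallelic arrangement polymorphism;
  systems with multiple co-segregating inversions in one window need more
  than three clusters and are out of scope.
- Automated 1-D clustering on PC1 is a declared stand-in for visual
  stripe assignment; strongly oblique or diffuse stripe geometries that a
  human might still read will fail the silhouette floor instead.
- The scorer ignores genotype likelihoods; at very low coverage the
  supporting-tag fraction flags trouble but cannot recover information
  the genotype caller discarded.
- TBE supports are computed from distance-based NJ replicates only; no
  model-based phylogenetics, rooting or dating is attempted.
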