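# Methods

This note records the statistical definitions, conventions and design
choices baked into haplopop, in the spirit of a model-description appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and coordinates

All internal coordinates are 0-based half-open; VCF and GFF3 are converted
at the format boundary and nowhere else. Genotypes are haploid allele
indices (0 = reference, 1.. = alternates, −1 = missing). Diploid-style
homozygous calls in an input VCF collapse to one allele; heterozygous calls
are loaded flagged and masked by the call filter, since a heterozygous call
in a haploid organism is read as a genotyping error. Multi-allelic sites are
retained everywhere and handled by the general k-allele forms of each
statistic; only the LD stage reduces them (major-allele-vs-rest, flagged).

The analysis substrate is the *complete-site matrix*: polymorphic sites
where every sample has a retained call, together with per-chromosome
"callable" interval sets that stand in for the retained monomorphic sites.
Carrying the callable track explicitly is what gives per-site statistics
correct denominators without materialising an all-sites matrix; an all-sites
VCF or a BED callable track are both accepted.

## QC and masking

Read filtering follows a fixed order: end-trimming to the first/last run of
10 bases at phred ≥ 30; removal of 3′ regions past 150 and then 200 bp when
≥ 10% of the region is below phred 20 (both checkpoints are applied
sequentially); whole-read removal at ≥ 10% bases below phred 20; adapter
trimming against a user-supplied list (no adapter discovery); minimum length
45 bp; removal of single-base-composition reads, reads with ≥ 3 consecutive
Ns, and pairs that are mutual reverse complements; pair-consistent removal.

Call filtering: site QUAL ≥ 30, per-sample depth ≥ 10 and below an upper
bound. The phrase "below 3 times the standard deviation of the average
depth" is ambiguous; the default bound is mean + 3·SD per sample (the
standard outlier rule), with `depth_rule="literal_3sd"` preserving the
literal reading of 3·SD as an absolute cap.

Repeat masking scans each chromosome for maximal runs with period 1, 2, 3
(`s[i] == s[i-p]`). A run is masked when it contains > 9 bases (period 1) or
> 5 complete units (periods 2 and 3); partial trailing units are included in
the masked span; period-2/3 runs that are pure homopolymers are left to the
period-1 rule. Each masked run, and each indel anchor, gets 10 bp flanks.
Masks are unions: overlapping reasons coexist, and applying a mask twice is
a no-op.

## Site classification and Nei–Gojobori accounting

Classes are assigned with precedence CDS > UTR > intron > ncRNA >
intergenic. tRNA/rRNA/snoRNA, pseudogenes, repeats and masked landmark
features are *excluded* rather than intergenic, so "intergenic" means
"between annotated elements". Elements with < 50 called bp or ≥ 1/3 missing
sites are removed from their class. Intron sites run from position 8
(1-based from the 5′ splice site, on the sense strand) to the base before
the leftmost CTAAC branchpoint match at or after position 8; an exact match
is preferred over a one-mismatch match, ties break leftmost; introns with no
match are excluded. An optional strict-intergenic mode additionally excludes
a configurable flank (500 bp reproduces the published robustness check)
around UTR boundaries.

NG86 site counts: at each codon position the synonymous fraction is the
share of the three single-base changes preserving the amino acid; changes
*to* stop codons count as nonsynonymous, so syn + nonsyn = 3 exactly for all
61 sense codons. Codon differences are averaged over all orderings of the
differing positions, excluding pathways through stop codons and
re-weighting; if every pathway hits a stop the raw difference count is split
equally (a fixed, flagged convention for an edge case the data rarely
exercises). Codons containing masked or ambiguous bases, and codons where
any sample carries a stop variant, are excluded entirely — for site counts
and difference counts alike. Per-gene synonymous site totals are per-sample
counts averaged over samples; gene-level Tajima's D uses all called CDS
sites of the gene, and πN/πS histograms restrict to genes with > 200
synonymous sites.

Per-class pooled π sums pairwise differences over all sites of the class and
divides by the class's called-site total (classes pool sites; elements are
not weighted equally). For CDS SNPs the site's pairwise differences are
split between the synonymous and nonsynonymous pools by the position's NG86
fraction.

## Diversity statistics

π per site is the proportion of discordant unordered sample pairs,
`(n² − Σ_a c_a²) / 2 / C(n,2)`; region π averages over *called* sites, so
monomorphic sites dilute the numerator. Tajima's D uses the standard 1989
constants; it is undefined (NaN) at S = 0 and for n = 2 (zero variance).
Windows anchor at position 0 with the configured step; the first window
whose end reaches the chromosome end is the last, emitted at its true
extent (a 100 kb chromosome at 20 kb/4 kb gives exactly 21 windows). The
folded spectrum bins by the count of the most common non-major allele,
tallying multi-allelic sites separately; a collapse-group option treats a
strain set as one sample and drops sites varying within it. Dxy is the mean
cross-group per-site difference proportion over the window's called sites,
reported with within-group π of the larger group as a control.

## Structure

p-distance uses all called sites (SNP differences over the callable total) —
the constant denominator makes this equivalent, up to scale, to SNP-only
distances. Neighbor joining is the standard Saitou–Nei agglomeration with a
deterministic tie-break (lexicographically smallest pair of representative
leaf labels); branch lengths are reported as computed, including negative
ones. SNP thinning follows the published rule: a uniform random start among
SNPs within 50 kb of the 5′-most SNP, then repeatedly the closest SNP at
least 50 kb downstream; the selection depends only on positions and the
seed. PCA encodes genotypes 0/1 (major/minor), centres columns without
variance scaling (a flag enables it), drops constant columns, and fixes
signs by making the largest-magnitude loading positive.

## LD and the recombination rate

r² is the squared correlation of 0/1 allelic states across haploids,
computed for within-chromosome pairs with both MAFs ≥ 10% and distance up to
500 kb (banded evaluation keeps this linear in the number of in-range
pairs). Distances bin into non-overlapping 1 kb half-open bins. The fit
minimises the pair-count-weighted squared error between bin means and
σd²(ρ·midpoint) over bins inside 1–100 kb, with a bounded 1-D search over
log ρ (so the noise-free inversion is recovered to ~1e-9 relative and ρ → 0
is reachable for flat decays).

σd² approximates the *population* quantity; observed sample r² additionally
carries a ≈ 1/n sampling inflation. The estimator therefore exposes a
finite-sample adjustment (σd² + 1/n), off by default so the plain published
curve is the default path. The simulation-recovery check in the test suite
fits with the adjustment, because its target is the generating ρ of sample
data; the unadjusted default fit recovers the same ρ with a modest downward
bias (geometric-mean factor ≈ 2 at 1 Mb).

Scaling note: with pairwise coalescent time T₂, θ = 2T₂μ and the σd²
argument is C = 2T₂r·d, so ρ̂/θ̂ estimates r/μ — the "recombination ≈ 1/100
of mutation" ratio is scale-free.

## PHS

Identity tracts are maximal intervals over which a sample pair agrees at
every compared site. Boundaries sit at the flanking discordant positions
(exclusive) or chromosome ends; a span ≥ 30 kb (physical bp) with no
compared site terminates tracts at its edges and contributes no tract
itself. Genetic lengths come from per-chromosome quartic bp→cM polynomials
fitted to marker tables by least squares, clamped to the marker range, and
repaired to their running maximum on a 1 kb grid if non-monotone (flagged;
exact polynomial evaluation is kept when no repair is needed). Pair moments
d̄ and σ (population SD) pool all tracts genome-wide, not only tracts
spanning SNPs. Clone-like pairs (σ = 0 or fewer than two tracts) contribute
Z ≡ 0 with a degenerate flag, so a pair of identical strains cannot dominate
the statistic. At a pair's own discordant site the spanning tract has length
zero; at a gap edge the tract starts at the edge.

PHS is computed for every allele with ≥ 2 carriers at every SNP. Candidates
are records at or above the empirical (1 − 0.001) quantile of their
carrier-count class (frequency conditioning, since the null distribution of
PHS depends strongly on allele frequency); a global-ranking mode exists. In
small scan sets a class's top-0.1% threshold degenerates to its maximum, so
"candidates" are the extreme records of each class — the sweep-detection
test accordingly asserts that the flagged candidates inside an injected
sweep carry the sweep haplotype, not that one pre-named SNP is the class
maximum.

## Synthetic data

Genealogies come from msprime's coalescent with recombination (haploid
samples), which replaces any hand-rolled approximation: it is exact and fast
at these scales. Parameters are expressed on the pairwise-coalescent
timescale — θ is the expected per-site pairwise diversity, ρ the matching
scaled recombination rate — with defaults n = 32, θ = 0.003 and ρ = θ/100,
echoing the study system this emulates (≈ 0.3% diversity; effective
recombination two orders below mutation). The divergent clade is a
two-population split (default 3 coalescent-time units), which makes the five
members monophyletic and roughly fourfold diverged from the rest. The
reference carries the ancestral allele at variant sites; annotation is laid
out first and feature-interior sequence rewritten (stop-free CDS, GT..AG
introns with a CTAAC motif at offset ≥ 12, genuine low-complexity repeat
tracts, telomere/centromere landmarks) so every generator contract is
checkable, then mutations are dropped onto that sequence.

Signals are injected post hoc with recorded truth: a partial sweep copies
one carrier's haplotype across the interval; a divergent segment gives the
clade a new shared derived allele at each site with the target probability,
and the realized between-group dxy of the segment is measured from the final
matrix. Injections are exactly localized, which the tests verify.

What the generator does *not* emulate: sequencing error and depth variation
(fixture QUAL/DP are benign constants; the call filter is exercised by
dedicated small fixtures), gene conversion, mutation-rate heterogeneity,
sample contamination, and reference bias. Passing tests therefore validate
the statistical machinery and its conventions, not robustness to those
artefacts.

Problem sizes in the test suite are chosen to keep the full run in a few
minutes while leaving each check well-powered: 100 kb × 200 replicates for
neutral calibration, 1 Mb × 20 for ρ recovery, 500 kb × 20 for sweep
detection (a 50 kb sweep must remain a small fraction of the genome-wide
tract moments; at 200 kb it is a quarter of the genome and contaminates its
own null), 150 kb × 20 for clan recovery, 100 kb × 20 for the divergence
scan. The acceptance script uses the same conditions with 10 replicates per
stochastic rate.

## Known limitations

- The PHS scan is quadratic in sample count through the per-pair tract
  precomputation; n = 32 (496 pairs) is comfortable, hundreds of samples
  would want a sparser representation.
- The σd² fit assumes a single panmictic rate; population structure biases
  ρ̂ downward (visible when fitting the clade scenarios).
- Gene-level NG86 ignores within-codon phase ambiguity across samples with
  more than two haplotypes per codon only insofar as pathway averaging
  resolves it; this is the standard convention.
- The genetic-map repair (running maximum) flattens decreasing stretches
  instead of rejecting the map; strongly non-monotone marker data deserve
  inspection rather than silent repair — the flag is exposed for that.
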