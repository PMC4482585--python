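# Methods

This note documents the models, rules and numerical choices behind
`polygbs`, in the order data flows through the package.

## Population and sequencing model (simdata)

**Inheritance.** Samples are random-mating autotetraploids with polysomic
inheritance and independent loci: at a locus with A1 frequency `p`, a
sample's A1 copy number (dosage) is Binomial(4, p). No linkage and no
double reduction are modelled — every downstream operation treats loci
independently, so a locus-wise model is sufficient for testing them.
Recurrent selection is emulated as a deterministic frequency shift of
magnitude `shift_magnitude` (random direction, clamped to [0.01, 0.99]) at
a marked fraction of loci, not as explicit breeding cycles; that is enough
to give PCA a real signal to find while leaving most of the genome
undifferentiated.

**Allele frequencies.** `PopulationModel.random` draws per-locus A1
frequencies from Uniform(0.1, 0.9): discovered SNPs in a broad-based
outcrossed cultivar segregate mostly at intermediate frequency, and the
uniform default exercises the MAF filter on both sides of its threshold.

**Tags.** Each locus is a pair of 64-base tags that begin with the ApeKI
half-site remnant `CAGC` and differ at exactly one post-remnant position.
A GBS read is `barcode + tag`; barcodes default to a length-6 (hence
prefix-free) deterministic set.

**Depth.** Reads per sample-locus are Poisson(mean_depth x S_i x L_j) with
log-normal sample and locus multipliers of unit mean (defaults:
sample sd 0.4, locus sd 0.7 on the log scale) and a 5% dropout
probability. Real GBS depth is heavy-tailed across both samples and loci
over several orders of magnitude; the published accounts give ranges, not a
distribution, so the log-normal spread is a stand-in chosen once and
flagged here. An allele whose restriction site is flagged polymorphic
yields zero reads (allele dropout), which is how restriction-site mutations
bias dosage in real libraries.

**Errors.** GBS reads receive per-base substitutions (default 0.2%),
applied to the 64 tag bases; a substitution in the remnant makes the read
fail demultiplexing, as it would in practice. Amplicon reads instead
receive homopolymer indels (one inserted or deleted base at a
mononucleotide run of length >= 3, default rate 0.001 per run per read) —
the signature artefact of pyrosequencing chemistry. Truth tables count
*emitted* reads per allele, so error-bearing reads are still attributed to
their source allele; conservation tests rely on this.

**Amplicon panel.** `design_amplicons` builds one amplicon per locus
(~550 bp consensus embedding the A1 tag inside the first 400 bases), with
the plain A1/A2 haplotypes plus extra haplotypes carrying 1-3 additional
in-window, out-of-tag substitutions. Each sample's four haplotype copies
are drawn consistent with its true dosage, and `sample_amplicon_reads`
rejects any phase whose A1 copy number contradicts the truth. Real panels
sometimes cover two SNP loci with one amplicon; the generator does not,
because jointly phasing two loci through one haplotype set adds complexity
without exercising any additional code path — the validate module itself
accepts arbitrary loci-per-amplicon inputs.

**Seeding.** One master seed lives on the population model; read
generation and amplicon design derive child seeds by fixed offsets
(+1 GBS, +2 amplicons, +3 design), recorded in CLI output metadata. Every
operation is bit-reproducible for a fixed seed.

## Tag network (tagnet)

A read is *good* iff its barcode matches exactly, the cut-site remnant
follows, and the 64 post-barcode bases exist with no `N`; good reads are
trimmed to the 64-base tag. Reads shorter than barcode + 64 are dropped
(padding short fragments would only manufacture artificial tags). Tags
with more than `min_reads = 5` total reads are *good tags* (strict
inequality).

Hamming-distance-1 neighbors are found exactly by 4-piece indexing: a pair
differing at one base differs in exactly one 16-base quarter, so bucketing
on the other three quarters finds each pair exactly once; a quadratic
all-pairs scan serves as the oracle in tests. When assessing a tag's
partners, partners with fewer than `error_tolerance_rate = 0.03` times its
own count are set aside as sequencing-error tags; a SNP locus is emitted
only when each member's sole remaining partner is the other. The 0.03
default reproduces the published behavior of network-based GBS SNP
callers; it is a config parameter, not a constant. A1 is the
higher-count allele, ties broken toward the lexicographically smaller
sequence — an arbitrary but stable orientation.

Final per-allele counts are clipped at 127 (the storage cap of the
reference pipeline's output format), with the raw tallies retained so the
genotype-level filters can run on uncapped counts, mirroring the recovery
of counts from per-sample tag files.

## Genotype calling (gcall)

The one-read rule zeroes any allele supported by exactly one read, *before*
the ratio is computed, in every context (GBS and validation platform
alike) — uniform application keeps the two platforms' calls comparable.
With effective counts, `r = RC_A1/(RC_A1+RC_A2)`; zero effective total is
missing. Diploid: homozygous at `r <= 0.1` or `r >= 0.9` (boundaries
homozygous), heterozygous strictly inside. A corollary worth knowing: at
depth 1 every call is missing, because the single read is always erased.

Tetraploid dosage: the homozygous classes 4|0 and 0|4 are assigned exactly
on the diploid homozygote regions (`r >= 0.9`, `r <= 0.1`); inside the open
interval the dosage is the nearest quarter among {1,2,3}, with the
midpoints 0.375 and 0.625 resolved toward the balanced 2|2 class. Two
reasons: it keeps the two calling modes exactly consistent (a 4|0 call is
always a diploid HomA1, a 3|1 always a Het — verified exhaustively for all
count splits with total <= 200), and the toward-balanced tie is
conservative against dosage overcall, the dominant error mode at shallow
depth. Naive `round(4r)` violates the consistency property on
(0.875, 0.9) and was rejected.

`het_recovery_probability(depth, dosage, err)` gives the exact probability
of a correct diploid call by enumerating k ~ Binomial(depth, p_eff) A1
reads (p_eff folds in a per-read allele-flip probability `err`) and pushing
every split through the caller. At depth 4 for a true 2|2 heterozygote it
equals C(4,2)/2^4 = 0.375 and it is non-decreasing in depth.

## Filters (filters)

Whole-dataset level: samples below a good-read threshold are excluded
(default 1,000,000 reads — a population-scale value; desk-scale synthetic
runs pass `min_reads=0` or a scaled value); loci need call-based
MAF >= 0.05 and call rate >= 0.5, both boundaries inclusive. MAF is
computed from diploid calls (HomA1 counts two A1 alleles, Het one of each)
rather than raw read fractions: the read-level definition used inside the
reference pipeline is undocumented, and the call-based one is exactly
reproducible from the package's own outputs.

Genotype level: homozygotes with total RC < 11, heterozygotes with < 2
reads of either allele or min(RC)/total < 0.1 become missing. The filter
is idempotent and can only move calls to missing, never rewrite them —
both are tested properties. After genotype-level filtering loci are
re-screened at call rate >= 0.5 (toggleable), producing the final set; the
re-screened set is provably a subset of the dataset-filtered set because
filtering can only lower call rates.

## Validation (validate)

Reads are labelled by exact 64-base identity with either allele; remaining
reads are anchored to the consensus by a 20-base exact seed in the first
100 bases followed by ungapped extension (the generator selects
amplicon regions without long mononucleotide runs early in the sequence, so
a clean seed exists; indel-bearing reads simply mismatch downstream and
fall into the error partition, which is the correct fate for them).
Anchored reads spanning the tag window but mismatching are *imperfect*;
unanchorable or short reads are *unalignable*.

Haplotypes are defined over the first 400 consensus bases (per-amplicon
override available, e.g. to pull in a restriction site just beyond 400):
positions where a non-consensus base reaches 5% within-sample frequency in
at least one sample form the variant alphabet; reads project onto base
patterns at those positions; patterns reaching 5% in some sample are the
defined haplotypes. Sub-threshold patterns are attributed to sequencing
error and rescued onto the nearest defined haplotype within Hamming
distance 2 (the published analyses describe the partition but not a rescue
radius; 2 accommodates one real private variant plus one error), else
pooled as "other". The 5% rule is applied per sample with an any-sample
qualifier. A haplotype matches a GBS allele when its reconstructed
sequence reproduces the 64-base tag exactly.

Concordance classification per sample-locus: missing if either call is
missing; equal calls are concordant (hom/het by the shared class);
discordance is sub-classified by the GBS side's class, and two heterozygous
tetraploid dosages that differ are "discordant_ratio". The six-category
scheme has no slot for opposite homozygotes (one platform >= 0.9, the
other <= 0.1); those are tallied under discordant_ratio and are
essentially unobservable in practice. The after-filter table applies the
genotype-level filters to the GBS side only (the validation platform's
depth is orders of magnitude higher); filtering can only move records to
missing, so the transition counts (concordant-to-missing,
discordant-to-missing) fully reconcile the two tables — a conservation
property tested on hundreds of random grids.

## Structure (structure)

Diploid calls are encoded as major-allele counts {0,1,2} per locus (the
"collapse non-major alleles" convention; the exact numeric coding of the
reference implementation is undocumented, so this biallelic dosage coding
is pinned here). Missing cells are filled by copying from the nearest
sample under the unweighted Manhattan distance over jointly observed loci,
normalized by their number — donor copy, not mean fill, following the
distance-based description of the reference tool; ties break by sample
order and donor-less cells fall back to the locus mode (both logged).
Samples above 50% missingness are removed first.

PCA is the covariance method: column-center, no variance scaling, SVD;
variance proportions sum to one; each loading vector is oriented so its
largest-magnitude element is positive, making scores reproducible up to
nothing. Separation between two populations is assessed by a permutation
test on the difference of mean PC1 scores (999 label shuffles, p includes
the observed labelling).

On synthetic populations with 5% of loci shifted by 0.2 (72 samples,
2,000 loci), PC1 separates the populations at p < 0.01 while explaining
only ~2% of the variance — differentiation driven by a small slice of an
otherwise unstructured genome, the same regime reported for real
recurrent-selection material; with no shift the test is non-significant in
>= 95% of seeded runs.

## Synteny (synteny)

Hits above the E-value cutoff (default 1e-8) are ignored; scores are
compared as bit scores (E-value is only the cutoff). Per allele the top
score is retained and a tie for the top discards the locus (applied per
allele: a tie on either allele discards). "The two alleles mapping at
different positions" is operationalized as different chromosome OR
non-overlapping subject intervals, with a slack parameter defaulting to 0
(the strictest defensible reading); a locus with hits for only one allele
is assigned that allele's position. Loci located through a unique best
among several hits are tabulated separately ("multi") from clean
single-hit loci, matching the usual reporting split. One caveat: relaxing
the cutoff can in principle flip a located locus to discarded by letting a
tying hit through, so only the unlocated count is monotone in the cutoff.

## Problem sizes and what the tests show

The acceptance-scale runs use 96 samples x 2,000 loci at mean depth 15
(about 2.8M reads, ~13 s) for discovery, 14 loci x 8 samples for
validation grids, and 72 samples x 2,000 loci for PCA — sizes chosen to
exercise every rule at full fidelity while staying desk-scale. Passing
tests demonstrate the *rules* are implemented exactly and behave as
analyzed under the generator's assumptions (independent loci, polysomic
inheritance, log-normal-Poisson depth, substitution/homopolymer errors).
They do not certify performance on real data with linkage, PCR duplicates,
organellar contamination, GC bias or paralog families larger than the
simulated ones; the generator deliberately omits those (see Non-goals in
the module docstrings).

## Known limitations

- The reciprocal-exclusivity rule is the documented core of network-based
  tag-pair callers; historical implementations vary in their exact
  network-topology filters across versions, so counts on real data may
  differ at the margins.
- The amplicon aligner is exact-seed + ungapped extension; it is not a
  general-purpose aligner and will classify heavily indel-ridden reads as
  unalignable or error rather than recovering them.
- Multi-SNP tags (more than one mismatch between alleles) are out of scope
  by design, as is running BLAST or any reference alignment.
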