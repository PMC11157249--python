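# Methods

`hbbnipt` infers fetal genotypes at beta-globin (*HBB*) mutation sites from
maternal-plasma cell-free DNA sequencing.  Plasma cfDNA is a mixture: a
fraction *f* (the fetal fraction, FF) of molecules is of fetal origin, the
rest maternal.  The package implements four connected procedures — fetal
fraction estimation, in-silico size selection, allele-ratio genotype
calling, and haplotype transmission inference — plus a synthetic-data
generator that makes every stage testable against planted truth.

## Fragment model and deduplication

The unit of analysis is a *fragment observation*: one sequenced cfDNA
molecule covering one panel site, with an allele, a fragment length in bp,
and a unique molecular identifier (UMI).  Coordinates are 1-based GRCh37/
hg19.  PCR duplicates are collapsed by grouping observations on
(UMI, site, alignment start when known); the consensus allele is the
per-group majority (ties break lexicographically, base qualities not being
carried through the fragment table) and the consensus length is the
longest in the group.  Groups of size one pass through, so no probed
region is lost.  Deduplication is idempotent.  Dedup runs before size
selection, matching the upstream processing order
(alignment → duplicate removal → size selection).

SAM/BAM input is read through pysam; fragment length is |template length|
for paired records and the aligned read length for merged single-end
records.  The 619 bp *HBB* intron 2 – exon 3 deletion
(chr11:5246486–5247107) is handled as a region: an alignment with a ≥50 bp
deletion operation overlapping the region supports the deleted chromosome
(`SPANNING_DEL`), an alignment crossing or inside the intact region
supports the reference chromosome (`SPANNING_REF`), all other fragments
are uninformative for the deletion.

## Fetal fraction

An *informative SNP* is a genomic panel site where the mother is
homozygous but the plasma carries a second allele — necessarily paternally
transmitted and fetal.  Because the fetus also inherits one maternal-type
allele, the obligate-fetal allele tags only half of the fetal molecules:

    FF = 2 × mean over informative SNPs of (fetal-allele reads / depth).

A candidate non-maternal allele is accepted when its read proportion lies
in [0.5%, 25%]: below the floor it is indistinguishable from sequencing
error, above the cap it more plausibly reflects a maternal genotyping
error (a true fetal allele cannot much exceed FF/2).  Sites with two or
more non-maternal alleles above the floor are discarded as error-prone.
When paternal genotypes are available, a fetal allele the father does not
carry flags the site (possible non-paternity or genotyping error) and
excludes it from the average.  The unweighted mean is the primary
estimator; a depth-weighted (read-pooling) variant is available behind a
flag.

## In-silico size selection (ISS)

Fetal cfDNA fragments are modally shorter than maternal ones, so
discarding fragments above a length cutoff enriches the fetal fraction at
the cost of depth.  `iss_scan` re-applies the whole FF pipeline (filter →
recount → re-detect informative SNPs → re-estimate) over a descending
cutoff grid, by default 167 bp down to 100 bp in 1 bp steps; the boundary
is inclusive (keep length ≤ L).  `select_cutoff` picks the FF-maximising
cutoff among points that retain at least 20% of the unfiltered informative
reads (ties go to the larger, gentler cutoff).  The retention floor is a
design choice: the gain in FF must be balanced against the statistical
noise that read loss introduces, and no universal constant exists; 20% is
configurable and deliberately conservative.

## Ratio-based genotype calling

At a site where the mother carries dosage d_m ∈ {0,1,2} of a counted
allele and the fetus dosage d_f, the expected plasma proportion of that
allele is

    p(d_f) = (1 − f)·d_m/2 + f·d_f/2.

For a homozygous mother and a heterozygous fetus this reduces to the
familiar "maternal allele at 100% − FF/2".  Candidate fetal genotypes are
restricted to Mendelian transmissions from the parental genotypes (de novo
events are out of scope), each scored with a binomial log-likelihood
Bin(k; n, p(d_f)) where n is the depth over the site's parental alleles
(error alleles are kept in the table for noise estimation but do not
dilute the ratio).  Expected proportions are clamped to [1e-3, 1−1e-3] so
that homozygous-reference hypotheses at indel sites retain a sequencing
noise floor instead of an impossible p = 0.

The maximum-likelihood genotype is called; when the log-likelihood ratio
to the runner-up falls below τ = 2 natural-log units the call is reported
as an explicit two-genotype ambiguity ("G/T or T/T").  The threshold is a
design decision (roughly a 7:1 likelihood ratio), configurable, and
deliberately labelled a confidence *flag* rather than a calibrated
posterior probability — no probability metric over calls is claimed.
Likelihood ranking coincides with nearest-expected-ratio classification at
fixed depth; the nearest-ratio rule is available via
`selection="nearest"`.  When a size-selection cutoff is in force, expected
proportions use the post-ISS fetal fraction, since enrichment changes both
the observed and the expected ratios.  Calling refuses f = 0 (hypotheses
coincide at maternal-het sites) and depths below 50 post-dedup reads.

The 619 bp deletion is genotyped with the same machinery as a biallelic
DEL619/REF site using the spanning-fragment counts.

## Haplotype phasing and transmission inference

Long reads over a 2.2 kb amplicon (chr11:5246155–5248406) span several
heterozygous sites per read.  Heterozygous candidates are called where the
minor-allele read frequency exceeds 16% (30% for indel tokens, reflecting
the higher indel error of long-read platforms), requiring ≥100 reads.
Phasing is a greedy two-cluster partition: seed haplotypes from the two
most frequent complementary patterns at the highest-coverage pair of
called sites, assign each read to the consensus it agrees with best
(matches minus mismatches; ties unassigned), recompute per-cluster
majorities, and iterate to a fixed point.  Reads spanning the 619 bp
deletion junction carry DEL619 as an allele at a pseudo-site, so the
deletion phases with its linked SNPs.  This replaces the commercial
long-read phasing step with a transparent reconstruction; any consistent
two-haplotype solution suffices for the downstream inference.

Each of the four (maternal haplotype, paternal haplotype) transmission
combinations implies one fetal genotype at every phased site and hence an
expected plasma proportion; the combination score is the sum of per-site
binomial log-likelihoods.  This joint statistic is the package's design
choice for aggregating linked-SNP evidence (a per-site thresholding
scheme would discard the accumulation across sites that motivates
haplotyping in the first place).  The top combination is selected; log-LR
below the shared τ marks the transmission ambiguous, and if all four
combinations imply identical genotypes at every covered site the result
is *uninformative*.  As f → 0 the four log-likelihoods converge, so
transmission inference degrades gracefully at low fetal fraction.
Paternal-only informative sites participate in the joint likelihood: the
obligate-fetal reads there discriminate the paternal haplotypes strongly.

The combined call applies a fixed precedence: an informative, unambiguous
transmission result overrides the single-site ratio call; otherwise the
ratio call stands, annotated with the haplotype status.

## Case bundles and fixtures

Two reference fixtures ship in-package as JSON: seven families with
single-site plasma ratio evidence, recorded fetal fractions before/after
size selection, haplotype-based predictions, and CVS-confirmed fetal
genotypes; and one five-site family (IBT 42) with full parental haplotype
vectors, where the mutation-site region call is resolved by linked SNPs.
Printed integer ratio strings are stored verbatim and normalised to
proportions at load (ratios summing to 99 or 101 reflect rounding).
Because read depths at individual sites are not part of the recorded
evidence, the fixtures assign nominal post-dedup depths (2000 reads per
site for the seven families, 800 for the five-site family) consistent
with probe-capture short-read sequencing after deduplication; likelihood
ratios, and hence ambiguity flags, scale with this choice, which is fixed
once in the fixture files.  Parental genotypes not recorded in the
sources are reconstructed to be consistent with the documented calls and
are flagged `parental_gt_reconstructed`.  SNP1–SNP4 coordinates in the
IBT-42 fixture are synthetic placeholders within the amplicon.

## Synthetic-data generator

`simulate_plasma` emulates the study conditions: per site, molecules are
fetal with probability `ff_true`; each molecule carries one of its origin
genotype's alleles with probability 1/2; fragment lengths are normal with
origin-specific modes 143 bp (fetal) and 166 bp (maternal), sd 15 bp —
consistent with reported plasma cfDNA sizes and the fetal-shorter premise;
exact distributions are not published, so these are configurable,
including an equal-distributions null mode.  Sequencing error flips a
read's allele to a random other base at rate 0.002 per read; PCR
duplication re-reads a molecule Poisson-many times under one UMI.  UMIs
are idealised unique tags (collisions are a platform artifact the
generator does not model).  Defaults are 50 genomic SNPs at 2000 molecules
per site.  `simulate_amplicon_reads` draws long reads from two haplotype
vectors with per-site error, optionally placing the 619 bp deletion on one
haplotype (its reads become junction-spanning and lose sites inside the
deleted interval).

What the generator does *not* emulate — GC-dependent coverage, strand
bias, mappability, maternal mosaicism, realistic indel error profiles,
base qualities, UMI collisions — bounds what passing tests show: they
validate the estimators' statistical behaviour under the stated mixture
model, not robustness to every artifact of real libraries.

## Numerical and scale choices

Simulation-based checks use problem sizes chosen to make sampling noise
negligible relative to the tolerances tested: FF recovery uses 50
informative SNPs × 2000 molecules × 20 seeds per fetal fraction;
enrichment checks 20 seeds (with a 50-seed null); phasing and transmission
recovery use 100 seeds each; caller/oracle agreement uses 1000 random
instances against an independent lgamma-based enumeration.  The f → 0
convergence of transmission likelihoods is evaluated on fixed balanced
counts, since it is a property of the likelihood function at given data
rather than of any particular random draw.  Degenerate inputs are
explicit errors or no-calls: empty fragment tables dedup to empty tables,
scan points with no surviving informative SNP are flagged invalid rather
than aborting the scan, zero deletion-spanning fragments yield a no-call,
and FF estimates above 1 are clipped with a warning.

## Known limitations

Single-fetus pregnancies only; no copy-number or maternal-mosaicism
modelling; no calibrated posterior probability on calls (the τ flag is a
likelihood-ratio heuristic); the greedy phaser assumes exactly two
haplotypes and will not detect template-switching chimeras; SAM ingestion
assumes upstream trimming/merging/alignment was done by standard tools.
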