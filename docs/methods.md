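# Methods

## The comparison problem

A matched pair consists of two sequencing libraries from the same
tissue, one fresh-frozen (FF) and one formalin-fixed paraffin-embedded
(FFPE). The two observations share all biological truth — reference
sequence, germline and somatic variants, copy-number segments — and
differ only in preservation chemistry: formalin deaminates cytosine,
which reads report as C>T (or G>A on the complementary strand)
substitutions concentrated at CpG dinucleotides, and FFPE libraries may
carry lower, more dispersed coverage and lower mapping quality. The
package measures how far those artifacts propagate into base calls,
variant calls, somatic calls, and copy-number profiles, using the FF
member as the reference sample throughout.

## Observation model (synthetic data)

The generator works at pileup resolution; it never emits reads or
alignments (read-level FASTQ/BAM and library fragmentation are out of
scope by design).

**Reference.** Bases are drawn to a target GC fraction (default 0.41,
human-like). CpG density is a first-class parameter because both
endogenous C>T mutation and deamination artifacts concentrate there:
for `cpg_enrichment > 1` the sequence is built from single-base units
interleaved with planted "CG" units, with the single-base pool adjusted
so the expected composition stays exactly at the target GC; for
enrichment < 1 a matching fraction of chance CG occurrences is broken
by composition-preserving swaps. CG dinucleotide frequency therefore
scales monotonically with the parameter (it is not an exact
observed/expected ratio; nothing downstream assumes one — all context
denominators are computed from the realized sequence). The default is
1.0; analyses that emulate CpG-rich targeted territory set 3–4.

**Truth.** Germline heterozygous SNVs at rate 1e-3/bp; somatic SNVs
(tumor-only) at 1e-5/bp with truth VAF drawn from a Beta distribution
with mean `tumor_vaf_mean` (default 0.4 — tumor purity is absorbed
here; no subclonal structure); INDELs at 1e-4/bp, insertion/deletion
50:50 with geometric sizes of mean 6 bp and 9 bp respectively. Variant
classes occupy disjoint positions. Coordinates are 1-based inclusive
everywhere; BED files are converted at the I/O boundary only.

**Pileups.** Depth is negative-binomial with variance
`m + d·m²` (Poisson as the dispersion d → 0; the degree of FFPE
over-dispersion is a free parameter, default 0.1, since no empirical
value is established). Default depth means are 79× (FF) and 61× (FFPE),
the typical exome-pair asymmetry. Each read base equals the truth
allele (het 0.5; somatic truth VAF in tumor kinds), is flipped to a
uniform other base with probability `seq_error_rate` (default 5e-4),
and then — FFPE kinds only — reads showing C at a reference C are
flipped to T with probability `deamination_rate_cpg` (default 0.01)
when the 3′ neighbour is G, else `deamination_rate_noncpg` (default
1e-3); reference-G sites are handled identically on the complementary
strand. Deamination is per read, strand-collapsed, because all
downstream analyses use collapsed C·G>T·A classes. Tumor depth scales
with copy_state/2 of the covering CNV segment. MAPQ is a per-position
scalar (the filters act per position) drawn from a normal censored to
[0, 60]. INDEL support is binomial at the event's truth VAF,
independent of deamination (formalin damage to INDEL detection is not
separately modeled).

**Low-pass counts.** Expected bin count is
`lowpass_mean_coverage · width / read_length`, scaled by copy_state/2
in tumor kinds and by a linear GC-bias factor `1 + s·(gc − 0.5)`
floored at 0.05 (default s = 0.3); counts are negative-binomial.
Defaults: 0.2× coverage, 100-bp reads, 15-kb bins.

**Array genotypes.** Emitted at germline sites; each genotype class is
corrupted to a uniform wrong class with a given error probability —
an idealization of an orthogonal genotyping platform.

**Determinism.** All randomness flows from one seed through named
substreams keyed by (module, sample kind), so identical configurations
are byte-identical and adding a stage never perturbs another stage's
draws.

### What the generator does *not* emulate

Alignment and mappability structure, PCR duplicates, strand-specific
damage (it is collapsed), DNA fragmentation, subclonality, and
inter-operator fixation variability. Consequently, passing tests show
that the *analysis* behaves correctly under the stated stochastic
model; they do not certify performance on real alignments, where
mapping artifacts add discordance mechanisms this model lacks.

## Calling and classification

Callable: depth ≥ `min_coverage` (13; 20 in targeted/TES mode) and
per-position MAPQ ≥ 43. Consensus is the majority base with an exact
tie yielding NO_CALL — a deterministic stand-in for pileup-consensus
behaviour that is not otherwise pinned down. SNVs: the single best
non-reference allele, called when VAF > 0.2 strictly; het below 0.8,
hom_alt at or above (the 0.8 boundary is this package's choice).
INDELs reuse the same thresholds on insertion/deletion support; the
higher-supported event wins and an exact ins/del tie is NO_CALL.

Variant-level pair classification compares alternate alleles, not
genotype classes (genotype agreement is reported separately in the
array comparison). The intersect denominator is the pair's shared
callable territory, optionally restricted to target regions; both
views are exposed because published concordance rates are quoted
against more than one denominator.

### Heterozygous sites and base-level concordance

At a heterozygous site the two alleles are equally supported, so the
majority base of each sample is close to a coin flip and a matched pair
disagrees at roughly half of its het sites even with zero error and
zero artifact. This is a property of majority-vote consensus, not of
preservation chemistry. Two consequences are documented deliberately:

* *Zero-artifact fidelity* is demonstrated in two parts: base-level
  concordance is exactly 1.0 on a variant-free genome, and
  variant-level concordance is exactly 1.0 (FP = FN = 0) on a genome
  with variants, both with error and deamination rates at zero.
* *Artifact localization* (the C·G>T·A excess on the FFPE side of
  discordant positions) is computed over base-level discordant
  positions. Under the strict VAF > 0.2 calling rule, a realistic
  deamination rate (≈2% of reads) can essentially never change which
  alternate allele wins at a variant site, so allele-discordant variant
  calls carry no artifact signal in this model; at C/T-heterozygous CpG
  sites, however, deamination tips the FFPE majority toward T, which is
  exactly the directional excess measured. `discordant_ct_rate`
  accepts the per-position detail of either classification level.

Similarly, the coverage analysis behind the 13× filter compares
*disagreeing* positions (discordant + false positive + false negative)
against concordant ones: under threshold calling, disagreements arise
from VAF sampling noise and filter crossings, which concentrate at low
depth.

## Artifact spectrum

Substitutions are collapsed onto the reference pyrimidine strand
(G sites complemented), giving six classes; transitions are C>T and
T>C. The global mismatch rate is (non-reference read bases)/(read
bases) over filter-passing positions *excluding called variants*, so
true polymorphism does not inflate it — the denominator convention is
configurable since published definitions vary. Context rates classify
every internal reference C (and complemented G) by 3′ neighbour
(CpA/CpC/CpG/CpT) and 5′ neighbour (ApC/CpC/GpC/TpC) and are available
at call level (sites with a C·G>T·A call / eligible sites) and read
level (mutant reads / read bases); both are provided because published
per-sample rates do not fix one denominator.

Paired t tests follow the convention t = mean(FFPE − FF)/(sd/√n) with
df = n − 1; an all-zero difference vector reports t = 0, p = 1, and a
constant non-zero difference (zero variance) is an error. Dunnett
many-to-one comparisons are adjusted by seeded Monte Carlo of the null
max-|t| distribution (default 1e5 draws, accurate to ~0.003 in p and
cross-checked against the closed-form implementation in scipy); the
one-way ANOVA F and p come from scipy.

## Copy number

GC correction divides each bin count by the median of its GC-decile
stratum and rescales to the original overall median; zero-median strata
are flagged and left uncorrected. This decile-median scheme is
deterministic and adequate at the bin counts involved (a loess fit
would add smoothness but no testable behaviour). Log2 ratios are taken
to the sample median with zero-count bins masked.

Segmentation is penalized recursive binary segmentation: a split is
accepted while it reduces the within-segment SSE by more than
`penalty · log(n)` (n = bins on the chromosome; default penalty 2.0, a
BIC-like scale). It is deterministic and, on copy-number-like signals,
matches an exhaustive dynamic-programming optimum (tested on all
fixture signals of ≤ 12 bins); exact boundary parity with any
particular published segmenter is a non-goal — agreement is asserted as
injected-truth recovery. Masked bins inherit the covering segment.
Segment calls: loss at mean log2 ≤ −0.15, gain at ≥ +0.15 (inclusive
boundaries; thresholds configurable, no published value exists).

Region harmonization imposes the union of all samples' breakpoints and
averages each sample's log2 ratios per region. Clustering is
agglomerative with Euclidean distance and average linkage; sample
similarity is the Pearson correlation of region profiles, with
zero-variance profiles reported missing. Distance and linkage are this
package's choices. Region-size distributions are reported but no
acceptance bound is placed on size parity between pair members, which
is known to vary.

## Somatic accounting

Subtraction is allele-aware: a tumor call survives unless the matched
normal carries the *same* alternate allele at the same position; a
different allele at the same position is retained. Idempotence follows
by construction. Recurrence filtering drops synonymous variants,
variants carried by any supplied normal set, and variants with
population frequency strictly above 10% (exactly 10% is kept); variants
lacking an annotation row are dropped with a logged count — functional
annotation is an input table, never computed. Published per-sample
"somatic" totals involve additional unstated criteria and are not
reproduced; the package reports its own documented definition.

## Problem sizes used in the checks

The self-checks simulate at sizes chosen to make each effect
statistically decisive at desk scale: 1 Mb pairs for fidelity (with
clonal somatic truth VAF 0.5, so the strict VAF filter is not itself a
disagreement mechanism in the zero-artifact setting — threshold
crossings are the filter sweep's subject); 0.4 Mb
of CpG-rich sequence at 50× (≥10⁶ CpG read observations) for
deamination-rate recovery; 16 Mb at 150× for artifact localization
(≥5000 base-level discordant positions, two-proportion z ≈ 5); 1 Mb at
30× negative-binomial coverage for the coverage–disagreement
comparison; 7 pairs × 2000 bins × 100 seeded cohorts for copy-number
pairing. The copy-number pairing check operates on log2-ratio profiles
with Gaussian bin noise (SD 0.2) injected directly, which isolates the
segmentation–harmonization–clustering path from count-level noise
already covered elsewhere.

## Known limitations

* Pileup-level simulation cannot reproduce alignment-driven
  discordance (mapping ambiguity, indel realignment), which dominates
  real discordant calls at well-covered positions.
* The INDEL observation channel carries its event sequence in a truth
  side-channel of the pileup dialect; INDEL discovery from read
  evidence is not modeled.
* MAPQ censoring at [0, 60] places point mass at the bounds rather
  than renormalizing the density; only threshold comparisons consume
  MAPQ, so this is immaterial downstream.
* Dunnett adjustment is Monte-Carlo, so adjusted p-values carry
  ~1/√draws noise; raise `n_draws` where that matters.
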