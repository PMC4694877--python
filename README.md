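# ffpe-concord

Toolkit for asking a practical question in cancer genomics: **can
formalin-fixed, paraffin-embedded (FFPE) tissue — the standard archival
material of pathology — substitute for fresh-frozen (FF) tissue in
sequencing studies?** Formalin fixation deaminates cytosines, which
sequencing reads report as artifactual C>T (or G>A on the opposite
strand) substitutions, concentrated at CpG dinucleotides. `ffpe-concord`
implements the complete matched-pair comparison used to answer that
question, together with a synthetic-data generator that emulates matched
FF/FFPE samples so every stage is testable without any sequencing data.

## What it computes

For a matched FF/FFPE pair observed as per-position pileups:

* **Hard-filtered calling.** A position is callable when depth ≥ 13 and
  per-position mapping quality ≥ 43 (20× depth for targeted panels).
  The consensus base is the majority base (tie → no call); an SNV is
  called when the best non-reference allele fraction is strictly > 0.2,
  heterozygous below a VAF of 0.8 and homozygous at or above it.
* **Concordance classification.** Base level: positions called in both
  samples are *concordant* (same base) or *discordant*. Variant level:
  additionally *false positive* (FFPE-only call) and *false negative*
  (FF-only call), with FF as the reference sample. An orthogonal
  array-style genotype table can be compared the same way.
* **Artifact spectrum.** Substitutions collapsed onto the pyrimidine
  strand into six classes (C·G>T·A, …), the C·G>T·A share over all and
  over discordant positions, the global read-level mismatch rate,
  Ts/Tv, and C>T rates stratified by 3′ (CpN) and 5′ (NpC) neighbour.
  Paired t tests, one-way ANOVA, and Dunnett many-to-one comparisons
  (seeded Monte-Carlo adjustment) quantify FF-vs-FFPE differences.
* **Filter sweeps.** Concordance/FP/FN recomputed along coverage, MAPQ
  and VAF threshold grids, and the coverage comparison between
  agreeing and disagreeing positions that motivates the 13× filter.
* **Somatic accounting.** Allele-aware germline subtraction
  (tumor − matched normal), FF/FFPE somatic overlap counts, and
  cross-sample recurrence filtering (non-synonymous, absent from
  normals, population frequency ≤ 10%).
* **Low-pass copy number.** 15-kb binned read counts → GC correction by
  decile medians → log2 ratios → penalized binary segmentation →
  loss/neutral/gain calls → union-of-breakpoints region matrix →
  average-linkage clustering and Pearson correlation across samples.

The simulator draws negative-binomial coverage, per-read sequencing
error, and — only for the FFPE member — per-read C→T deamination at a
CpG-specific rate, plus shared germline/somatic/INDEL/copy-number truth,
low-pass binned counts with GC bias, and array genotypes. A single seed
fans out into named substreams, so identical configurations are
byte-identical.

## Worked example

```python
from ffpe_concord import SimulationConfig, FilterConfig, simulate_pair
from ffpe_concord.calling import call_snv_table, consensus_base_calls
from ffpe_concord.concordance import classify_base_calls, classify_variants

cfg = SimulationConfig(genome_length=1_000_000, seed=3,
                       cpg_enrichment=4.0, deamination_rate_cpg=0.02,
                       mean_coverage_ff=100, mean_coverage_ffpe=100,
                       coverage_dispersion=0.0, mapq_sd=3.0)
truth, ff, ffpe = simulate_pair(cfg)
filt = FilterConfig()                     # 13x / MAPQ 43 / VAF > 0.2

base = classify_base_calls(consensus_base_calls(ff, filt),
                           consensus_base_calls(ffpe, filt))
snv = classify_variants(call_snv_table(ff, filt),
                        call_snv_table(ffpe, filt))
print(f"base concordance  {base.concordance_rate:.5f} "
      f"({base.n_discordant} discordant of {base.n_intersect})")
print(f"SNV concordance   {snv.concordance_rate:.5f} "
      f"(FP={snv.n_false_positive}, FN={snv.n_false_negative})")
```

prints

```
base concordance  0.99954 (455 discordant of 990072)
SNV concordance   1.00000 (FP=0, FN=10)
```

With a 2% CpG deamination rate the pair is still >99.9% concordant at
the base level; the 455 discordant positions are dominated by
heterozygous sites where majority voting flips between the two equally
supported alleles, and their FFPE-side calls are enriched for C·G>T·A
(8.1% vs 5.3% on the FF side in this run,
`artifact_spectrum.discordant_ct_rate`) — the deamination fingerprint
the spectrum module quantifies. The ten false negatives are FFPE
positions whose mapping quality fell below the 43 threshold.

The same pipeline runs from the shell:

```bash
ffpe-concord simulate --config sim.cfg --outdir out/
ffpe-concord concord --ff out/pileup_ff_normal.tsv \
    --ffpe out/pileup_ffpe_normal.tsv --level variant --out conc.tsv
ffpe-concord cnv --counts out/lowpass_ff_tumor.tsv \
    --counts out/lowpass_ffpe_tumor.tsv --outdir cnv/
```

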