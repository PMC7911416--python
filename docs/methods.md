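# Methods

## Scope and model

`bincnv` infers copy number from read *depth* alone: uniquely mapped,
non-duplicate reads are counted in fixed 20-kb bins, and the per-bin count
is modeled as

    count_i ~ Poisson( d · cn_i / 2 · b(gc_i) )

where `d` is the mean depth per bin at disomy, `cn_i` the local copy
number and `b` a GC-bias multiplier. Inside a CNV present in a fraction
`f` of cells with `c` copies, `cn = 2(1−f) + c·f`; maternal-cell
contamination at fraction `m` mixes the maternal genome in the same way.
There is no allele-frequency (SNP) information at this depth, so mosaicism
and contamination are seen only through intermediate CN levels.

## Pipeline stages and the parameters that matter

**Trimming and QC.** Raw reads are 45 bp: a 36-bp genomic insert followed
by a 9-bp adapter. Trimming cuts at the first exact match of the
adapter's 7-bp seed; no mismatch tolerance (low-pass QC does not need
error-tolerant trimming). The QC panel: unique-mapping ratio
(unique/raw), redundancy (duplicates among *uniquely mapped* reads, by
flag or repeated (chrom, 5′ position, strand); the denominator choice is
echoed in the report header because conventions differ), CV of unmasked
bin counts using the population SD (bins number in the thousands, but the
estimator must be fixed for exact tests), median read depth per bin, GC
ratio over A/C/G/T only, and Q30 (fraction of bases with Phred ≥ 30).

**Binning.** Internally all coordinates are 0-based half-open; reports and
truth files are 1-based inclusive, converted only at I/O boundaries. Each
chromosome is tiled with `floor(L / 20000)` full bins; the trailing
partial bin is dropped rather than truncated, since variable-width bins
would bias both CV and CN. A read is assigned by its 5′-most coordinate
(reads are 36 bp against 20-kb bins, so the choice is immaterial but must
be fixed). Bins overlapping excluded regions or centromeres, and bins
with GC outside [0.28, 0.60], are masked and excluded from all statistics
(but still drawn in plots).

**GC correction.** Stratified-median: strata of width 0.01 in GC, factor =
stratum median / global median over unmasked bins; strata with fewer than
10 bins borrow the nearest populated stratum's factor. Width and minimum
were chosen to be coarse enough for toy genomes and fine enough for a
full-genome grid. With a single stratum the correction is the identity.

**Normalization.** `CN_i = 2 c_i / m` with `m` the median corrected count
over unmasked **autosomal** bins (sex chromosomes excluded so male samples
do not depress the baseline). A one-pass re-estimation recomputes `m`
over bins whose provisional CN lies in (1.8, 2.2), which keeps the
baseline honest in the presence of aneuploidies or large CNVs. This
within-sample baseline replaces a reference panel; with ~20+ autosomes a
whole-chromosome trisomy shifts `m` by well under 2% after re-estimation.
On genomes with very few autosomes the aberrant fraction of bins can
approach the median's breakdown point — the synthetic genomes used here
are sized so aberrant material stays a clear minority. CN is exactly
invariant to scaling all counts by a constant.

**Sex chromosomes.** Sex is inferred before any X/Y call by matching
(chrX CN, chrY CN) against XX/XY/XO/XXY/XXX/XYY patterns within ±0.3
(chrY below 0.2 reads as absent); no match flags the sample
"sex undetermined". For segmentation, sex-chromosome CN is rescaled so
the sex-expected copy number maps to 2 (and an expected-absent chrY is
skipped), so a male X is not reported as a giant deletion.

**Smoothing and segmentation.** Detection runs on a per-chromosome
running median over consecutive unmasked bins (window 5, centered,
truncated at ends; window 1 is the identity). Segments are maximal runs
of unmasked bins on the same side of the open disomy band (≤ 1.8 or
≥ 2.2); runs separated by at most 2 masked or in-band bins are merged,
and runs with fewer than 5 member bins are discarded — 5 bins of 20 kb
matches the ~0.1 Mb resolution this class of assay claims. Quantification
is decoupled from detection: the reported mean CN comes from the
*unsmoothed* profile over the merged span.

Two additions where the segmentation design was genuinely open:

* *Edge refinement.* The smoothing window bleeds CNV signal into
  flanking bins, extending run ends by several bins. Each end is
  trimmed with a CUSUM-style rule on raw CN: per-bin evidence
  `|cn − 2| − |cn − level|` (`level` = run median) is accumulated from
  the edge up to the first decisively segment-like bin (evidence
  > 0.5), cutting at the most negative cumulative sum if the deficit
  exceeds one disomic bin's worth (1.0). On seeded 1-Mb CNVs at 30
  reads/bin this brings ~96% of replicates within ±3 bins of the true
  boundaries without clipping genuine edges.
* *Significance gate.* At 30 reads/bin the per-bin CN noise SD is
  ≈ 0.37, and the bare run rule emits dozens of short spurious "mosaic"
  excursions per genome. A segment is kept only when
  `|mean − 2| ≥ 4 · σ/√n`, with σ estimated robustly from successive
  differences of the profile (insensitive to the piecewise-constant
  signal; exactly 0 for noiseless input, so constructed tests are
  unaffected). This leaves ~1–2 short low-grade mosaic calls per
  simulated euploid sample; set `seg_min_z = 0` to disable.

**Classification.** Duplication CN > 2.8, deletion CN < 1.2, disomy
1.8 < CN < 2.2, mosaic trisomy 2.2 < CN < 2.8, mosaic monosomy
1.2 < CN < 1.8. The defining inequalities are strict on both sides, so a
value exactly at 1.2/1.8/2.2/2.8 is undefined by them; such values are
assigned to the adjacent mosaic band and flagged "boundary". Mosaic
fraction is the inversion `f = CN − 2` (gain side) or `f = 2 − CN`
(loss side), clipped to [0, 1], reported only for mosaic states.

**Whole-chromosome calls and karyotype strings.** An autosome with more
than 90% of its unmasked bins outside the disomy band on one side is a
whole-chromosome gain/loss; same-side segments on that chromosome are
absorbed into the whole-chromosome call (the masked centromere would
otherwise split it in two). Karyotype strings use the clinical dialect
(`46,XN`, `47XN,+21`, `45,XO`, `47,XXY`); the chromosome count is the
implied *human* complement (44 autosomes + sex chromosomes) even on toy
genomes, so result strings remain comparable with clinical reports.
Fetal sex is masked as "XN" for normal XX/XY unless configured otherwise.

**CNV naming.** `<chrom><startBand>-<endBand>(<del|dup>, <size> Mb)` from
the cytoband containing each endpoint, the band printed once for
single-band segments, size in Mb to 2 decimals; without cytoband coverage
the name falls back to `chrom:start-end(...)`. Mosaic states print their
side (del/dup).

**Concordance.** Per truth interval:
`100 × |union of same-side call overlaps| / |truth length|`, plus the
reciprocal overlap (`100 × |∩| / |∪|`) of the single best-overlapping
call. The truth interval is the denominator because the benchmark is
"how much of the microarray-defined CNV did sequencing recover"; the exact
formula used in published comparisons is typically pictorial, so the
reciprocal overlap is reported alongside. CN agreement is the integer
match of the call's rounded mean CN with the expected copies.

**MCC gate.** Per informative STR locus (a maternal allele absent from
the fetal genotype), contamination = `2 · h_specific / Σ h`; the factor 2
converts one allele's dosage into a genome fraction. MCC percent is 100 ×
the median over informative loci; the sample passes iff strictly < 5%.
With no informative locus the result is flagged uninformative (gate
decision configurable, default pass-with-warning). When fetal genotypes
are not supplied they are inferred as the two tallest peaks per locus.

## The simulator: what it emulates and what it does not

Count tier draws independent Poisson counts at the expected CN per bin
(fractional at CNV edge bins, by overlap); read tier adds 45-bp reads
(36-bp insert + 9-bp adapter `AGATCGGAA`, configurable), two-state
per-base qualities (94% high state Q37, else Q17, making Q30 ≈ 0.94
non-trivial), mapping status (unique with probability 0.62, matching the
stable 60–65% unique-mapping regime of PCR-free libraries; the remainder
split multi/unmapped), and duplicates that re-emit an earlier read's
mapping. GC bias is a quadratic multiplier normalized to 1 at GC 0.40
with coefficients defaulting to 0 (off) — real GC effects are shown
qualitatively by instruments, not by a published model. MCC mixing uses
binomial thinning, matching the mixture in expectation (variance slightly
sub-Poisson). Defaults are the stated assay regime: 5 million raw reads,
30 reads/bin at count tier.

Not emulated: sequencing errors in the insert, library chemistry and
yield, real hg19 sequence or mappability, correlated (wavy) coverage
noise, and reference-panel normalization. A green simulation test
therefore establishes correctness of the *computational* contracts under
the Poisson read-sampling model, not performance on real flow-cell data.

The default toy genome is ~188 Mb over 8 chromosomes (chr1..chr5, chr21,
chrX, chrY; 9,400 bins), sized so the largest benchmark CNV (31.8 Mb)
fits inside one q arm while staying a minority of autosomal bins; each
chromosome carries a centromere, one excluded region and a 6-band
cytoband table.

## Numerical choices and degenerate inputs

Population SD everywhere a CV is computed; medians for all baselines;
ties in nearest-stratum borrowing resolve to the numerically nearest key.
Zero-coverage scopes, empty alignment tables, genomes with fewer than 50
(GC correction) or 100 (normalization) unmasked autosomal bins, negative
CN and malformed quality strings raise or reject explicitly rather than
propagating NaN. Count-tier simulation, grid construction and the whole
calls pipeline are bit-deterministic for a fixed seed and configuration;
output files embed the tool version and a hash of the configuration.

## Known limitations

* Independent-Poisson noise is optimistic; real low-pass data have
  correlated biases, so the ~1 low-grade mosaic false call per sample
  seen at 30 reads/bin is a lower bound on the real FP rate.
* The within-sample median baseline assumes most autosomal material is
  disomic; near-triploid genomes would normalize incorrectly.
* Segmental CNVs on an aneuploid chromosome with the same sign as the
  aneuploidy are absorbed into the whole-chromosome call.
* Mosaic fractions below ~20% at 30 reads/bin are not separable from
  noise by the significance gate for sub-Mb segments.
* STR-based MCC estimation takes peak heights as given; capillary signal
  processing and stutter are out of scope.
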