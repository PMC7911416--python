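# bincnv

Low-pass whole-genome-sequencing copy-number analysis for prenatal
diagnostics, as a tested Python library plus a command-line tool.

## The problem

Clinically significant chromosome disorders — whole-chromosome aneuploidies
such as trisomy 21 and monosomy X, and segmental
microdeletion/microduplication syndromes — can be detected from *shallow*
single-end sequencing of amniocyte genomic DNA (a few million 36-bp reads
per sample). `bincnv` implements the full computational side of such an
assay:

1. **Sequencing QC** — adapter trimming of 45-bp raw reads to their 36-bp
   genomic inserts, plus the standard indicator panel: unique-mapping
   ratio, read redundancy, coefficient of variation (CV = SD/mean) of bin
   counts genome-wide and per chromosome, median read depth, GC ratio of
   uniquely mapped reads, and Q30.
2. **Binning** — uniquely mapped, non-duplicate reads are counted into
   fixed 20-kb bins tiled along each chromosome; bins overlapping excluded
   regions, centromeres or extreme GC are masked.
3. **Normalization** — stratified-median GC correction, then scaling so the
   autosomal median count maps to copy number CN = 2:
   `CN_i = 2 c_i / m`, with a one-pass re-estimation of the baseline `m`
   that excludes bins outside the disomy band.
4. **Calling** — running-median smoothing, run-based segmentation with
   edge refinement, and classification with the clinical thresholds
   duplication CN > 2.8, deletion CN < 1.2, disomy 1.8 < CN < 2.2,
   mosaic trisomy 2.2 < CN < 2.8, mosaic monosomy 1.2 < CN < 1.8.
   Whole-chromosome calls and the sex karyotype are folded into an
   ISCN-style result string such as `47XN,+21` or
   `5p15.33-p13.3(del, 31.90 Mb)`.
5. **Concordance** — calls are benchmarked against microarray-defined
   truth intervals (percent of the truth interval covered by same-state
   calls, plus reciprocal overlap), and samples are gated on maternal-cell
   contamination (MCC < 5% acceptable), estimated from STR peak heights.
6. **Simulation** — a two-tier synthetic-data generator (Poisson bin
   counts, or raw reads with adapter and qualities plus an alignment-truth
   table) so every stage is testable without any external data.

## Worked example

```
bincnv simulate --karyotype "47,XX,+21" --cnv "chr3:10000001-14800000:del" \
    --depth-per-bin 30 --seed 5 --tier counts --out sim/
bincnv call --counts sim/counts.tsv --genome sim/genome.json --no-plots --out out/
```

prints

```
47XN,+21	PASS
```

and `out/calls.tsv` contains

```
chrom	start1	end1	state	mean_cn	size_mb	n_bins	mosaic_fraction	boundary	name
chr2	15080001	15360000	mosaic trisomy	2.405	0.28	12	0.405	0	2q1(dup, 0.28 Mb)
chr3	10000001	14800000	deletion	0.988	4.8	237		0	3q1(del, 4.80 Mb)
```

i.e. the trisomy-21 karyotype is recovered exactly (it is reported once,
as a whole-chromosome gain, not as segments) and the simulated 4.8-Mb
deletion is called with CN ≈ 1 at its true coordinates.  The short chr2
"mosaic trisomy" is a bin-noise excursion — at 30 reads/bin roughly one
such sub-Mb low-grade call per sample survives the significance gate (see
`docs/methods.md`).  `out/karyotype.txt` lists per-chromosome and per-arm
CN values (chr21 ≈ 3.0, autosomes ≈ 2.0 here).  Scoring against the
simulation's own truth:

```
bincnv concordance --calls out/calls.tsv --truth sim/truth_cnvs.tsv --out conc.tsv
min	100.00
median	100.00
```

Exit codes: 0 success, 2 QC failure (e.g. `--mcc-percent 6` trips the
contamination gate), 3 input error.

## Acceptance benchmarks

`scripts/acceptance.py` re-runs the package's seeded validation benchmarks
from scratch and writes them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It simulates, at count tier and 30 reads/bin on the built-in toy genome:
a panel of deletions/duplications from 0.7 to 31.8 Mb (10 replicates each,
reporting the minimum percentage of the truth interval recovered), ten
monosomy-X replicates (consensus chrX integer CN) and ten trisomy-21
replicates (consensus chr21 q-arm integer CN).

See `docs/methods.md` for the model, parameter defaults and limitations.
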