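# cashcandi

Discovery of cancer-specific hypermethylated (CaSH) regions from tissue and
plasma methylation profiles, and read-level quantification of circulating
tumor DNA (the ctCandi score) in cell-free DNA sequencing data.

The package implements the full analysis chain:

1. **methylio** — readers/writers for per-CpG cytosine-report count tables,
   BED regions, and aligned reads carrying per-CpG methylation calls
   (SAM/BAM with `XM`-style call strings, or a plain-text TSV dialect).
   Internal coordinates are 1-based inclusive everywhere; BED conversion
   handles the 0-based half-open convention on disk.
2. **discovery** — per-CpG beta values, missingness filtering, two-sided
   Wilcoxon rank-sum tests (exact for small samples, tie/continuity-corrected
   normal approximation otherwise), Benjamini–Hochberg FDR, beta-threshold
   filters (Δβ > 0.3 versus normal tissue, healthy-plasma mean β < 0.05 for
   the hyper direction), merging of surviving CpGs within 75 bp flanks into
   fragments, and region finalization (≥ 10 member CpGs; region spans first
   to last member CpG). A mirrored "hypo" mode is included.
3. **ctcandi** — candidate-read calling: a read counts for a region when it
   is completely contained in it and its read methylation density (RMD,
   methylated / total CpG calls) is strictly above 0.6 (hyper) or strictly
   below 0.3 (hypo). Per-region counts are CPM-normalized by total mapped
   reads; the scalar score is the mean over all regions.
4. **insilico** — in-silico dilution validation: deterministic downsampling
   and replacement mixing of tumor reads into healthy-plasma reads over a
   fraction grid (0.1–5 %), plus Spearman correlation (exact permutation
   p-value for n ≤ 8).
5. **cohorteval** — unpenalized logistic regression with stratified k-fold
   cross-validation, ROC/AUC via the Mann–Whitney identity, Youden-J
   operating points, rank-sum group comparison, longitudinal post-operative
   score deltas, and paired per-region signed-rank contribution tests.
6. **synthdata** — a deterministic generator of toy genomes, group
   methylation profiles (beta-binomial with symmetric conversion error) and
   read sets, with planted differential regions and a serializable truth
   table, so the whole pipeline is testable offline.

## Command line

All functionality is exposed through one entry point:

```sh
cashcandi synth --seed 1 --n-cases 3 --n-controls 3 --out study/
cashcandi discover --tumor study/tumor_tissue_*.cytosine.tsv \
                   --normal study/normal_tissue_*.cytosine.tsv \
                   --plasma study/healthy_plasma_*.cytosine.tsv \
                   --direction hyper --delta 0.3 --fdr 0.05 \
                   --flank 75 --min-cpgs 10 --min-cov 5 -o regions.bed
cashcandi score --reads study/case_0.reads.tsv --regions regions.bed \
                --direction hyper --rmd-min 0.6 -o case_0.score.tsv
cashcandi simulate-dilution --plasma healthy.reads.tsv --tumor tumor.reads.tsv \
                --regions regions.bed --reps 6 --seed 1 -o dilution.tsv
cashcandi classify --features features.tsv --labels labels.tsv \
                --folds 3 --seed 7 --feature vector -o metrics.json
cashcandi monitor --scores longitudinal.tsv -o monitor.tsv
```

Every subcommand writes a resolved-config YAML next to its output and logs
the seeds of all stochastic steps.

## File formats

**Cytosine report TSV** (input to `discover`): one row per cytosine with
columns `chrom  pos  strand  count_methylated  count_unmethylated  context`;
only CpG-context rows are used, and opposite-strand counts are collapsed
onto the plus-strand C position.

**Read-call TSV dialect** (binary-free alternative to SAM/BAM): one row per
read (mates of a pair are independent rows) with columns
`chrom  start  end  calls  offsets`, where `calls` is a string of `M`
(methylated CpG) / `u` (unmethylated CpG) and `offsets` are comma-separated
0-based distances of each call from `start`. A read spanning chr1:100–249
with a methylated call at 110, an unmethylated call at 150 and a methylated
call at 200 is:

```
chr1	100	249	MuM	10,50,100
```

A read without CpG calls uses `.` for both fields. SAM/BAM input with
Bismark-style `XM` tags (`Z` = methylated CpG, `z` = unmethylated CpG,
other symbols ignored) parses to identical records.

**Region BED**: standard 0-based half-open BED3/BED4; internally
`chr6:391824-393789` (length 1966 bp) corresponds to the BED line
`chr6  391823  393789`.

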