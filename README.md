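# sagescape

Multiplexed SAGE-style tag expression profiling, end to end: simulate tag
libraries from a synthetic transcriptome, extract and quantify 19 bp tags,
and run the downstream statistics — rarefaction, PCA, moderated-t
tissue-specific calling, bootstrap-seeded K-means clustering, and PWM
motif over-representation.

## What it does

A tag library read is `barcode + 2 degenerate bases + CATG + 19 bp tag +
linker fill` (50 bp single-end), cut from a 119 bp amplified construct by
a type III enzyme that cleaves 25/27 nt downstream of its recognition
site. The package covers:

- **synthetic_data** — seeded generators for the transcriptome FASTA,
  sample sheet (sample/tissue/barcode TSV), block-structured tissue
  expression with lognormal replicate noise, multiplexed FASTQ reads with
  the construct geometry, and promoter sets with planted PWM sites —
  plus ground truth for every piece.
- **tagref** — virtual tag reference: each transcript's tag is the 19
  bases 3′ of its 3′-most CATG; multi-mapping tags keep the full
  transcript list.
- **extract** — per-read quality filter (fails when more than 20% of
  bases have Phred-implied accuracy below 0.5), barcode demultiplexing,
  two-base digital removal, exact-anchor tag extraction, and exact
  accounting stats.
- **quantify** — tag counting, transcript assignment with even count/k
  splitting of multi-mapped tags (mass-conserving), quantile
  normalization, log2 transform.
- **rarefaction** — without-replacement subsampling curves, closed-form
  hypergeometric expectation, saturation index.
- **diffexp** — tissue-vs-rest two-group fits, empirical-Bayes variance
  shrinkage (method-of-moments prior on log variances), moderated t with
  augmented degrees of freedom, and the fold-change > 5 / p < 1e-6
  filter.
- **cluster** — row adjustment (median-center, unit norm),
  Bradley–Fayyad bootstrap-refined K-means seeding (default K=10,
  S=400 subsamples), duplicated-run agreement (ARI), per-cluster
  average-linkage dendrograms on correlation distance (Newick), PCA with
  iterative sample exclusion, and a (K, S) sweep.
- **motif** — JASPAR flat-format PWM I/O, likelihood-ratio scanning on
  both strands, set raw score (sum of ln average LR), randomization
  p-values (background draws or per-sequence shuffling), site calls, and
  a per-cluster enrichment table with BH FDR.

## CLI

```bash
sagescape simulate --n-transcripts 500 --tissues 8 --reps 4 --depth 10000 --seed 1 --out sim/
sagescape extract  --fastq sim/reads.fastq --samples sim/samples.tsv --out ex/
sagescape quantify --tags-dir ex/ --samples sim/samples.tsv --transcripts sim/transcriptome.fasta --out quant/
sagescape rarefy   --counts quant/tag_counts.tsv --out curves.tsv
sagescape diffexp  --log2-matrix quant/expression_log2.tsv --samples sim/samples.tsv --out de.tsv
sagescape cluster  --log2-matrix quant/expression_log2.tsv --k 10 --s 400 --seed 1 --out clust/
sagescape motif    --clusters promoters/ --jaspar motifs.jaspar --background background.fasta --out report.tsv
```

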