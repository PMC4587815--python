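# episuite

An integrated Python toolkit for the analysis of base-resolution DNA
methylomes and their integration with other epigenomics data: ChIP-seq
signal, transcription-factor binding, gene models and Gene Ontology
annotation.

It is aimed at groups producing whole-genome or targeted bisulfite
sequencing (WGBS/RRBS) data alongside histone-mark and RNAPII ChIP-seq,
who need one coherent set of primitives for methylation calling,
differential methylation, region scoring, annotation and integrative
visualization.

## What it does

**Methylome store** (`episuite.methstore`). Per-cytosine tables
(chrom, pos, strand, context, #C, #T) are imported, statistically
called and kept on disk as bgzip-compressed, tabix-indexed TSVs, so
multi-sample whole-genome data can be interval-queried without loading
anything into memory. The confidence of each methyl-cytosine call is a
one-sided binomial test: with depth *n* = #C + #T and null success
probability *p₀* = (1 − conversion rate) + sequencing error rate,

> p = P(X ≥ #C), X ~ Binomial(n, p₀),

BH-corrected across all retained cytosines of a sample. Only cytosines
with #C ≥ 1 are stored; a companion routine extracts the zero-coverage
regions of the alignment, so every genomic cytosine is classifiable as
methylated, unmethylated or unmapped. Consistent-estimation output for
hydroxymethylation (mC/hmC level tables) imports into the same store
type.

**Region profiles** (`episuite.profiles`). Absolute (mC/bp) and
relative (mC per potential context site) methylation over binned
regions of interest, for one sample or congruent collections of
samples.

**Differential methylation** (`episuite.dmr`). A dynamic sliding
window walks each chromosome: a called, covered cytosine with a
minimum between-group level difference seeds a window, downstream
qualifying cytosines within *D* bp join it, and windows with enough
data points (and not too many unmapped cytosines) are tested — Wilcoxon
signed-rank on paired per-cytosine group means for two groups,
Kruskal–Wallis for more. Known-SNP cytosines and excluded regions
(e.g. partially methylated domains, found by `find_pmds`) never enter
the scan. Candidates are BH-corrected and nearby same-direction
survivors merged, combining p-values with Fisher's method.

**Region counts** (`episuite.regioncounts`). Total/per-base/binned
read counts with library- and length-normalization, coverage summits,
log2 ChIP/input enrichment, and the RNAPII stalling index
SI = (promoter read density)/(gene-body read density) with its
cumulative distributions.

**Annotation** (`episuite.annotate`). Nearest-TSS distance and
promoter/intragenic/intergenic location against all isoforms of a GTF
gene set, plus arbitrary user tracks; promoter CpG-content classes
(high/intermediate/low) by sliding-window GC fraction and CpG
observed/expected.

**Feature callers** (`episuite.features`). Enhancers as
promoter-distal H3K4me1/H3K27ac peaks (optionally CGI-excluded) with
nearest-gene matching and TF-binding stratification; putative lncRNA
loci from promoter-distal H3K4me3 seeds whose flanking windows exceed
a random-background quantile in every supplied transcription-evidence
track.

**Ontology** (`episuite.ontology`). Hypergeometric GO enrichment with
ancestor propagation, and iterative pruning of enriched parents that
are redundant with an enriched child.

**Heatmaps** (`episuite.heatmap`). ROI × multi-track binned matrices
mixing interval, alignment, methylation, score and gene-model tracks;
per-track quantile/threshold normalization; hierarchical row
clustering on chosen tracks; rendering with significance-based
dimming. The matrix and dendrogram remain available as plain data.

**Synthetic data** (`episuite.fixtures`). Seeded generators for
genomes, grouped WGBS methylomes with planted DMRs/PMDs, alignments
with fold-enriched features, gene models and GO DAGs — each with
machine-readable ground truth.

## Worked example

Simulate six methylomes (two groups of three, mean depth 30×) on a
200 kb genome with four planted DMRs of 20 CpGs and a methylation
difference of 0.4, then run the differential pipeline:

```python
from tempfile import mkdtemp
from episuite.fixtures import synth_genome, synth_methylomes
from episuite.dmr import DmrParams, find_dmrs, consolidate_dmrs

work = mkdtemp()
genome = synth_genome(f"{work}/genome.fa", length=200_000, cpg_density=0.01, seed=7)
stores, truth = synth_methylomes(genome, work, groups=2, samples_per_group=3,
                                 depth_mean=30, dmr_spec=(4, 20, 0.4), seed=7)

candidates = find_dmrs(stores, DmrParams(min_depth=5, min_diff=0.25))
regions = consolidate_dmrs(candidates, q_threshold=0.05, merge_dist=200)

print(f"planted: {[(iv.start, iv.end) for iv in truth.planted_dmrs]}")
print(f"{len(candidates)} candidate windows -> {len(regions)} DMRs")
for r in regions:
    print(f"{r.chrom}:{r.start}-{r.end}  {r.direction}  p={r.pvalue:.2e}  "
          f"q={r.qvalue:.2e}  merged={r.n_merged}")
```

Output:

```
planted: [(2173, 2947), (37220, 37847), (51499, 52051), (57877, 58471)]
6 candidate windows -> 4 DMRs
chr1:2223-2946  hyper  p=1.05e-06  q=7.63e-06  merged=2
chr1:36670-37980  hyper  p=3.78e-10  q=5.72e-06  merged=2
chr1:51499-52050  hyper  p=3.81e-06  q=7.63e-06  merged=1
chr1:57877-58470  hyper  p=7.63e-06  q=1.14e-05  merged=1
```

All four planted regions are recovered (group 1 is the hypermethylated
one, so every call is `hyper`), each within a few dozen bp of the
planted bounds, and nothing else is reported. Two planted DMRs were
each covered by two overlapping candidate windows, which consolidation
merged (`merged=2`) with Fisher-combined p-values.

The same analysis is available from the shell:

```bash
episuite simulate methylomes --seed 7 --length 200000 --n-dmr 4 --out sim/
episuite dmr \
  --group A=sim/group1_s1.bsstore.gz,sim/group1_s2.bsstore.gz,sim/group1_s3.bsstore.gz \
  --group B=sim/group2_s1.bsstore.gz,sim/group2_s2.bsstore.gz,sim/group2_s3.bsstore.gz \
  --out dmrs.bed
```

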