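# Methods

This note records the statistical models, the design choices made where
more than one defensible option existed, and what the synthetic data do
and do not demonstrate.

## Methylation calling and storage

Bisulfite treatment converts unmethylated cytosine to uracil (read as
T) and leaves methylcytosine intact, so reads carrying a C support a
methylation call. Two processes mimic methylation at an unmethylated
site: incomplete conversion (rate 1 − c, with c the conversion rate
measured from an unmethylated spike-in and supplied by the user) and
sequencing error (rate e). We therefore test the observed #C against

  X ~ Binomial(#C + #T, p₀),  p₀ = (1 − c) + e,

one-sided (upper tail), following the original base-resolution
methylome analyses. The addition slightly overstates p₀ (a doubly
corrupted read cancels out), which is conservative; an error is raised
if p₀ ≥ 1 or p₀ ≤ 0. q-values are Benjamini–Hochberg across all
retained cytosines of one sample, computed once at import time and
stored — interval queries filter on the stored q and never re-correct,
so a query's significance does not depend on the query window.

Only cytosines with #C ≥ 1 are stored. This is the trade-off that keeps
whole-genome stores small while remaining exact: combined with the
zero-coverage intervals extracted from the alignment
(`find_uncovered_regions`), every cytosine is recoverable as methylated
(at some significance), unmethylated (covered, no C-read) or unmapped.
The store is a bgzip-compressed TSV with a tabix index on the 1-based
position column; all in-memory intervals are 0-based half-open (BED
convention). Floats are serialized with a fixed format so re-importing
identical input yields a byte-identical payload.

Sequence context (CG/CHG/CHH) is taken from the input table or derived
from the genome: a plus-strand C followed by G is CG; followed by
non-G then G is CHG; else CHH; mirrored for minus-strand cytosines
(reference G read leftwards).

Hydroxymethylation stores parse consistent mC/hmC estimation output;
the level column carries the hmC estimate, #C is reconstructed as
round(level × depth), and since no binomial test backs these numbers
the p/q columns hold the sentinel −1. Queries skip sentinel records
unless explicitly asked to include them, so an hmC store can never leak
into a significance-filtered analysis by accident.

## Region profiles

Absolute methylation of a region or bin is called-mC count per bp;
relative methylation divides by the number of potential context sites
in the same stretch, counted on both strands by default (a symmetric
CpG contributes two sites; the original's convention here is unstated,
and counting strands separately matches the per-strand storage model).
A bin with zero potential sites has undefined relative methylation
(NaN), never zero. Binning partitions [s, e) exactly as
bin b = [s + ⌊bL/n⌋, s + ⌊(b+1)L/n⌋) — deterministic, exhaustive, bins
differing by at most 1 bp — and minus-strand regions report bins
5′→3′. "Called mC" means passing user thresholds, default min_depth 1
and q ≤ 0.05.

## Differential methylation

The scan walks each chromosome over the union of profiled cytosine
positions of all samples, with three-state data per sample and
position: a level #C/(#C+#T) where a record exists, 0 where the
position is covered but has no C-supporting read (unmethylated under
the storage model), and missing where it falls in that sample's
unsequenced regions.

A position is *eligible* when (i) at least one sample has a
significant call (q ≤ max_q, default 0.05) at depth ≥ min_depth
(default 5), and (ii) the spread of group means at that position is at
least min_diff (default 0.25). The walker seeds at the first eligible
position, extends over eligible positions within D bp (default 1000),
tests the window if it has ≥ min_points (default 5) positions and at
most max_missing (default 2) missing sample-values, then re-seeds at
the first qualifying position ≥ seed + D/2 and repeats. A flag
(`seed_must_qualify=False`) relaxes re-seeding to the first called
position regardless of min_diff, since the original description is
ambiguous on this point; the default is the stricter reading. The
tested-window sets are verified against a literal brute-force
enumeration of the procedure in the tests.

Two groups are compared with the Wilcoxon signed-rank test pairing the
two group-mean levels at each cytosine (exact null up to n = 25
without ties, normal approximation with continuity correction beyond);
more groups with Kruskal–Wallis on all (cytosine, sample) levels
pooled by group. Kruskal–Wallis has no paired form; the Friedman test
would be the paired analogue but is not what the method names, so KW
is implemented as named. Windows with zero between-group variance are
skipped rather than assigned p = 1, so they do not dilute the
multiple-testing correction. Defaults are package choices — the method
defines the cutoffs as user-set and names no values.

Consolidation BH-corrects all candidate p-values, keeps q ≤ threshold
(default 0.05), and merges same-direction survivors closer than
merge_dist (default 200 bp; overlapping candidates always merge). A
merged region reports the Fisher-combined p of its members
(−2Σln p ~ χ² with 2k df; a literal p = 0 is clamped to the smallest
positive float with a warning, and the combined value may then
underflow to 0) and, as its q, the minimum member q — correction
happened before merging, and no second correction pass is defined.

Region mode tests one region at a time on per-sample mean levels
(paired Wilcoxon across equal-sized groups, else Kruskal–Wallis),
skipping regions where any sample has fewer than min_points
informative cytosines; intended for sparse non-CpG contexts where
windows are unreliable.

Partially methylated domains are found per sample as runs of 10 kb
windows (5 kb step) holding ≥ 20 CpG records with mean level in
[0.2, 0.7), merged, with runs shorter than 20 kb dropped. These bounds
mirror the published characterization of PMDs in differentiated human
cells; the domains can be passed to the DMR scan as excluded regions,
since they are differential against pluripotent methylomes by
definition and would otherwise swamp the focused scan.

Per-chromosome sharding is the unit of parallelism: results of
scanning chromosomes independently and concatenating equal the serial
scan exactly (tested), because no state crosses a chromosome boundary.

## Read counts, enrichment, stalling

A read counts for a region when its alignment interval overlaps it by
≥ 1 bp (a spanning read counts in every region it touches);
secondary, supplementary, duplicate and unmapped records are ignored,
and the library size is the count of primary mapped reads.
Normalizations divide by library/10⁶ and/or region length/10³
(counts per million, per kb); the factors are recorded alongside the
scores so raw counts are recoverable. Summits are the 1-based position
of maximum per-base depth, ties resolved to the smallest position,
zero-coverage regions reported as missing. Enrichment is
log2[((chip + ps)/chip_lib)/((input + ps)/input_lib)] with
pseudocount ps = 0.5.

The stalling index is the promoter-to-gene-body ratio of RNAPII read
densities. Windows are gene-oriented: promoter [TSS − 300, TSS + 300),
gene body [TSS + 1250, TES); both densities are (reads + ps)/bp with
ps = 0.5 so unexpressed genes stay finite, and genes shorter than the
offset are skipped. The window sizes are package defaults (the
underlying definition leaves them open). Because an SI shift can come
from either window, the cumulative-distribution view reports the
promoter and gene-body density ECDFs alongside the log-SI ECDF.

## Annotation and promoter classes

Nearest-TSS distance is measured from the region midpoint, signed in
gene orientation (negative = upstream); midpoint was chosen over
closest-edge as the least degenerate option for wide regions. Location
is promoter if the region overlaps any isoform's [TSS − 2000,
TSS + 1000) window, else intragenic on transcript-span overlap, else
intergenic; all overlapping isoforms are reported. Promoter CpG
classes use 500 bp windows stepped by 5 bp: GC fraction and CpG
observed/expected = (#CpG · w)/(#C · #G) (defined 0 when #C or #G is
0); high if any window reaches GC ≥ 0.55 and o/e ≥ 0.75, low if no
window reaches o/e ≥ 0.48, intermediate otherwise — the standard
sliding-window thresholds for this classification. Windows more than
half N are ignored; an all-N promoter gets no class.

## Feature callers

Enhancer calls are peaks of H3K4me1 (active or poised) or H3K27ac
(active) that overlap no promoter, optionally no CpG island, and
optionally lie ≥ min_tss_dist from every TSS. lncRNA seeds are
H3K4me3 peaks ≥ 10 kb (default) from every promoter whose
library-normalized H3K4me1/H3K4me3 density ratio is ≤ 1.0 — excess
H3K4me1 marks an enhancer, and a ratio is the operational reading of
"lower H3K4me1 density"; when no H3K4me3 alignment is supplied the
K4me1 density is instead compared against its genome-wide mean.
Probe windows of 2 kb immediately up- and downstream of each seed are
scored on every supplied transcription-evidence track (RNA-seq,
H3K79me2, RNAPII); the null distribution comes from 1000 random
promoter-free size-matched regions (chromosomes weighted by length,
rejection sampling, fixed seed), and a direction is called when
*every* track exceeds its background quantile (default 0.95) — the
all-tracks rule is the stricter reading of an ambiguous conjunction
and is switchable in principle by passing fewer tracks. Raising the
quantile can only remove calls (tested).

## Ontology

Enrichment is the classic upper-tail hypergeometric test per term
after propagating gene annotations to all ancestors, BH-corrected
across tested terms. This is deliberately plainer than
elimination-style topGO algorithms: the contribution here is the
pruning step, and a transparent base statistic makes its behaviour
auditable. Pruning iterates to a fixed point: an enriched term whose
enriched *direct* parent shares more than overlap_threshold (default
0.75) of the child's query genes causes the parent to be dropped. The
child's gene set is the denominator — redundancy is judged against the
more specific term that will be kept; parent- and union-denominator
variants are available. Drops are collected against the current state
before applying, making the result order-independent (tested);
children are never removed by the rule.

## Heatmaps

Tracks are evaluated independently and concatenated, so assembly is
order-independent and per-track normalization provably ignores other
tracks. Quantile normalization maps each value to (rank − 0.5)/n with
average ranks for ties — a constant block maps to exactly 0.5, and
outputs stay inside (0, 1). Threshold normalization clips at the given
percentiles then rescales min–max to [0, 1]. NaNs are excluded from
the statistics, preserved in the matrix, and rendered grey. Gene-model
tracks encode exon = 2, intron = 1, none = 0 per bin (an explicit
categorical convention; none is inherent to the data). Row clustering
is complete-linkage Euclidean hierarchical clustering on the selected
column blocks (missing imputed as 0 with a warning); the dendrogram is
exportable as Newick. Dimming maps a per-region significance s to a
brightness weight clamp(log10 s / log10 s_full, 0, 1) with
s_full = 0.01: full brightness at or below s_full, fading linearly in
−log10 space to 0 at s = 1.

## Synthetic data

The generators define the test conditions. Genomes are i.i.d. bases at
the requested GC content with accidental CpGs destroyed and the exact
target number planted back, so CpG density is controlled to within a
few percent. Methylomes simulate per-CpG counts: a per-site grand mean
level from Beta(5, 1.5) (mean 0.77 — a typical somatic CpG landscape),
per-sample levels Beta-distributed around the group mean with
concentration 30 (between-sample overdispersion so rank tests face
realistic replicate noise, not just binomial sampling), depth
Poisson(30), and #C Binomial(depth, level). Planted DMRs reset group
1's site means to Uniform(0.6, 0.9) and lower the other groups' by
delta; planted PMDs set all groups to levels near 0.45. Alignments are
uniform read starts plus (fold − 1)× extra density over feature
intervals.

Default study conditions used by the tests and the acceptance script:
DMR recovery on a 1 Mb genome, 3 vs 3 samples, 10 planted DMRs of 20
CpGs with delta 0.4 at depth 30; the null control on 400 kb of the
same generator with delta 0 (sized so the scan tests well over 200
windows); PMD recovery of one 50 kb domain at level 0.45 in a 0.9
background on 200 kb.

What the simulations do not emulate: read sequences and alignment
artefacts, context-dependent or strand-asymmetric conversion failure,
spatial correlation of methylation outside planted features, copy
number, or contaminating subpopulations. Passing recovery tests
therefore shows the algorithms implement their definitions and detect
their target signal at realistic noise, not that the defaults are
optimal for any particular real dataset.

## Limitations

No beta-binomial/shrinkage modelling, smoothing-based DMR detection or
covariate adjustment; the Wilcoxon/KW tests treat cytosines within a
window as exchangeable replicates, ignoring their spatial correlation,
which is anti-conservative for strongly autocorrelated data and is the
usual caveat of rank-based window tests. Conversion rate is an input,
never estimated. The lncRNA caller scores chromatin and transcription
evidence only — it does not assemble transcripts or score coding
potential. GO enrichment ignores annotation evidence codes and treats
the universe as exchangeable.
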