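"""Read-count metrics over genomic regions from aligned reads.

Covers the routine ChIP-seq quantifications: total or per-base read
counts in regions (optionally normalized by library size and/or region
length), peak summit location, input-corrected log2 enrichment, and the
RNA polymerase II stalling index (promoter over gene-body read density),
together with its cumulative distribution across genes.

A read counts for a region when its alignment interval overlaps it by at
least one bp; a read spanning two regions counts in both.  Unmapped,
secondary, supplementary and duplicate-flagged alignments are ignored
everywhere, and the library size is the number of primary mapped reads.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .intervals import Interval, IntervalSet

logger = logging.getLogger(__name__)


def _is_countable(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate
    )


def library_size(bam_path: str) -> int:
    """Number of primary mapped, non-duplicate reads."""
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        return sum(1 for read in bam.fetch() if _is_countable(read))


@dataclass
class ScoredRegions:
    """Per-region scores plus the normalization that produced them."""

    rois: IntervalSet
    scores: list  # one number or one np.ndarray per ROI
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.rois):
            raise ValueError("one score entry per ROI required")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tname\tscore\n")
            for iv, sc in zip(self.rois, self.scores):
                if isinstance(sc, np.ndarray):
                    val = ",".join(f"{v:g}" for v in sc)
                else:
                    val = "NA" if sc is None else f"{sc:g}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{val}\n")


def _clip_roi(iv: Interval, chrom_len: Optional[int]) -> Interval:
    if chrom_len is not None and iv.end > chrom_len:
        warnings.warn(
            f"ROI {iv.chrom}:{iv.start}-{iv.end} extends past chromosome end; clipped"
        )
        return Interval(iv.chrom, min(iv.start, chrom_len), chrom_len,
                        iv.name, iv.score, iv.strand)
    return iv


def base_coverage(bam: pysam.AlignmentFile, iv: Interval) -> np.ndarray:
    """Per-base depth vector over [start, end) from countable reads."""
    depth = np.zeros(iv.length, dtype=np.int64)
    if iv.chrom not in bam.references or iv.length == 0:
        return depth
    for read in bam.fetch(iv.chrom, iv.start, iv.end):
        if not _is_countable(read):
            continue
        s = max(read.reference_start - iv.start, 0)
        e = min(read.reference_end - iv.start, iv.length)
        if e > s:
            depth[s:e] += 1
    return depth


def region_counts(
    bam_path: str,
    rois: IntervalSet,
    mode: str = "total",
    nbins: int = 1,
    norm_lib: bool = False,
    norm_len: bool = False,
) -> ScoredRegions:
    """Count reads in regions.

    mode="total" counts each overlapping read once per ROI; "per_base"
    returns depth vectors; "binned" returns per-bin total counts using
    the midpoint-free overlap rule (a read counts in every bin its
    alignment overlaps).  norm_lib divides by (library size / 1e6),
    norm_len by (region length / 1e3); neither applies to per_base.
    """
    if mode not in ("total", "per_base", "binned"):
        raise ValueError(f"unknown mode {mode!r}")
    from .profiles import bin_edges

    lib = library_size(bam_path) if norm_lib else None
    scores: list = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        chrom_lens = dict(zip(bam.references, bam.lengths))
        for iv in rois:
            iv = _clip_roi(iv, chrom_lens.get(iv.chrom))
            if mode == "per_base":
                scores.append(base_coverage(bam, iv))
                continue
            reads = []
            if iv.chrom in chrom_lens and iv.length > 0:
                reads = [
                    (r.reference_start, r.reference_end)
                    for r in bam.fetch(iv.chrom, iv.start, iv.end)
                    if _is_countable(r)
                ]
            if mode == "total":
                val = float(len(reads))
                if norm_lib:
                    val /= max(lib, 1) / 1e6
                if norm_len:
                    val /= max(iv.length, 1) / 1e3
                scores.append(val)
            else:
                edges = bin_edges(iv.start, iv.end, nbins)
                row = np.zeros(nbins)
                for b, (bs, be) in enumerate(edges):
                    row[b] = sum(1 for s, e in reads if s < be and e > bs)
                if norm_lib:
                    row /= max(lib, 1) / 1e6
                if norm_len:
                    lens = np.array([be - bs for bs, be in edges], dtype=float)
                    row /= np.maximum(lens, 1) / 1e3
                if iv.strand == "-":
                    row = row[::-1]
                scores.append(row)
    return ScoredRegions(
        rois=rois, scores=scores,
        normalization={"library_size": lib, "norm_lib": norm_lib, "norm_len": norm_len},
    )


def coverage_summit(bam_path: str, rois: IntervalSet) -> list[Optional[int]]:
    """1-based position of maximum depth per ROI (ties -> smallest
    position); None where the ROI has zero coverage."""
    out: list[Optional[int]] = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        chrom_lens = dict(zip(bam.references, bam.lengths))
        for iv in rois:
            iv = _clip_roi(iv, chrom_lens.get(iv.chrom))
            depth = base_coverage(bam, iv)
            if depth.size == 0 or depth.max() == 0:
                out.append(None)
            else:
                out.append(iv.start + int(np.argmax(depth)) + 1)
    return out


def enrichment(
    chip_bam: str,
    input_bam: str,
    rois: IntervalSet,
    pseudocount: float = 0.5,
) -> ScoredRegions:
    """Per-region log2 enrichment of ChIP over matched input.

    log2[((chip + ps) / chip_lib) / ((input + ps) / input_lib)].
    """
    chip_lib = library_size(chip_bam)
    input_lib = library_size(input_bam)
    if chip_lib == 0 or input_lib == 0:
        raise ValueError("zero-size library")
    chip = region_counts(chip_bam, rois, mode="total")
    inp = region_counts(input_bam, rois, mode="total")
    scores = [
        math.log2(((c + pseudocount) / chip_lib) / ((i + pseudocount) / input_lib))
        for c, i in zip(chip.scores, inp.scores)
    ]
    return ScoredRegions(
        rois=rois, scores=scores,
        normalization={"chip_library": chip_lib, "input_library": input_lib,
                       "pseudocount": pseudocount},
    )


@dataclass
class StallingResult:
    """Promoter vs gene-body RNAPII densities for one gene."""

    gene_id: str
    chrom: str
    strand: str
    promoter: tuple[int, int]  # 0-based half-open windows actually used
    genebody: tuple[int, int]
    promoter_density: float  # reads/bp, pseudocount included
    genebody_density: float
    stalling_index: float


def stalling_index(
    bam_path: str,
    genes: Sequence,
    promoter_window: tuple[int, int] = (300, 300),
    genebody_offset: int = 1250,
    pseudocount: float = 0.5,
) -> list[StallingResult]:
    """Stalling index per gene: promoter over gene-body read density.

    The promoter window is [TSS-up, TSS+down) in gene orientation; the
    gene body starts ``genebody_offset`` bp downstream of the TSS and
    runs to the TES.  The pseudocount is added to both read counts so
    unexpressed genes stay finite.  ``genes`` is a sequence of
    :class:`episuite.annotate.GeneModel`.
    """
    up, down = promoter_window
    out: list[StallingResult] = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        chrom_lens = dict(zip(bam.references, bam.lengths))
        for gene in genes:
            tx = gene.transcripts[0]  # gene-level windows from first/canonical isoform
            tss, tes, strand, chrom = tx.tss, tx.tes, tx.strand, tx.chrom
            if abs(tes - tss) < genebody_offset:
                logger.info("gene %s shorter than genebody offset; skipped", gene.gene_id)
                continue
            # tss/tes are 0-based base positions; windows are gene-oriented
            if strand == "+":
                prom = (tss - up, tss + down)
                body = (tss + genebody_offset, tes + 1)
            else:
                prom = (tss - down + 1, tss + up + 1)
                body = (tes, tss - genebody_offset + 1)
            prom = (max(prom[0], 0), min(prom[1], chrom_lens.get(chrom, prom[1])))
            body = (max(body[0], 0), min(body[1], chrom_lens.get(chrom, body[1])))
            if prom[1] <= prom[0] or body[1] <= body[0]:
                logger.info("gene %s windows collapse after clipping; skipped", gene.gene_id)
                continue
            n_prom = sum(
                1 for r in bam.fetch(chrom, *prom) if _is_countable(r)
            ) if chrom in chrom_lens else 0
            n_body = sum(
                1 for r in bam.fetch(chrom, *body) if _is_countable(r)
            ) if chrom in chrom_lens else 0
            pd = (n_prom + pseudocount) / (prom[1] - prom[0])
            bd = (n_body + pseudocount) / (body[1] - body[0])
            out.append(StallingResult(
                gene_id=gene.gene_id, chrom=chrom, strand=strand,
                promoter=prom, genebody=body,
                promoter_density=pd, genebody_density=bd,
                stalling_index=pd / bd,
            ))
    return out


def stalling_index_cdf(
    results_by_sample: dict[str, Sequence[StallingResult]],
) -> dict[str, dict[str, np.ndarray]]:
    """Empirical CDFs of log10 SI, promoter and gene-body densities.

    Returns, per sample, arrays ``log_si``/``promoter``/``genebody``
    (sorted values) and matching ``*_cdf`` fractions ending at 1; the
    dissection of an SI shift into its promoter and gene-body components
    falls out of plotting the three side by side.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for sample, results in results_by_sample.items():
        if not results:
            raise ValueError(f"no stalling results for sample {sample!r}")
        tabs: dict[str, np.ndarray] = {}
        for key, vals in (
            ("log_si", [math.log10(r.stalling_index) for r in results]),
            ("promoter", [r.promoter_density for r in results]),
            ("genebody", [r.genebody_density for r in results]),
        ):
            v = np.sort(np.asarray(vals))
            tabs[key] = v
            tabs[key + "_cdf"] = np.arange(1, v.size + 1) / v.size
        out[sample] = tabs
    return out


def plot_stalling_cdf(cdfs: dict[str, dict[str, np.ndarray]], out_path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for sample, tabs in cdfs.items():
        axes[0].step(tabs["log_si"], tabs["log_si_cdf"], where="post", label=sample)
        axes[1].step(tabs["promoter"], tabs["promoter_cdf"], where="post", label=sample)
        axes[2].step(tabs["genebody"], tabs["genebody_cdf"], where="post", label=sample)
    for ax, title in zip(axes, ("log10 stalling index", "promoter density", "genebody density")):
        ax.set_title(title)
        ax.set_ylabel("cumulative fraction")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
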