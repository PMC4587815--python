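"""Summaries of methylomes over (binned) regions of interest.

Two densities are reported per region or bin: the absolute methylation
level (called mCs per base pair) and the relative level (called mCs over
the number of potential methylation sites of the requested context in
the same stretch of sequence, so a fully methylated CpG island and a
CpG-poor region can be told apart from a merely CpG-dense one).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pyfaidx

from .intervals import Interval, IntervalSet
from .methstore import MethylomeStore, derive_context


def bin_edges(start: int, end: int, nbins: int) -> list[tuple[int, int]]:
    """Exact partition of [start, end) into ``nbins`` near-equal bins.

    Bin b spans [start + floor(b*L/n), start + floor((b+1)*L/n)); uneven
    remainders fall in later bins.
    """
    length = end - start
    return [
        (start + (b * length) // nbins, start + ((b + 1) * length) // nbins)
        for b in range(nbins)
    ]


def count_context_sites(
    genome: "pyfaidx.Fasta | str",
    chrom: str,
    start: int,
    end: int,
    context: str = "CG",
    strand_mode: str = "both",
) -> int:
    """Number of cytosines of ``context`` within [start, end), 0-based.

    ``strand_mode`` selects plus-strand Cs, minus-strand Cs (reference
    Gs whose complement is a C in context), or both; symmetric CpG sites
    therefore count twice under ``both``.
    """
    if strand_mode not in ("both", "plus", "minus"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if isinstance(genome, str):
        genome = pyfaidx.Fasta(genome)
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome FASTA")
    # two bases of flank on each side so edge cytosines get their context
    lo = max(start - 2, 0)
    seq = str(genome[chrom][lo : end + 2]).upper()
    n = 0
    for i in range(start - lo, min(end, len(genome[chrom])) - lo):
        if strand_mode in ("both", "plus") and seq[i] == "C":
            if derive_context(seq, i, "+") == context:
                n += 1
        if strand_mode in ("both", "minus") and seq[i] == "G":
            if derive_context(seq, i, "-") == context:
                n += 1
    return n


@dataclass
class RegionProfile:
    """Binned methylation matrices for one sample over a fixed ROI set.

    ``abs_meth`` holds called mCs per bp, ``rel_meth`` called mCs per
    potential site (NaN where a bin contains no site), with minus-strand
    ROIs reported 5'->3'.
    """

    rois: IntervalSet
    nbins: int
    sample_id: str
    context: str
    mc_counts: np.ndarray
    site_counts: np.ndarray
    abs_meth: np.ndarray
    rel_meth: np.ndarray

    def to_tsv(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        header = "\t".join(
            ["chrom", "start", "end", "strand"] + [f"bin{b}" for b in range(self.nbins)]
        )
        for name, mat in (
            ("abs_meth", self.abs_meth),
            ("rel_meth", self.rel_meth),
            ("mc_counts", self.mc_counts),
            ("site_counts", self.site_counts),
        ):
            path = os.path.join(out_dir, f"{self.sample_id}.{name}.tsv")
            with open(path, "w") as fh:
                fh.write(header + "\n")
                for iv, row in zip(self.rois, mat):
                    vals = "\t".join("NA" if np.isnan(v) else f"{v:g}" for v in row)
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand or '.'}\t{vals}\n")


class ProfileCollection(dict):
    """sample_id -> RegionProfile, all congruent in ROIs, bins and context."""

    def __setitem__(self, key: str, value: RegionProfile) -> None:
        for other in self.values():
            if (
                value.nbins != other.nbins
                or value.context != other.context
                or len(value.rois) != len(other.rois)
            ):
                raise ValueError("profiles in a collection must share ROIs, bins and context")
        super().__setitem__(key, value)


def profile_regions(
    store: MethylomeStore,
    rois: IntervalSet,
    nbins: int = 1,
    genome: Optional["pyfaidx.Fasta | str"] = None,
    context: str = "CG",
    min_depth: int = 1,
    max_q: float = 0.05,
) -> RegionProfile:
    """Profile called mCs of a store over binned ROIs.

    A cytosine counts as methylated when it passes the depth and
    corrected-significance thresholds.  ``site_counts`` (and hence
    relative methylation) requires the genome FASTA; without it,
    rel_meth is all-NaN.
    """
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    if len(rois) == 0:
        raise ValueError("empty ROI set")
    if isinstance(genome, str):
        genome = pyfaidx.Fasta(genome)

    n = len(rois)
    mc = np.zeros((n, nbins), dtype=float)
    sites = np.zeros((n, nbins), dtype=float)
    for r, roi in enumerate(rois):
        if roi.length < nbins:
            raise ValueError(
                f"ROI {roi.chrom}:{roi.start}-{roi.end} shorter than nbins={nbins}"
            )
        edges = bin_edges(roi.start, roi.end, nbins)
        recs = store.query(
            roi.chrom, roi.start, roi.end,
            min_depth=min_depth, max_q=max_q, context_filter=[context],
        )
        positions = np.array([rec.pos - 1 for rec in recs], dtype=int)  # 0-based
        for b, (bs, be) in enumerate(edges):
            mc[r, b] = np.count_nonzero((positions >= bs) & (positions < be))
            if genome is not None:
                sites[r, b] = count_context_sites(genome, roi.chrom, bs, be, context)
        if roi.strand == "-":  # report bins 5'->3'
            mc[r] = mc[r, ::-1]
            sites[r] = sites[r, ::-1]

    lengths = np.array(
        [[be - bs for bs, be in bin_edges(roi.start, roi.end, nbins)] for roi in rois],
        dtype=float,
    )
    for r, roi in enumerate(rois):
        if roi.strand == "-":
            lengths[r] = lengths[r, ::-1]
    abs_meth = mc / lengths
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_meth = np.where(sites > 0, mc / np.maximum(sites, 1), np.nan)
    if genome is None:
        rel_meth = np.full_like(mc, np.nan)
        sites = np.zeros_like(mc)
    return RegionProfile(
        rois=rois, nbins=nbins, sample_id=store.sample_id, context=context,
        mc_counts=mc, site_counts=sites, abs_meth=abs_meth, rel_meth=rel_meth,
    )


def region_scores_profile(
    rois: IntervalSet, scores: Sequence[float], sample_id: str, context: str = "CG"
) -> RegionProfile:
    """Wrap externally supplied region-level methylation scores (e.g. from
    low-resolution enrichment assays) as a single-bin RegionProfile."""
    vals = np.asarray(scores, dtype=float).reshape(-1, 1)
    if vals.shape[0] != len(rois):
        raise ValueError("one score per ROI required")
    nan = np.full_like(vals, np.nan)
    return RegionProfile(
        rois=rois, nbins=1, sample_id=sample_id, context=context,
        mc_counts=nan.copy(), site_counts=nan.copy(), abs_meth=vals, rel_meth=vals.copy(),
    )
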