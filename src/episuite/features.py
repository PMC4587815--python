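"""Epigenetic-signature feature callers: enhancers and lncRNA loci.

Enhancers are promoter-distal H3K4me1 (active or poised) or H3K27ac
(active) ChIP-seq peaks, optionally purged of CpG islands, and can be
matched to their most proximal gene and stratified by transcription
factor binding.  Putative lncRNA loci start from promoter-distal
H3K4me3 peaks that lack the enhancer-typical excess of H3K4me1, then
require every supplied transcription-evidence track (RNA-seq, H3K79me2,
RNAPII) to exceed a background quantile in a probe window immediately
up- or downstream of the seed peak; the background is drawn from random
size-matched promoter-free regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import Interval, IntervalSet
from .regioncounts import library_size, region_counts


@dataclass
class EnhancerCall:
    interval: Interval
    state: str  # "active" (H3K27ac) or "any" (H3K4me1)
    matched_gene: Optional[str] = None
    matched_distance: Optional[int] = None
    tf_bound: dict = field(default_factory=dict)  # tf name -> bool


def find_enhancers(
    mark_peaks: IntervalSet,
    mark: str,
    promoters: IntervalSet,
    cgi: Optional[IntervalSet] = None,
    min_tss_dist: int = 0,
    tss_positions: Optional[Sequence[tuple[str, int]]] = None,
) -> list[EnhancerCall]:
    """Promoter-distal peaks of an enhancer mark.

    A peak is kept when it overlaps no promoter, lies at least
    ``min_tss_dist`` bp (peak midpoint to TSS) from every TSS in
    ``tss_positions`` (when given), and, if ``cgi`` is supplied, does
    not overlap a CpG island.
    """
    if mark not in ("H3K4me1", "H3K27ac"):
        raise ValueError(f"unsupported enhancer mark {mark!r}")
    state = "active" if mark == "H3K27ac" else "any"
    calls: list[EnhancerCall] = []
    for peak in mark_peaks:
        if promoters.overlapping(peak.chrom, peak.start, peak.end):
            continue
        if cgi is not None and cgi.overlapping(peak.chrom, peak.start, peak.end):
            continue
        if tss_positions and min_tss_dist > 0:
            mid = peak.midpoint
            if any(
                chrom == peak.chrom and abs(mid - pos) < min_tss_dist
                for chrom, pos in tss_positions
            ):
                continue
        calls.append(EnhancerCall(interval=peak, state=state))
    return calls


def match_enhancers(
    enhancers: Sequence[EnhancerCall],
    tss_set: Sequence[tuple[str, int, str]],  # (chrom, tss position, gene id)
    tf_peaks: Optional[Mapping[str, IntervalSet]] = None,
    max_dist: int = 100_000,
) -> list[EnhancerCall]:
    """Attach the most proximal gene and TF-binding flags to each call.

    The nearest TSS within ``max_dist`` of the enhancer midpoint becomes
    the matched gene (none beyond that); each named TF peak set yields a
    boolean overlap flag, enabling stratified summaries of TF-bound
    versus unbound enhancers per gene (:func:`stratify_enhancers`).
    """
    if not enhancers:
        raise ValueError("empty enhancer list")
    tf_peaks = tf_peaks or {}
    out: list[EnhancerCall] = []
    for call in enhancers:
        mid = call.interval.midpoint
        best: Optional[tuple[float, str]] = None
        for chrom, pos, gene in tss_set:
            if chrom != call.interval.chrom:
                continue
            d = abs(mid - pos)
            if d <= max_dist and (best is None or (d, gene) < best):
                best = (d, gene)
        flags = {
            name: bool(peaks.overlapping(call.interval.chrom, call.interval.start,
                                         call.interval.end))
            for name, peaks in tf_peaks.items()
        }
        out.append(EnhancerCall(
            interval=call.interval, state=call.state,
            matched_gene=best[1] if best else None,
            matched_distance=int(round(best[0])) if best else None,
            tf_bound=flags,
        ))
    return out


def stratify_enhancers(matched: Sequence[EnhancerCall]) -> dict[str, dict[str, dict[str, int]]]:
    """Per TF, per matched gene: counts of bound vs unbound enhancers."""
    tfs = sorted({tf for c in matched for tf in c.tf_bound})
    out: dict[str, dict[str, dict[str, int]]] = {tf: {} for tf in tfs}
    for c in matched:
        gene = c.matched_gene or "(unmatched)"
        for tf in tfs:
            slot = out[tf].setdefault(gene, {"bound": 0, "unbound": 0})
            slot["bound" if c.tf_bound.get(tf) else "unbound"] += 1
    return out


@dataclass
class LncRnaCandidate:
    seed_peak: Interval
    direction: str  # upstream | downstream (genomic right/left of the peak)
    probe_window: Interval
    densities: dict  # track -> reads/bp (library-normalized) in the probe
    cutoffs: dict  # track -> background quantile cutoff
    marks_passed: list


def _sample_background(
    chrom_sizes: Mapping[str, int],
    promoters: IntervalSet,
    probe_len: int,
    n: int,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> IntervalSet:
    """Random promoter-free probe-length regions, chromosomes weighted by length."""
    chroms = sorted(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    usable = [c for c, L in zip(chroms, lengths) if L >= probe_len]
    if not usable:
        raise ValueError("no chromosome long enough for the probe length")
    weights = np.array([chrom_sizes[c] for c in usable], dtype=float)
    weights /= weights.sum()
    regions: list[Interval] = []
    while len(regions) < n:
        for _ in range(max_tries):
            chrom = usable[int(rng.choice(len(usable), p=weights))]
            start = int(rng.integers(0, chrom_sizes[chrom] - probe_len + 1))
            if not promoters.overlapping(chrom, start, start + probe_len):
                regions.append(Interval(chrom, start, start + probe_len))
                break
        else:
            raise RuntimeError("could not place a promoter-free background region")
    return IntervalSet(regions)


def find_lncrna(
    k4me3_peaks: IntervalSet,
    promoters: IntervalSet,
    k4me1_bam: str,
    signal_bams: Mapping[str, str],
    chrom_sizes: Mapping[str, int],
    min_tss_dist: int = 10_000,
    probe_len: int = 2_000,
    n_background: int = 1_000,
    quantile: float = 0.95,
    k4me1_max_ratio: float = 1.0,
    k4me3_bam: Optional[str] = None,
    seed: int = 0,
) -> list[LncRnaCandidate]:
    """Call putative lncRNA loci from chromatin plus transcription signal.

    Seeds are H3K4me3 peaks whose midpoint is at least ``min_tss_dist``
    from every promoter midpoint and whose library-normalized H3K4me1
    over H3K4me3 read density stays at or below ``k4me1_max_ratio``
    (excess H3K4me1 flags an enhancer instead).  For each seed, probe
    windows of ``probe_len`` bp immediately up- and downstream are
    scored on every track in ``signal_bams``; a direction is called when
    all tracks exceed their background-quantile cutoff, the background
    being ``n_background`` random promoter-free regions (fixed ``seed``).
    """
    if not signal_bams:
        raise ValueError("at least one transcription-signal track is required")
    for chrom in {p.chrom for p in k4me3_peaks}:
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome size missing for {chrom!r}")
    rng = np.random.default_rng(seed)

    # seed selection: promoter-distal and K4me1-low relative to K4me3
    distal: list[Interval] = []
    prom_mids = [(p.chrom, p.midpoint) for p in promoters]
    for peak in k4me3_peaks:
        mid = peak.midpoint
        if any(c == peak.chrom and abs(mid - m) < min_tss_dist for c, m in prom_mids):
            continue
        if promoters.overlapping(peak.chrom, peak.start, peak.end):
            continue
        distal.append(peak)
    if not distal:
        return []

    seeds: list[Interval] = []
    peak_set = IntervalSet(distal)
    k4me1 = region_counts(k4me1_bam, peak_set, mode="total", norm_lib=True, norm_len=True)
    if k4me3_bam is not None:
        k4me3 = region_counts(k4me3_bam, peak_set, mode="total", norm_lib=True, norm_len=True)
        for peak, d1, d3 in zip(peak_set, k4me1.scores, k4me3.scores):
            if d3 > 0 and d1 / d3 <= k4me1_max_ratio:
                seeds.append(peak)
    else:
        # no K4me3 signal track: require K4me1 density not above the genome-wide mean
        lib = max(library_size(k4me1_bam), 1)
        genome_rate = lib / max(sum(chrom_sizes.values()), 1) * 1e3 / (lib / 1e6)
        for peak, d1 in zip(peak_set, k4me1.scores):
            if d1 <= k4me1_max_ratio * genome_rate:
                seeds.append(peak)
    if not seeds:
        return []

    background = _sample_background(chrom_sizes, promoters, probe_len, n_background, rng)
    cutoffs: dict[str, float] = {}
    bg_scores: dict[str, np.ndarray] = {}
    for name, bam in sorted(signal_bams.items()):
        sc = region_counts(bam, background, mode="total", norm_lib=True, norm_len=True)
        bg_scores[name] = np.asarray(sc.scores, dtype=float)
        cutoffs[name] = float(np.quantile(bg_scores[name], quantile))

    out: list[LncRnaCandidate] = []
    for peak in seeds:
        for direction in ("upstream", "downstream"):
            if direction == "upstream":
                ps, pe = peak.start - probe_len, peak.start
            else:
                ps, pe = peak.end, peak.end + probe_len
            ps = max(ps, 0)
            pe = min(pe, chrom_sizes[peak.chrom])
            if pe - ps < probe_len:
                continue
            probe = Interval(peak.chrom, ps, pe)
            densities: dict[str, float] = {}
            passed: list[str] = []
            for name, bam in sorted(signal_bams.items()):
                sc = region_counts(bam, IntervalSet([probe]), mode="total",
                                   norm_lib=True, norm_len=True)
                densities[name] = float(sc.scores[0])
                if densities[name] > cutoffs[name]:
                    passed.append(name)
            if len(passed) == len(signal_bams):
                out.append(LncRnaCandidate(
                    seed_peak=peak, direction=direction, probe_window=probe,
                    densities=densities, cutoffs=dict(cutoffs), marks_passed=passed,
                ))
    return out
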