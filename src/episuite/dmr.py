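"""Differential methylation between sample groups.

The detector walks each chromosome with a dynamic sliding window:

(i)   a cytosine with a significant methylation call, sufficient depth
      and a minimum between-group level difference seeds a window;
(ii)  downstream cytosines satisfying the same cutoffs within a maximum
      distance D of the seed join it, requiring a minimum number of data
      points and tolerating a bounded number of unmapped cytosines;
(iii) per-cytosine methylation levels are compared between groups with a
      Wilcoxon signed-rank test (two groups, paired on group means per
      cytosine) or a Kruskal-Wallis test (more groups);
(iv)  the next window is seeded at the first call at or beyond the
      previous seed plus D/2, and the walk repeats.

Candidate windows are then multiple-testing corrected, thresholded and
merged into consolidated regions (Fisher-combined p-values).  Large
partially methylated domains, which are differential almost by
definition against pluripotent methylomes, can be located separately
(:func:`find_pmds`) and excluded from the window walk.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import Interval, IntervalSet
from .methstore import MethylomeStore, adjust_pvalues_bh

logger = logging.getLogger(__name__)


@dataclass
class DmrParams:
    """Cutoffs controlling seeding, window growth and testing.

    min_depth and max_q define a usable methylation call; min_diff is the
    smallest absolute between-group difference of mean levels a cytosine
    must show to seed or join a window; max_dist is the window span D in
    bp; min_points / max_missing bound the data points required and the
    unmapped cytosines tolerated per window.
    """

    min_depth: int = 5
    min_diff: float = 0.25
    max_dist: int = 1000
    min_points: int = 5
    max_missing: int = 2
    test: str = "wilcoxon"
    context: str = "CG"
    max_q: float = 0.05
    seed_must_qualify: bool = True

    def __post_init__(self) -> None:
        if self.max_dist <= 0:
            raise ValueError("max_dist must be positive")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        if not 0.0 <= self.min_diff <= 1.0:
            raise ValueError("min_diff must be in [0, 1]")
        if self.test not in ("wilcoxon", "kruskal"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class DmrCandidate:
    chrom: str
    start: int  # 0-based half-open, spanning first..last tested C
    end: int
    n_cytosines: int
    group_means: dict
    diff: float  # mean(group 1) - mean(group 2)
    pvalue: float

    @property
    def direction(self) -> str:
        return "hyper" if self.diff > 0 else "hypo"


@dataclass
class DmrRegion:
    chrom: str
    start: int
    end: int
    direction: str
    pvalue: float  # Fisher-combined over merged members
    qvalue: float  # min of member BH q-values
    n_merged: int


@dataclass
class PmdRegion:
    chrom: str
    start: int
    end: int
    mean_level: float
    n_sites: int


# ---------------------------------------------------------------------------
# window walker

def walk_windows(
    eligible: Sequence[int],
    call_positions: Sequence[int],
    max_dist: int,
    min_points: int,
    missing_at: Optional[Mapping[int, int]] = None,
    max_missing: int = 0,
    seed_must_qualify: bool = True,
) -> list[tuple[int, ...]]:
    """Enumerate tested windows over sorted cytosine positions.

    ``eligible`` are positions passing all seed/member cutoffs;
    ``call_positions`` is the superset of positions with a methylation
    call, used for re-seeding when ``seed_must_qualify`` is False.
    ``missing_at[pos]`` counts unmapped sample values at that position.
    Returns the member-position tuple of every window that satisfied
    min_points and max_missing.
    """
    eligible = sorted(eligible)
    seeds = eligible if seed_must_qualify else sorted(call_positions)
    missing_at = missing_at or {}
    windows: list[tuple[int, ...]] = []
    if not seeds:
        return windows
    seed = seeds[0]
    epos = np.asarray(eligible, dtype=np.int64)
    while True:
        lo = np.searchsorted(epos, seed, side="left")
        hi = np.searchsorted(epos, seed + max_dist, side="right")
        members = tuple(int(p) for p in epos[lo:hi])
        if len(members) >= min_points:
            missing = sum(missing_at.get(p, 0) for p in members)
            if missing <= max_missing:
                windows.append(members)
        nxt = seed + max_dist // 2
        advanced = False
        for p in seeds:
            if p >= nxt and p > seed:
                seed = p
                advanced = True
                break
        if not advanced:
            break
    return windows


# ---------------------------------------------------------------------------
# per-chromosome data assembly

def _chrom_matrix(
    stores: Sequence[MethylomeStore],
    chrom: str,
    context: str,
    uncovered: Mapping[str, IntervalSet],
):
    """Union position vector plus per-sample level/depth/q arrays.

    Level is NaN where the sample has no record AND the position falls in
    its uncovered (unsequenced) set; 0 where it simply has no supporting
    read (an unmethylated cytosine under the storage model).
    """
    per_sample: list[dict[int, tuple[float, int, float]]] = []
    all_pos: set[int] = set()
    for st in stores:
        recs = {}
        with_q = {}
        for rec in st.query(chrom, 0, 2**31 - 1, min_depth=1, max_q=1.0,
                            context_filter=[context], include_nocall=True):
            recs[rec.pos] = (rec.level, rec.depth, rec.qvalue)
        per_sample.append(recs)
        all_pos.update(recs)
    positions = np.array(sorted(all_pos), dtype=np.int64)
    n, m = len(stores), len(positions)
    levels = np.zeros((n, m))
    depths = np.zeros((n, m), dtype=np.int64)
    qvals = np.ones((n, m))
    for i, (st, recs) in enumerate(zip(stores, per_sample)):
        unc = uncovered.get(st.sample_id)
        for j, pos in enumerate(positions):
            hit = recs.get(int(pos))
            if hit is not None:
                levels[i, j], depths[i, j], qvals[i, j] = hit
            elif unc is not None and unc.contains_point(chrom, int(pos) - 1):
                levels[i, j] = np.nan
    return positions, levels, depths, qvals


def _test_window(levels_by_group: list[np.ndarray], test: str) -> Optional[float]:
    """p-value for one window, or None when there is nothing to test.

    ``levels_by_group[g]`` is an (n_samples_g, n_cytosines) level matrix.
    """
    if test == "wilcoxon":
        g1 = np.nanmean(levels_by_group[0], axis=0)
        g2 = np.nanmean(levels_by_group[1], axis=0)
        ok = ~(np.isnan(g1) | np.isnan(g2))
        d = g1[ok] - g2[ok]
        if d.size < 2 or np.all(d == 0):
            return None  # zero between-group variance
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                                     method="auto")
            except ValueError:
                return None
        return float(res.pvalue)
    # Kruskal-Wallis on all (cytosine, sample) levels pooled per group
    groups = [g[~np.isnan(g)] for g in (lv.ravel() for lv in levels_by_group)]
    groups = [g for g in groups if g.size]
    if len(groups) < 2:
        return None
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.kruskal(*groups)
    return float(res.pvalue)


def find_dmrs(
    stores_by_group: Mapping[str, Sequence[MethylomeStore]],
    params: Optional[DmrParams] = None,
    snp_mask: Optional[IntervalSet] = None,
    excluded_regions: Optional[IntervalSet] = None,
    uncovered: Optional[Mapping[str, IntervalSet]] = None,
    chroms: Optional[Sequence[str]] = None,
) -> list[DmrCandidate]:
    """Run the dynamic sliding-window scan over every chromosome.

    Two groups are tested with the Wilcoxon signed-rank test pairing the
    two group-mean levels at each cytosine; more groups with
    Kruskal-Wallis.  Cytosines under ``snp_mask`` or ``excluded_regions``
    never enter the analysis; ``uncovered`` maps sample_id to its
    unsequenced regions so unmapped cytosines can be told apart from
    unmethylated ones.
    """
    params = params or DmrParams()
    groups = list(stores_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if not stores_by_group[g]:
            raise ValueError(f"group {g!r} is empty")
    ids = [st.sample_id for g in groups for st in stores_by_group[g]]
    if len(set(ids)) != len(ids):
        raise ValueError("overlapping group membership: duplicate sample ids")
    uncovered = uncovered or {}
    test = params.test if len(groups) > 2 or params.test == "kruskal" else "wilcoxon"
    if len(groups) > 2:
        test = "kruskal"

    flat_stores = [st for g in groups for st in stores_by_group[g]]
    group_slices = []
    off = 0
    for g in groups:
        k = len(stores_by_group[g])
        group_slices.append(slice(off, off + k))
        off += k

    if chroms is None:
        seen: set[str] = set()
        for st in flat_stores:
            seen.update(st.chromosomes())
        chroms = sorted(seen)

    candidates: list[DmrCandidate] = []
    for chrom in chroms:
        positions, levels, depths, qvals = _chrom_matrix(
            flat_stores, chrom, params.context, uncovered
        )
        if positions.size == 0:
            continue
        masked = np.zeros(positions.size, dtype=bool)
        for ivset in (snp_mask, excluded_regions):
            if ivset is not None:
                for j, pos in enumerate(positions):
                    if ivset.contains_point(chrom, int(pos) - 1):
                        masked[j] = True
        keep = ~masked
        positions, levels, depths, qvals = (
            positions[keep], levels[:, keep], depths[:, keep], qvals[:, keep]
        )
        if positions.size == 0:
            continue

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            group_means = np.vstack(
                [np.nanmean(levels[sl], axis=0) for sl in group_slices]
            )
        # a usable methylation call in at least one sample
        called = np.any((qvals >= 0) & (qvals <= params.max_q) & (depths >= params.min_depth), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spread = np.nanmax(group_means, axis=0) - np.nanmin(group_means, axis=0)
        spread = np.where(np.isnan(spread), 0.0, spread)
        eligible_mask = called & (spread >= params.min_diff)
        eligible = positions[eligible_mask]
        calls = positions[called]
        missing_at = {
            int(p): int(np.count_nonzero(np.isnan(levels[:, j])))
            for j, p in enumerate(positions)
        }
        windows = walk_windows(
            eligible, calls, params.max_dist, params.min_points,
            missing_at, params.max_missing, params.seed_must_qualify,
        )
        pos_index = {int(p): j for j, p in enumerate(positions)}
        for members in windows:
            idx = [pos_index[p] for p in members]
            by_group = [levels[sl][:, idx] for sl in group_slices]
            p = _test_window(by_group, test)
            if p is None:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gmeans = {
                    g: float(np.nanmean(np.nanmean(by_group[k], axis=0)))
                    for k, g in enumerate(groups)
                }
            diff = gmeans[groups[0]] - gmeans[groups[1]]
            candidates.append(DmrCandidate(
                chrom=chrom, start=int(members[0]) - 1, end=int(members[-1]),
                n_cytosines=len(members), group_means=gmeans,
                diff=diff, pvalue=p,
            ))
    return candidates


def find_dmrs_regions(
    stores_by_group: Mapping[str, Sequence[MethylomeStore]],
    rois: IntervalSet,
    params: Optional[DmrParams] = None,
) -> list[DmrCandidate]:
    """One test per region on per-sample mean levels (useful for sparse,
    unevenly spread non-CpG methylation).

    Regions where any sample has fewer than ``min_points`` informative
    cytosines are skipped and logged.  Two equal-sized groups are tested
    with a Wilcoxon signed-rank on paired sample means; otherwise
    Kruskal-Wallis on the sample means pooled per group.
    """
    params = params or DmrParams()
    groups = list(stores_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(rois) == 0:
        raise ValueError("empty ROI set")
    candidates: list[DmrCandidate] = []
    for roi in rois:
        sample_means: dict[str, list[float]] = {}
        skip = False
        for g in groups:
            means = []
            for st in stores_by_group[g]:
                recs = st.query(roi.chrom, roi.start, roi.end,
                                min_depth=params.min_depth, max_q=1.0,
                                context_filter=[params.context], include_nocall=True)
                if len(recs) < params.min_points:
                    logger.info("ROI %s:%d-%d skipped: %s has %d < %d informative Cs",
                                roi.chrom, roi.start, roi.end, st.sample_id,
                                len(recs), params.min_points)
                    skip = True
                    break
                means.append(float(np.mean([r.level for r in recs])))
            if skip:
                break
            sample_means[g] = means
        if skip:
            continue
        if len(groups) == 2 and params.test == "wilcoxon":
            a, b = sample_means[groups[0]], sample_means[groups[1]]
            if len(a) != len(b):
                raise ValueError("paired Wilcoxon requires equal group sizes")
            d = np.array(a) - np.array(b)
            if np.all(d == 0):
                continue  # zero between-group variance
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.wilcoxon(d, zero_method="wilcox", correction=True,
                                         method="auto").pvalue)
        else:
            pooled = [np.asarray(sample_means[g]) for g in groups]
            flat = np.concatenate(pooled)
            if np.all(flat == flat[0]):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.kruskal(*pooled).pvalue)
        gmeans = {g: float(np.mean(sample_means[g])) for g in groups}
        candidates.append(DmrCandidate(
            chrom=roi.chrom, start=roi.start, end=roi.end,
            n_cytosines=params.min_points, group_means=gmeans,
            diff=gmeans[groups[0]] - gmeans[groups[1]], pvalue=p,
        ))
    return candidates


# ---------------------------------------------------------------------------
# consolidation

def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's method: survival of chi2 with 2k df at -2*sum(log p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to smallest positive float")
        p = np.maximum(p, np.nextafter(0.0, 1.0))
    statval = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(statval, 2 * p.size))


def consolidate_dmrs(
    candidates: Sequence[DmrCandidate],
    q_threshold: float = 0.05,
    merge_dist: int = 200,
) -> list[DmrRegion]:
    """BH-correct candidate p-values, keep survivors and merge neighbours.

    Same-direction significant candidates whose gap is below
    ``merge_dist`` (overlapping ones always) are merged; the merged
    region reports the Fisher-combined p of its members and the minimum
    member q-value.
    """
    if not candidates:
        return []
    qvals = adjust_pvalues_bh([c.pvalue for c in candidates])
    keep = [(c, q) for c, q in zip(candidates, qvals) if q <= q_threshold]
    by_key: dict[tuple[str, str], list[tuple[DmrCandidate, float]]] = {}
    for c, q in keep:
        by_key.setdefault((c.chrom, c.direction), []).append((c, q))
    out: list[DmrRegion] = []
    for (chrom, direction), items in sorted(by_key.items()):
        items.sort(key=lambda cq: (cq[0].start, cq[0].end))
        cur: list[tuple[DmrCandidate, float]] = [items[0]]
        cur_end = items[0][0].end

        def flush(members: list[tuple[DmrCandidate, float]]) -> None:
            ps = [m[0].pvalue for m in members]
            out.append(DmrRegion(
                chrom=chrom,
                start=min(m[0].start for m in members),
                end=max(m[0].end for m in members),
                direction=direction,
                pvalue=fisher_combine(ps) if len(ps) > 1 else ps[0],
                qvalue=float(min(m[1] for m in members)),
                n_merged=len(members),
            ))

        for c, q in items[1:]:
            if c.start - cur_end < merge_dist:
                cur.append((c, q))
                cur_end = max(cur_end, c.end)
            else:
                flush(cur)
                cur = [(c, q)]
                cur_end = c.end
        flush(cur)
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def dmrs_to_bed(regions: Sequence[DmrRegion], path: str) -> None:
    """BED6+ export: name, -10*log10(q) score, direction, p, n_merged."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            score = -10.0 * math.log10(max(r.qvalue, 1e-300))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tDMR_{i}\t{score:.2f}\t"
                f"{'+' if r.direction == 'hyper' else '-'}\t{r.direction}\t"
                f"{r.pvalue:.6e}\t{r.n_merged}\n"
            )


# ---------------------------------------------------------------------------
# partially methylated domains

def find_pmds(
    store: MethylomeStore,
    window: int = 10_000,
    step: int = 5_000,
    level_bounds: tuple[float, float] = (0.2, 0.7),
    min_sites: int = 20,
    min_run: int = 20_000,
) -> list[PmdRegion]:
    """Locate large domains of intermediate (partial) CpG methylation.

    Windows of ``window`` bp advanced by ``step`` qualify when they hold
    at least ``min_sites`` CpG records with mean level in
    [lo, hi); qualifying windows are unioned and merged runs shorter than
    ``min_run`` dropped.
    """
    if window < step:
        raise ValueError("window must be >= step")
    lo, hi = level_bounds
    hits: list[Interval] = []
    per_chrom: dict[str, list] = {}
    for rec in store.fetch_all():
        if rec.context == "CG":
            per_chrom.setdefault(rec.chrom, []).append((rec.pos - 1, rec.level))
    for chrom, recs in per_chrom.items():
        pos = np.array([p for p, _ in recs])
        lev = np.array([l for _, l in recs])
        last = int(pos.max()) + 1
        for start in range(0, last, step):
            sel = (pos >= start) & (pos < start + window)
            n = int(np.count_nonzero(sel))
            if n >= min_sites and lo <= float(lev[sel].mean()) < hi:
                hits.append(Interval(chrom, start, min(start + window, last)))
    merged = IntervalSet(hits).union()
    out: list[PmdRegion] = []
    for iv in merged:
        if iv.length < min_run:
            continue
        recs = per_chrom.get(iv.chrom, [])
        inside = [l for p, l in recs if iv.start <= p < iv.end]
        out.append(PmdRegion(iv.chrom, iv.start, iv.end,
                             float(np.mean(inside)), len(inside)))
    return out
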