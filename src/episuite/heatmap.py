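"""Integrative multi-track heatmaps over regions of interest.

Rows are ROIs, columns are user-defined tracks (each split into a
chosen number of bins): interval presence/score tracks, alignment read
counts, binned absolute/relative methylation, externally supplied
region scores, and gene-model tracks rendered categorically
(exon=2, intron=1, none=0).  Each track can be normalized independently
(empirical-quantile or percentile-threshold), rows can be clustered
hierarchically on any subset of tracks, and per-ROI significance scores
can progressively dim non-significant cells in the rendering while the
underlying matrix stays available for downstream analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .intervals import Interval, IntervalSet

TRACK_KINDS = (
    "interval_presence", "interval_score", "alignment_counts",
    "methylation_absolute", "methylation_relative", "region_score", "gene_model",
)


@dataclass
class TrackSpec:
    """One heatmap column block: what to draw and how to scale it."""

    name: str
    kind: str
    source: object
    nbins: int = 1
    normalization: Optional[tuple] = None  # ("quantile",) or ("threshold", lo, hi)
    significance: Optional[Sequence[float]] = None  # per-ROI, for dimming
    cluster_with: bool = True

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.nbins < 1:
            raise ValueError("nbins must be >= 1")
        if self.normalization is not None:
            method = self.normalization[0]
            if method == "threshold":
                lo, hi = self.normalization[1], self.normalization[2]
                if not 0 <= lo < hi <= 100:
                    raise ValueError("threshold percentiles must satisfy 0 <= lo < hi <= 100")
            elif method != "quantile":
                raise ValueError(f"unknown normalization {method!r}")


@dataclass
class HeatmapMatrix:
    rois: IntervalSet
    values: np.ndarray  # nROI x sum(track nbins)
    column_map: list[tuple[str, int]]  # column -> (track name, bin index)
    tracks: list[TrackSpec]
    row_order: np.ndarray
    dim_weights: np.ndarray  # per-cell brightness in [0, 1]
    dendrogram: Optional[np.ndarray] = None  # scipy linkage matrix

    def track_columns(self, name: str) -> list[int]:
        return [i for i, (t, _) in enumerate(self.column_map) if t == name]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            header = ["chrom", "start", "end", "strand"] + [
                f"{t}:{b}" for t, b in self.column_map
            ]
            fh.write("\t".join(header) + "\n")
            for iv, row in zip(self.rois, self.values):
                vals = "\t".join("NA" if np.isnan(v) else repr(float(v)) for v in row)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand or '.'}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "HeatmapMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            column_map = []
            for col in header[4:]:
                t, b = col.rsplit(":", 1)
                column_map.append((t, int(b)))
            rois: list[Interval] = []
            rows: list[list[float]] = []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                rois.append(Interval(f[0], int(f[1]), int(f[2]),
                                     strand=None if f[3] == "." else f[3]))
                rows.append([math.nan if v == "NA" else float(v) for v in f[4:]])
        values = np.array(rows, dtype=float)
        return cls(
            rois=IntervalSet(rois), values=values, column_map=column_map,
            tracks=[], row_order=np.arange(values.shape[0]),
            dim_weights=np.ones_like(values),
        )


def _bin_values_for_track(rois: IntervalSet, track: TrackSpec) -> np.ndarray:
    from .profiles import RegionProfile, bin_edges

    n = len(rois)
    vals = np.zeros((n, track.nbins), dtype=float)

    if track.kind in ("interval_presence", "interval_score"):
        src: IntervalSet = track.source
        for r, roi in enumerate(rois):
            edges = bin_edges(roi.start, roi.end, track.nbins)
            for b, (bs, be) in enumerate(edges):
                hits = src.overlapping(roi.chrom, bs, be)
                if track.kind == "interval_presence":
                    vals[r, b] = 1.0 if hits else 0.0
                else:
                    scores = [h.score for h in hits if h.score is not None]
                    vals[r, b] = max(scores) if scores else np.nan
            if roi.strand == "-":
                vals[r] = vals[r, ::-1]

    elif track.kind == "alignment_counts":
        from .regioncounts import region_counts

        sc = region_counts(track.source, rois, mode="binned", nbins=track.nbins,
                           norm_lib=True, norm_len=True)
        vals = np.vstack([np.atleast_1d(v) for v in sc.scores])

    elif track.kind in ("methylation_absolute", "methylation_relative"):
        prof: RegionProfile = track.source
        if len(prof.rois) != n or prof.nbins != track.nbins:
            raise ValueError(
                f"track {track.name!r}: profile dimensions do not match the heatmap ROIs"
            )
        vals = (prof.abs_meth if track.kind == "methylation_absolute"
                else prof.rel_meth).astype(float).copy()

    elif track.kind == "region_score":
        scores = np.asarray(track.source, dtype=float)
        if scores.shape[0] != n:
            raise ValueError(f"track {track.name!r}: one score per ROI required")
        vals = np.repeat(scores.reshape(-1, 1), track.nbins, axis=1)

    elif track.kind == "gene_model":
        exons: list[Interval] = []
        spans: list[Interval] = []
        for gene in track.source:
            for tx in gene.transcripts:
                spans.append(Interval(tx.chrom, tx.start, tx.end))
                for es, ee in tx.exons:
                    exons.append(Interval(tx.chrom, es, ee))
        exon_set, span_set = IntervalSet(exons), IntervalSet(spans)
        for r, roi in enumerate(rois):
            edges = bin_edges(roi.start, roi.end, track.nbins)
            for b, (bs, be) in enumerate(edges):
                if exon_set.overlapping(roi.chrom, bs, be):
                    vals[r, b] = 2.0
                elif span_set.overlapping(roi.chrom, bs, be):
                    vals[r, b] = 1.0
            if roi.strand == "-":
                vals[r] = vals[r, ::-1]

    return vals


def normalize_track(values: np.ndarray, method: str, *params: float) -> np.ndarray:
    """Normalize one track block to [0, 1].

    quantile: each value becomes its empirical quantile rank
    (rank - 0.5)/n with ties averaged, so a constant block maps to 0.5.
    threshold(lo, hi): clip at the given percentiles, then min-max
    rescale.  NaNs are excluded from the statistics and preserved.
    """
    from scipy.stats import rankdata

    out = np.array(values, dtype=float)
    mask = ~np.isnan(out)
    flat = out[mask]
    if flat.size == 0:
        return out
    if method == "quantile":
        ranks = rankdata(flat, method="average")
        out[mask] = (ranks - 0.5) / flat.size
    elif method == "threshold":
        lo_pct, hi_pct = params
        lo = np.percentile(flat, lo_pct)
        hi = np.percentile(flat, hi_pct)
        clipped = np.clip(flat, lo, hi)
        if hi > lo:
            out[mask] = (clipped - lo) / (hi - lo)
        else:
            out[mask] = 0.5
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return out


def dim_weight(sig: float, sig_full: float = 0.01) -> float:
    """Brightness multiplier from a significance score (p-like, in (0, 1]).

    Full brightness at sig <= sig_full, fading linearly in -log10 space
    down to 0 at sig = 1.
    """
    if sig <= 0:
        return 1.0
    w = math.log10(sig) / math.log10(sig_full)
    return min(max(w, 0.0), 1.0)


def build_heatmap_matrix(rois: IntervalSet, tracks: Sequence[TrackSpec]) -> HeatmapMatrix:
    """Assemble the ROI x binned-track matrix.

    Tracks are evaluated independently and concatenated in the given
    order; per-track normalization is applied after assembly; per-ROI
    significance scores become per-cell dim weights over that track's
    columns.
    """
    if len(rois) == 0:
        raise ValueError("empty ROI set")
    names = [t.name for t in tracks]
    if len(set(names)) != len(names):
        raise ValueError("track names must be unique")
    blocks: list[np.ndarray] = []
    column_map: list[tuple[str, int]] = []
    weights: list[np.ndarray] = []
    for track in tracks:
        if track.source is None:
            raise ValueError(f"track {track.name!r}: source missing")
        block = _bin_values_for_track(rois, track)
        if track.normalization is not None:
            block = normalize_track(block, track.normalization[0], *track.normalization[1:])
        w = np.ones_like(block)
        if track.significance is not None:
            sig = np.asarray(track.significance, dtype=float)
            if sig.shape[0] != len(rois):
                raise ValueError(f"track {track.name!r}: one significance score per ROI required")
            w *= np.array([[dim_weight(s)] * track.nbins for s in sig])
        blocks.append(block)
        weights.append(w)
        column_map.extend((track.name, b) for b in range(track.nbins))
    values = np.hstack(blocks)
    return HeatmapMatrix(
        rois=rois, values=values, column_map=column_map, tracks=list(tracks),
        row_order=np.arange(len(rois)), dim_weights=np.hstack(weights),
    )


def cluster_rows(
    matrix: HeatmapMatrix,
    track_subset: Optional[Sequence[str]] = None,
    method: str = "complete",
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchically cluster rows on selected tracks; sets row_order.

    Missing values in the selected blocks are imputed as 0 with a
    warning.  Returns (row_order, linkage matrix).
    """
    from scipy.cluster.hierarchy import leaves_list, linkage

    if track_subset is None:
        track_subset = [t.name for t in matrix.tracks if t.cluster_with]
    if not track_subset:
        raise ValueError("empty track subset for clustering")
    cols = [i for name in track_subset for i in matrix.track_columns(name)]
    if not cols:
        raise ValueError(f"no columns found for tracks {list(track_subset)}")
    data = matrix.values[:, cols].copy()
    if np.isnan(data).any():
        warnings.warn("missing values imputed as 0 for clustering")
        data = np.nan_to_num(data, nan=0.0)
    Z = linkage(data, method=method, metric=metric)
    order = leaves_list(Z)
    matrix.row_order = order
    matrix.dendrogram = Z
    return order, Z


def dendrogram_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick text for a scipy linkage matrix (branch lengths = heights)."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"


def render_heatmap(
    matrix: HeatmapMatrix,
    out_path: str,
    palette: str = "viridis",
    dimming: bool = False,
) -> None:
    """Render the (row-ordered) matrix to an image file.

    With ``dimming`` enabled, each cell's colour brightness is
    multiplied by its dim weight, so non-significant hits fade while
    significant ones keep full saturation.  Missing values render grey.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = matrix.values[matrix.row_order]
    wts = matrix.dim_weights[matrix.row_order]
    finite = vals[~np.isnan(vals)]
    lo = float(finite.min()) if finite.size else 0.0
    hi = float(finite.max()) if finite.size else 1.0
    span = (hi - lo) or 1.0
    cmap = plt.get_cmap(palette)
    rgba = cmap((vals - lo) / span)
    if dimming:
        rgba[..., :3] *= wts[..., None]
    rgba[np.isnan(vals)] = (0.6, 0.6, 0.6, 1.0)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * vals.shape[1]), max(3, 0.08 * vals.shape[0]))
    )
    ax.imshow(rgba, aspect="auto", interpolation="nearest")
    # column-block separators and labels per track
    xticks, xlabels = [], []
    pos = 0
    for track in matrix.tracks:
        xticks.append(pos + track.nbins / 2 - 0.5)
        xlabels.append(track.name)
        pos += track.nbins
        if pos < vals.shape[1]:
            ax.axvline(pos - 0.5, color="white", linewidth=0.8)
    if xticks:
        ax.set_xticks(xticks)
        ax.set_xticklabels(xlabels, rotation=45, ha="right", fontsize=8)
    ax.set_yticks([])
    ax.set_ylabel(f"{vals.shape[0]} regions")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
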