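"""Annotation of genomic regions against gene models and user tracks.

Regions are located with respect to transcript isoforms (promoter /
intragenic / intergenic, nearest TSS with signed distance) and promoters
are classified by CpG content with the classic sliding-window GC / CpG
observed-over-expected scoring: high-CpG promoters behave differently
from low-CpG ones under DNA methylation changes, so the class is a
standard covariate in methylome analyses.

Coordinate conventions: GTF input is 1-based inclusive and converted on
read; all in-memory spans are 0-based half-open, while ``tss``/``tes``
are 0-based positions of the first/last transcribed base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pyfaidx

from .intervals import Interval, IntervalSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty transcript span: {self}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    transcripts: list[Transcript]


def promoter_interval(tx: Transcript, up: int, down: int) -> Interval:
    """[TSS-up, TSS+down) in gene orientation, 0-based half-open."""
    if tx.strand == "+":
        s, e = tx.tss - up, tx.tss + down
    else:
        s, e = tx.tss - down + 1, tx.tss + up + 1
    return Interval(tx.chrom, max(s, 0), max(e, 0), name=tx.transcript_id,
                    strand=tx.strand)


def read_gtf(path: str) -> list[GeneModel]:
    """Load gene models from a GTF file via gffutils.

    Transcript spans come from ``transcript``/``mRNA`` records (inferred
    from exons by gffutils when absent); exon structure is attached when
    present.  GTF 1-based inclusive coordinates are converted to the
    package's 0-based half-open convention.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", verbose=False,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    tx_features = list(db.features_of_type("transcript")) + list(db.features_of_type("mRNA"))
    for feat in tx_features:
        tx_id = feat.attributes.get("transcript_id", [feat.id])[0]
        gene_id = feat.attributes.get("gene_id", [tx_id])[0]
        symbol = feat.attributes.get("gene_name", [gene_id])[0]
        exon_list = tuple(sorted(
            (e.start - 1, e.end) for e in db.children(feat, featuretype="exon")
        ))
        tx = Transcript(tx_id, feat.seqid, feat.strand, feat.start - 1, feat.end,
                        exon_list)
        genes.setdefault(gene_id, GeneModel(gene_id, symbol, [])).transcripts.append(tx)
    out = list(genes.values())
    for g in out:
        g.transcripts.sort(key=lambda t: (t.start, t.transcript_id))
    out.sort(key=lambda g: (g.transcripts[0].chrom, g.transcripts[0].start))
    return out


@dataclass
class AnnotatedRegion:
    roi: Interval
    nearest_tss: str
    tss_distance: int  # signed, in gene orientation: negative = upstream
    location: str  # promoter | intragenic | intergenic
    transcript_ids: list[str]
    gene_ids: list[str]
    symbols: list[str]
    extra: dict = field(default_factory=dict)  # track -> (bool, [names])


def annotate_regions(
    rois: IntervalSet,
    gene_models: Sequence[GeneModel],
    promoter_def: tuple[int, int] = (2000, 1000),
    extra_tracks: Optional[Mapping[str, IntervalSet]] = None,
) -> list[AnnotatedRegion]:
    """Annotate every region with its nearest TSS and genomic location.

    Distance is measured from the ROI midpoint to the TSS, signed in
    gene orientation.  A region is a promoter if it overlaps any
    isoform's [TSS-up, TSS+down) window, else intragenic if it overlaps
    any transcript span, else intergenic; all overlapping isoforms are
    reported.  ``extra_tracks`` adds per-track overlap flags and names.
    """
    if not gene_models:
        raise ValueError("empty gene model set")
    up, down = promoter_def
    txs = [tx for g in gene_models for tx in g.transcripts]
    tx_gene = {tx.transcript_id: g for g in gene_models for tx in g.transcripts}
    promoters = IntervalSet([promoter_interval(tx, up, down) for tx in txs])
    tx_spans = IntervalSet([
        Interval(tx.chrom, tx.start, tx.end, name=tx.transcript_id, strand=tx.strand)
        for tx in txs
    ])
    extra_tracks = extra_tracks or {}

    out: list[AnnotatedRegion] = []
    for roi in rois:
        mid = roi.midpoint
        best: Optional[tuple[float, str, int]] = None
        for tx in txs:
            if tx.chrom != roi.chrom:
                continue
            d = mid - tx.tss if tx.strand == "+" else tx.tss - mid
            key = (abs(d), tx.transcript_id)
            if best is None or key < (best[0], best[1]):
                best = (abs(d), tx.transcript_id, int(round(d)))
        if best is None:  # no gene on this chromosome: fall back to any TSS
            tx = min(txs, key=lambda t: t.transcript_id)
            best = (float("inf"), tx.transcript_id,
                    int(round(mid - tx.tss if tx.strand == "+" else tx.tss - mid)))
        prom_hits = promoters.overlapping(roi.chrom, roi.start, roi.end)
        span_hits = tx_spans.overlapping(roi.chrom, roi.start, roi.end)
        if prom_hits:
            location = "promoter"
        elif span_hits:
            location = "intragenic"
        else:
            location = "intergenic"
        hit_tx = sorted({iv.name for iv in prom_hits} | {iv.name for iv in span_hits})
        hit_genes = sorted({tx_gene[t].gene_id for t in hit_tx})
        hit_symbols = sorted({tx_gene[t].symbol for t in hit_tx})
        extra = {}
        for name, track in extra_tracks.items():
            hits = track.overlapping(roi.chrom, roi.start, roi.end)
            extra[name] = (bool(hits), sorted({h.name for h in hits if h.name}))
        out.append(AnnotatedRegion(
            roi=roi, nearest_tss=best[1], tss_distance=best[2], location=location,
            transcript_ids=hit_tx, gene_ids=hit_genes, symbols=hit_symbols,
            extra=extra,
        ))
    return out


def annotation_to_tsv(annotations: Sequence[AnnotatedRegion], path: str) -> None:
    extra_names = sorted({k for a in annotations for k in a.extra})
    with open(path, "w") as fh:
        cols = ["chrom", "start", "end", "nearest_tss", "tss_distance", "location",
                "transcript_ids", "gene_ids", "symbols"] + extra_names
        fh.write("\t".join(cols) + "\n")
        for a in annotations:
            row = [a.roi.chrom, str(a.roi.start), str(a.roi.end), a.nearest_tss,
                   str(a.tss_distance), a.location,
                   ",".join(a.transcript_ids) or ".",
                   ",".join(a.gene_ids) or ".", ",".join(a.symbols) or "."]
            for name in extra_names:
                flag, names = a.extra.get(name, (False, []))
                row.append(f"{int(flag)}:{','.join(names) or '.'}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# promoter CpG-content classification

@dataclass
class PromoterClassLabel:
    promoter: Interval
    cls: Optional[str]  # high | intermediate | low | None (all-N sequence)
    best_window: tuple[float, float]  # (gc_fraction, cpg_oe) of top-scoring window


def _window_scores(seq: str) -> tuple[float, float, float]:
    """(gc_fraction, cpg_oe, n_fraction) for one window sequence."""
    n_len = len(seq)
    c = seq.count("C")
    g = seq.count("G")
    cpg = seq.count("CG")
    n = seq.count("N")
    gc = (c + g) / n_len
    oe = (cpg * n_len) / (c * g) if c > 0 and g > 0 else 0.0
    return gc, oe, n / n_len


def promoter_class(
    genome: "pyfaidx.Fasta | str",
    promoters: IntervalSet,
    window: int = 500,
    step: int = 5,
    gc_high: float = 0.55,
    oe_high: float = 0.75,
    oe_low: float = 0.48,
) -> list[PromoterClassLabel]:
    """Classify promoters as high / intermediate / low CpG content.

    A sliding window of ``window`` bp advanced by ``step`` scores GC
    fraction and CpG observed/expected = (#CpG * window) / (#C * #G).
    High: any window with gc >= gc_high and o/e >= oe_high; low: no
    window reaches o/e >= oe_low; intermediate otherwise.  Windows that
    are mostly N are ignored; a promoter whose windows are all mostly N
    gets no class.
    """
    if isinstance(genome, str):
        genome = pyfaidx.Fasta(genome)
    out: list[PromoterClassLabel] = []
    for prom in promoters:
        if prom.length < window:
            raise ValueError(
                f"promoter {prom.chrom}:{prom.start}-{prom.end} shorter than window={window}"
            )
        seq = str(genome[prom.chrom][prom.start : prom.end]).upper()
        any_high = False
        any_mid = False
        best: Optional[tuple[float, float]] = None
        usable = 0
        for ws in range(0, len(seq) - window + 1, step):
            gc, oe, n_frac = _window_scores(seq[ws : ws + window])
            if n_frac > 0.5:
                continue
            usable += 1
            if best is None or oe > best[1] or (oe == best[1] and gc > best[0]):
                best = (gc, oe)
            if gc >= gc_high and oe >= oe_high:
                any_high = True
            if oe >= oe_low:
                any_mid = True
        if usable == 0:
            logger.info("promoter %s:%d-%d is mostly N; class missing",
                        prom.chrom, prom.start, prom.end)
            out.append(PromoterClassLabel(prom, None, (float("nan"), float("nan"))))
            continue
        cls = "high" if any_high else ("intermediate" if any_mid else "low")
        out.append(PromoterClassLabel(prom, cls, best))
    return out
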