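"""Indexed base-resolution methylome storage and methylation calling.

A methylome is imported from a per-cytosine table (chrom, pos, strand,
context, #C, #T), statistically called with a binomial test against a
null that combines bisulfite non-conversion and sequencing error, and
stored as a bgzip-compressed, coordinate-indexed (tabix) TSV so that
whole-genome data can be queried by interval without loading it into
memory.  Only cytosines with at least one read supporting methylation
(#C >= 1) are retained: together with the uncovered-region track derived
from the alignment, this is enough to classify every genomic cytosine as
methylated, unmethylated or unmapped.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import Interval, IntervalSet

#: q-value written for stores that carry no binomial call (e.g. hmC levels).
NO_CALL_SENTINEL = -1.0

STORE_COLUMNS = ["chrom", "pos", "strand", "context", "c_reads", "t_reads", "pvalue", "qvalue"]
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class CytosineRecord:
    """One profiled cytosine with its read support and methylation call."""

    chrom: str
    pos: int  # 1-based position of the C
    strand: str
    context: str
    c_reads: int
    t_reads: int
    pvalue: float
    qvalue: float

    @property
    def depth(self) -> int:
        return self.c_reads + self.t_reads

    @property
    def level(self) -> float:
        """Methylation level #C/(#C + #T)."""
        return self.c_reads / self.depth


def binomial_mc_pvalue(c_reads: int, t_reads: int, p0: float) -> float:
    """One-sided binomial p-value for a methylation call.

    Under the null, every read shows a C with probability ``p0`` (the
    chance that an unmethylated cytosine escapes conversion or is
    mis-read); the p-value is P(X >= c_reads) for X ~ Binomial(depth, p0).
    """
    if c_reads < 0 or t_reads < 0:
        raise ValueError("read counts must be non-negative")
    n = c_reads + t_reads
    if n < 1:
        raise ValueError("zero total depth: no reads to test")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null probability p0 must be in (0, 1), got {p0}")
    # sf(k-1) = P(X >= k)
    return float(stats.binom.sf(c_reads - 1, n, p0))


def adjust_pvalues_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def derive_context(seq: str, idx: int, strand: str) -> Optional[str]:
    """Sequence context (CG/CHG/CHH) of the cytosine at ``idx`` in ``seq``.

    On the minus strand the cytosine appears as a G in the reference and
    the context is read leftwards on the complement.
    """
    seq = seq.upper()
    if strand == "+":
        if seq[idx] != "C":
            return None
        nxt = seq[idx + 1] if idx + 1 < len(seq) else "N"
        nxt2 = seq[idx + 2] if idx + 2 < len(seq) else "N"
        if nxt == "G":
            return "CG"
        if nxt2 == "G":
            return "CHG"
        return "CHH"
    if strand == "-":
        if seq[idx] != "G":
            return None
        prv = seq[idx - 1] if idx - 1 >= 0 else "N"
        prv2 = seq[idx - 2] if idx - 2 >= 0 else "N"
        if prv == "C":
            return "CG"
        if prv2 == "C":
            return "CHG"
        return "CHH"
    raise ValueError(f"strand must be + or -, got {strand!r}")


class MethylomeStore:
    """A disk-backed, tabix-indexed collection of :class:`CytosineRecord`.

    Parameters
    ----------
    path:
        bgzip-compressed TSV with a ``.tbi`` index next to it, plus a
        ``.meta.json`` sidecar holding sample metadata.
    """

    def __init__(self, path: str):
        self.path = str(path)
        if not os.path.exists(self.path):
            raise FileNotFoundError(self.path)
        if not os.path.exists(self.path + ".tbi"):
            raise FileNotFoundError(f"missing tabix index for {self.path}")
        meta_path = self.path + ".meta.json"
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                meta = json.load(fh)
        else:
            meta = {}
        self.sample_id: str = meta.get("sample_id", os.path.basename(self.path))
        self.conversion_rate: Optional[float] = meta.get("conversion_rate")
        self.error_rate: Optional[float] = meta.get("error_rate")
        self.genome_id: Optional[str] = meta.get("genome_id")
        self.n_records: Optional[int] = meta.get("n_records")

    # -- queries -----------------------------------------------------------

    def chromosomes(self) -> list[str]:
        with pysam.TabixFile(self.path) as tbx:
            return list(tbx.contigs)

    def _parse_line(self, line: str) -> CytosineRecord:
        f = line.split("\t")
        return CytosineRecord(
            chrom=f[0], pos=int(f[1]), strand=f[2], context=f[3],
            c_reads=int(f[4]), t_reads=int(f[5]),
            pvalue=float(f[6]), qvalue=float(f[7]),
        )

    def query(
        self,
        chrom: str,
        start: int,
        end: int,
        min_depth: int = 1,
        max_q: float = 1.0,
        context_filter: Optional[Sequence[str]] = None,
        include_nocall: bool = False,
    ) -> list[CytosineRecord]:
        """Records with 1-based pos in (start, end] (0-based half-open input).

        Filters on total depth, corrected q-value and sequence context.
        Records carrying the no-call sentinel q-value pass the ``max_q``
        filter only when ``include_nocall`` is set.
        """
        out: list[CytosineRecord] = []
        if end <= start:
            return out
        contexts = set(context_filter) if context_filter else None
        with pysam.TabixFile(self.path) as tbx:
            if chrom not in tbx.contigs:
                return out
            for line in tbx.fetch(chrom, start, end):
                rec = self._parse_line(line)
                if rec.depth < min_depth:
                    continue
                if rec.qvalue == NO_CALL_SENTINEL:
                    if not include_nocall:
                        continue
                elif rec.qvalue > max_q:
                    continue
                if contexts is not None and rec.context not in contexts:
                    continue
                out.append(rec)
        return out

    def fetch_all(self) -> Iterator[CytosineRecord]:
        """All records in store order (chromosome, position)."""
        with pysam.TabixFile(self.path) as tbx:
            for chrom in tbx.contigs:
                for line in tbx.fetch(chrom):
                    yield self._parse_line(line)


def _format_float(x: float) -> str:
    if x == NO_CALL_SENTINEL:
        return "-1"
    return format(x, ".6e")


def _write_store(
    df: pd.DataFrame,
    out_path: str,
    sample_id: str,
    conversion_rate: Optional[float],
    error_rate: Optional[float],
    genome_id: Optional[str],
) -> MethylomeStore:
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    tmp = out_path + ".tmp.tsv"
    with open(tmp, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.context}\t"
                f"{row.c_reads}\t{row.t_reads}\t"
                f"{_format_float(row.pvalue)}\t{_format_float(row.qvalue)}\n"
            )
    pysam.tabix_compress(tmp, out_path, force=True)
    os.remove(tmp)
    pysam.tabix_index(out_path, seq_col=0, start_col=1, end_col=1, force=True)
    meta = {
        "sample_id": sample_id,
        "conversion_rate": conversion_rate,
        "error_rate": error_rate,
        "genome_id": genome_id,
        "n_records": int(len(df)),
    }
    with open(out_path + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return MethylomeStore(out_path)


def import_methylation_table(
    path: str,
    sample_id: str,
    conversion_rate: float,
    error_rate: float,
    out_path: str,
    genome: Optional[str] = None,
    genome_id: Optional[str] = None,
) -> MethylomeStore:
    """Import a per-cytosine report, call methylation and build a store.

    The input TSV carries chrom, pos (1-based), strand, context, c_reads,
    t_reads; context may be "." or empty if ``genome`` (a FASTA path) is
    given to derive it.  Rows with c_reads = 0 are dropped; binomial
    p-values use p0 = (1 - conversion_rate) + error_rate, and q-values are
    BH-corrected across all retained cytosines of the sample.
    """
    p0 = (1.0 - conversion_rate) + error_rate
    if p0 >= 1.0:
        raise ValueError(f"null probability p0 = {p0} >= 1; check conversion/error rates")
    if p0 <= 0.0:
        raise ValueError("null probability p0 must be positive; use error_rate > 0 or conversion_rate < 1")

    fasta = None
    _seq_cache: dict[str, str] = {}
    if genome is not None:
        import pyfaidx

        fasta = pyfaidx.Fasta(genome)

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                chrom, pos, strand = f[0], int(f[1]), f[2]
                context = f[3] if len(f) > 3 else "."
                c_reads, t_reads = int(f[-2]), int(f[-1])
                if strand not in "+-":
                    raise ValueError(f"bad strand {strand!r}")
                if pos < 1 or c_reads < 0 or t_reads < 0:
                    raise ValueError("negative count or non-positive position")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from None
            if c_reads == 0:
                continue  # inclusion rule: keep only Cs with read support
            if context in (".", "", "NA"):
                if fasta is None:
                    raise ValueError(
                        f"{path}: line {lineno} has no context and no genome was provided"
                    )
                seq = _seq_cache.get(chrom)
                if seq is None:
                    seq = _seq_cache[chrom] = str(fasta[chrom][:])
                ctx = derive_context(seq, pos - 1, strand)
                if ctx is None:
                    raise ValueError(
                        f"{path}: line {lineno}: reference base at {chrom}:{pos} "
                        f"is not a cytosine on strand {strand}"
                    )
                context = ctx
            rows.append((chrom, pos, strand, context, c_reads, t_reads))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "c_reads", "t_reads"])
    if len(df):
        df["pvalue"] = [
            binomial_mc_pvalue(c, t, p0) for c, t in zip(df.c_reads, df.t_reads)
        ]
        df["qvalue"] = adjust_pvalues_bh(df.pvalue.to_numpy())
    else:
        df["pvalue"] = []
        df["qvalue"] = []
    return _write_store(df, out_path, sample_id, conversion_rate, error_rate,
                        genome_id or (genome and os.path.basename(genome)))


def parse_mlml(path: str, sample_id: str, out_path: str) -> MethylomeStore:
    """Build an hmC store from consistent-estimation (MLML-style) output.

    Expected columns: chrom, pos (1-based), strand, context, mc_level,
    hmc_level, depth.  The store's level reflects the hmC estimate
    (c_reads = round(hmc_level * depth)); positions with no hmC support
    are dropped, and p/q-values carry the no-call sentinel since no
    binomial test backs these estimates.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                chrom, pos, strand, context = f[0], int(f[1]), f[2], f[3]
                hmc_level = float(f[5])
                depth = int(f[6])
                if not 0.0 <= hmc_level <= 1.0 or depth < 0:
                    raise ValueError("hmC level outside [0,1] or negative depth")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from None
            c_reads = int(round(hmc_level * depth))
            if c_reads == 0:
                continue
            rows.append((chrom, pos, strand, context, c_reads, depth - c_reads,
                         NO_CALL_SENTINEL, NO_CALL_SENTINEL))
    df = pd.DataFrame(rows, columns=STORE_COLUMNS)
    return _write_store(df, out_path, sample_id, None, None, None)


def find_uncovered_regions(bam_path: str, min_gap: int = 1) -> IntervalSet:
    """Maximal zero-coverage intervals of length >= ``min_gap`` per chromosome.

    Coverage is computed from primary, mapped, non-duplicate alignments
    over every chromosome declared in the BAM header; intervals are
    0-based half-open.
    """
    out: list[Interval] = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(f"missing index for {bam_path}")
        for chrom, length in zip(bam.references, bam.lengths):
            covered = np.zeros(length + 1, dtype=np.int32)
            for read in bam.fetch(chrom):
                if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                    continue
                s = max(read.reference_start, 0)
                e = min(read.reference_end, length)
                if e > s:
                    covered[s] += 1
                    covered[e] -= 1
            depth = np.cumsum(covered[:-1])
            gap = depth == 0
            # run-length encode the zero-coverage mask
            edges = np.flatnonzero(np.diff(np.concatenate(([0], gap.view(np.int8), [0]))))
            for s, e in zip(edges[::2], edges[1::2]):
                if e - s >= min_gap:
                    out.append(Interval(chrom, int(s), int(e)))
    return IntervalSet(out)
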