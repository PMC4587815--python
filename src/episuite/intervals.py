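"""Lightweight genomic interval sets shared by all modules.

Coordinates are 0-based half-open throughout the in-memory API, matching
the BED convention.  Only on-disk cytosine positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"interval end < start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of genomic intervals with fast overlap queries.

    Construction preserves the input order (many operations report results
    per input region); ``union()`` returns a sorted, non-overlapping set.
    """

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals: list[Interval] = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            if iv.end > iv.start:  # IntervalTree rejects empty intervals
                tree.addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        tree = self._trees.get(chrom)
        if tree is None or end <= start:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def contains_point(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(pos, pos + 1))

    def union(self) -> "IntervalSet":
        """Sorted set with overlapping/adjacent same-chromosome runs merged."""
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        merged: list[Interval] = []
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    merged.append(Interval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            merged.append(Interval(chrom, cur_s, cur_e))
        return IntervalSet(merged)

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        ivs: list[Interval] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                name = f[3] if len(f) > 3 else None
                score = float(f[4]) if len(f) > 4 and f[4] != "." else None
                strand = f[5] if len(f) > 5 and f[5] in "+-" else None
                ivs.append(Interval(f[0], int(f[1]), int(f[2]), name, score, strand))
        return cls(ivs)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fields = [iv.chrom, str(iv.start), str(iv.end)]
                if iv.name is not None or iv.score is not None or iv.strand is not None:
                    fields.append(iv.name if iv.name is not None else ".")
                    fields.append(f"{iv.score:g}" if iv.score is not None else ".")
                    fields.append(iv.strand if iv.strand is not None else ".")
                fh.write("\t".join(fields) + "\n")
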