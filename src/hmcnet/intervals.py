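"""Genomic intervals, read sets, coverage tracks and the standard flat-file formats.

Everything downstream addresses the genome through :class:`GenomicInterval`
(0-based, half-open, BED convention).  1-based dialects are converted at the
parsing boundary and never appear internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "ReadSet",
    "CoverageTrack",
    "FormatError",
    "read_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "count_overlapping_reads",
]


class FormatError(ValueError):
    """A malformed record in a genomic flat file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """The midpoint base, ``start + length // 2``."""
        return self.start + self.length // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 if the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(self.start - other.end, other.start - self.end, 0)

    def shift(self, delta: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + delta, self.end + delta, self.strand)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class ReadSet:
    """A set of aligned reads held as per-chromosome sorted coordinate arrays.

    Supports O(log n) interval counting in two modes:

    - ``midpoint``: a read is counted in a window iff its midpoint base lies
      inside it, so each read lands in exactly one window of a tiling.
    - ``any_overlap``: a read is counted iff it shares >= 1 bp with the window.
    """

    def __init__(self, reads: Iterable[GenomicInterval] = ()):
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        n = 0
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
            n += 1
        self.total_reads = n
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._mids: Dict[str, np.ndarray] = {}
        for chrom, rs in by_chrom.items():
            starts = np.array([r.start for r in rs], dtype=np.int64)
            ends = np.array([r.end for r in rs], dtype=np.int64)
            mids = starts + (ends - starts) // 2
            self._starts[chrom] = np.sort(starts)
            self._ends[chrom] = np.sort(ends)
            self._mids[chrom] = np.sort(mids)

    @classmethod
    def from_arrays(cls, chrom_arrays: Dict[str, np.ndarray], read_len: int = 100) -> "ReadSet":
        """Build from per-chromosome arrays of read *start* positions.

        All reads get the same length; only starts/ends/midpoints matter for
        counting, so this is the fast path used by the synthetic generator.
        """
        rs = cls()
        n = 0
        for chrom, starts in chrom_arrays.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = starts + read_len
            mids = starts + read_len // 2
            rs._starts[chrom] = np.sort(starts)
            rs._ends[chrom] = np.sort(ends)
            rs._mids[chrom] = np.sort(mids)
            n += len(starts)
        rs.total_reads = n
        return rs

    def chroms(self) -> List[str]:
        return sorted(self._starts)

    def count(self, region: GenomicInterval, mode: str = "midpoint") -> int:
        if mode not in ("midpoint", "any_overlap"):
            raise ValueError(f"unknown mode {mode!r}")
        if region.chrom not in self._starts:
            return 0
        if mode == "midpoint":
            mids = self._mids[region.chrom]
            return int(
                np.searchsorted(mids, region.end, "left")
                - np.searchsorted(mids, region.start, "left")
            )
        starts = self._starts[region.chrom]
        ends = self._ends[region.chrom]
        n = len(starts)
        n_right = n - np.searchsorted(starts, region.end, "left")  # start >= end
        n_left = np.searchsorted(ends, region.start, "right")  # end <= start
        return int(n - n_right - n_left)

    def count_windows(self, chrom: str, starts: np.ndarray, win: int) -> np.ndarray:
        """Vectorized midpoint counting over many windows of equal width."""
        starts = np.asarray(starts, dtype=np.int64)
        if chrom not in self._mids:
            return np.zeros(len(starts), dtype=np.int64)
        mids = self._mids[chrom]
        lo = np.searchsorted(mids, starts, "left")
        hi = np.searchsorted(mids, starts + win, "left")
        return hi - lo

    def intervals(self) -> List[GenomicInterval]:
        """Reconstructed read intervals (sorted); lengths are start/end pairings
        by rank, which is exact when all reads share one length."""
        out = []
        for chrom in self.chroms():
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out


class CoverageTrack:
    """Piecewise-constant nonnegative coverage with bedGraph semantics.

    Positions outside every covered span have value 0.
    """

    def __init__(self):
        self._bounds: Dict[str, np.ndarray] = {}   # interval starts/ends merged
        self._values: Dict[str, np.ndarray] = {}
        self._cum: Dict[str, np.ndarray] = {}      # cumulative integral at bounds

    @classmethod
    def from_intervals(
        cls, data: Dict[str, Sequence]
    ) -> "CoverageTrack":
        """``data[chrom]`` is a sequence of ``(start, end, value)`` tuples,
        non-overlapping within a chromosome."""
        t = cls()
        for chrom, rows in data.items():
            rows = sorted(rows)
            prev_end = -1
            for s, e, v in rows:
                if v < 0:
                    raise ValueError("coverage values must be >= 0")
                if s >= e:
                    raise ValueError("empty coverage interval")
                if s < prev_end:
                    raise ValueError(f"overlapping coverage intervals on {chrom}")
                prev_end = e
            if not rows:
                continue
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=np.float64)
            t._bounds[chrom] = np.stack([starts, ends], axis=1).reshape(-1)
            t._values[chrom] = vals
            seg = vals * (ends - starts)
            t._cum[chrom] = np.concatenate([[0.0], np.cumsum(seg)])
        return t

    def chroms(self) -> List[str]:
        return sorted(self._bounds)

    @property
    def total_signal(self) -> float:
        return float(sum(c[-1] for c in self._cum.values())) if self._cum else 0.0

    def _integral_to(self, chrom: str, pos: int) -> float:
        """Integral of the track over [-inf, pos)."""
        bounds = self._bounds[chrom]
        vals = self._values[chrom]
        cum = self._cum[chrom]
        i = np.searchsorted(bounds, pos, "right")
        k = i // 2
        if i % 2 == 0:  # in a gap (or before/after everything)
            return float(cum[k])
        # inside interval k
        s = bounds[2 * k]
        return float(cum[k] + vals[k] * (pos - s))

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Integral of coverage over [start, end) (sum over bases of the value)."""
        if chrom not in self._bounds:
            return 0.0
        return self._integral_to(chrom, end) - self._integral_to(chrom, start)

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._bounds:
            return 0.0
        bounds = self._bounds[chrom]
        i = np.searchsorted(bounds, pos, "right")
        if i % 2 == 1:
            return float(self._values[chrom][i // 2])
        return 0.0

    def to_rows(self) -> List[tuple]:
        rows = []
        for chrom in self.chroms():
            b = self._bounds[chrom].reshape(-1, 2)
            for (s, e), v in zip(b, self._values[chrom]):
                rows.append((chrom, int(s), int(e), float(v)))
        return rows


# ---------------------------------------------------------------------------
# flat-file I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Read a (multi-record) FASTA into ``{name: uppercase sequence}``.

    Record names are the header token up to the first whitespace.  Duplicate
    headers are ambiguous and rejected.
    """
    genome: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicated FASTA header {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome and os.path.getsize(path) > 0:
        raise FormatError(f"no FASTA records parsed from {path}")
    return genome


_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path) -> List[GenomicInterval]:
    """Read BED3/BED6 into a list of intervals (0-based half-open)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_bedgraph(path) -> CoverageTrack:
    data: Dict[str, List[tuple]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad bedGraph row") from exc
            data.setdefault(fields[0], []).append((s, e, v))
    try:
        return CoverageTrack.from_intervals(data)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.to_rows():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def count_overlapping_reads(
    reads: ReadSet, region: GenomicInterval, mode: str = "midpoint"
) -> int:
    """Count reads assigned to ``region`` (see :class:`ReadSet` for modes)."""
    return reads.count(region, mode=mode)
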