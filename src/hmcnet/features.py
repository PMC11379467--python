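"""Feature extraction: one-hot DNA sequence and sliding-window epigenetic profiles.

A standardized 1 kb region is described by two modalities:

- the one-hot encoded forward-strand sequence, a ``(1000, 4)`` 0/1 matrix with
  channel order A, C, G, T and all-zero rows for ambiguous bases;
- one profile vector per epigenetic mark: normalized read counts in 1 kb
  windows sliding by 500 bp across the region extended by 10 kb on each side,
  41 windows under the defaults.  Replicates of a mark stack as rows,
  giving an ``(n_h, 41)`` matrix per mark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .intervals import CoverageTrack, GenomicInterval, ReadSet

__all__ = [
    "PEAK_LEN",
    "FLANK",
    "WIN",
    "STEP",
    "NORM_SCALE",
    "FeaturePair",
    "standardize_peak",
    "one_hot_encode",
    "gc_fraction",
    "extract_epimark_feature",
    "build_feature_pair",
    "kmer_features",
    "n_windows",
]

PEAK_LEN = 1000     # standardized peak width (bp)
FLANK = 10_000      # extension on each side for profile features (bp)
WIN = 1000          # profile window width (bp)
STEP = 500          # profile window stride (bp)
NORM_SCALE = 1e7    # depth normalization: counts per 10 million reads

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

Signal = Union[ReadSet, CoverageTrack]


@dataclass
class FeaturePair:
    """The joint model input for one region: sequence + per-mark profiles."""

    seq: np.ndarray                  # (peak_len, 4)
    marks: List[np.ndarray]          # one (n_h, W) matrix per mark, fixed order
    region: GenomicInterval
    out_of_bounds: bool = False      # any profile window clipped at a contig edge

    def __post_init__(self):
        widths = {m.shape[1] for m in self.marks}
        if len(widths) > 1:
            raise ValueError(f"marks disagree on window count: {widths}")


class PeakBoundaryWarning(UserWarning):
    """A peak was skipped because its standardized window leaves the contig."""


def n_windows(peak_len: int = PEAK_LEN, flank: int = FLANK, win: int = WIN,
              step: int = STEP) -> int:
    """Number of sliding windows covering the flanked region."""
    span = 2 * flank + peak_len
    num = span - win
    if num % step != 0:
        raise ValueError(
            f"window grid does not tile: (2*{flank}+{peak_len}-{win}) % {step} != 0"
        )
    return num // step + 1


def standardize_peak(
    p: GenomicInterval,
    peak_len: int = PEAK_LEN,
    chrom_size: Optional[int] = None,
) -> Optional[GenomicInterval]:
    """Re-center ``p`` into a fixed-width window of ``peak_len`` bp.

    The output extends ``peak_len/2`` on each side of the input's center base.
    Windows that would leave the contig are *skipped* (returns None with a
    warning), never truncated, so every retained region has identical shape.
    """
    if peak_len % 2 != 0:
        raise ValueError("peak_len must be even")
    half = peak_len // 2
    center = p.midpoint
    start, end = center - half, center + half
    if start < 0 or (chrom_size is not None and end > chrom_size):
        warnings.warn(
            f"peak {p} skipped: standardized window [{start},{end}) "
            "extends past contig bounds",
            PeakBoundaryWarning,
            stacklevel=2,
        )
        return None
    return GenomicInterval(p.chrom, start, end, p.strand)


def one_hot_encode(seq: str, expected_len: Optional[int] = None) -> np.ndarray:
    """One-hot encode a DNA string as an ``(L, 4)`` matrix, channels A/C/G/T.

    A -> [1,0,0,0], C -> [0,1,0,0], G -> [0,0,1,0], T -> [0,0,0,1]; any other
    character (N etc.) becomes an all-zero row.
    """
    if expected_len is not None and len(seq) != expected_len:
        raise ValueError(f"sequence length {len(seq)} != expected {expected_len}")
    idx = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for base, j in _BASE_INDEX.items():
        out[idx == ord(base), j] = 1.0
    return out


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def extract_epimark_feature(
    region: GenomicInterval,
    signal: Signal,
    flank: int = FLANK,
    win: int = WIN,
    step: int = STEP,
    norm_scale: Optional[float] = NORM_SCALE,
    mode: str = "midpoint",
    chrom_size: Optional[int] = None,
) -> np.ndarray:
    """Profile one mark around ``region``: depth-normalized counts in sliding
    windows covering ``region`` extended by ``flank`` on both sides.

    Window ``i`` spans ``[region.start - flank + i*step, ... + win)``; with the
    defaults this yields 41 windows and window index 20 is centered on the
    peak.  Windows that stick out of the contig contribute 0.  Normalization
    multiplies raw counts by ``norm_scale / total`` (counts per 10 million by
    default); pass ``norm_scale=None`` for raw counts.
    """
    W = n_windows(region.length, flank, win, step)
    starts = region.start - flank + step * np.arange(W, dtype=np.int64)
    if isinstance(signal, ReadSet):
        if mode == "midpoint":
            counts = signal.count_windows(region.chrom, starts, win).astype(np.float64)
        else:
            counts = np.array(
                [
                    signal.count(GenomicInterval(region.chrom, max(int(s), 0),
                                                 max(int(s), 0) + win), mode=mode)
                    if s + win > 0 else 0
                    for s in starts
                ],
                dtype=np.float64,
            )
        total = signal.total_reads
    elif isinstance(signal, CoverageTrack):
        counts = np.array(
            [signal.window_sum(region.chrom, int(s), int(s) + win) for s in starts],
            dtype=np.float64,
        )
        total = signal.total_signal
    else:
        raise TypeError(f"unsupported signal type {type(signal).__name__}")

    # zero out windows that leave the contig (counting already returns 0 for
    # the uncovered part; full zeroing keeps the contract crisp)
    oob = starts < 0
    if chrom_size is not None:
        oob |= starts + win > chrom_size
    counts[oob] = 0.0

    if norm_scale is not None and total > 0:
        counts = counts * (norm_scale / total)
    return counts


def build_feature_pair(
    region: GenomicInterval,
    genome: Dict[str, str],
    mark_signals: Dict[str, Sequence[Signal]],
    mark_order: Optional[Sequence[str]] = None,
    flank: int = FLANK,
    win: int = WIN,
    step: int = STEP,
    norm_scale: Optional[float] = NORM_SCALE,
    mode: str = "midpoint",
    replicate_collapse: bool = False,
) -> FeaturePair:
    """Assemble the full model input for one standardized region.

    ``mark_signals`` maps mark name -> list of replicate signals; each mark
    becomes an ``(n_h, W)`` matrix (rows = replicates), or ``(1, W)`` of the
    replicate mean when ``replicate_collapse`` is set.  ``mark_order`` pins the
    modality order across a dataset (defaults to sorted names).
    """
    if region.chrom not in genome:
        raise KeyError(f"chromosome {region.chrom!r} not in genome")
    seq = genome[region.chrom][region.start:region.end]
    if len(seq) != region.length:
        raise ValueError(f"region {region} extends past contig end")
    chrom_size = len(genome[region.chrom])
    if mark_order is None:
        mark_order = sorted(mark_signals)
    marks = []
    oob = region.start - flank < 0 or region.end + flank > chrom_size
    for name in mark_order:
        reps = [
            extract_epimark_feature(
                region, sig, flank=flank, win=win, step=step,
                norm_scale=norm_scale, mode=mode, chrom_size=chrom_size,
            )
            for sig in mark_signals[name]
        ]
        mat = np.stack(reps).astype(np.float32)
        if replicate_collapse and mat.shape[0] > 1:
            mat = mat.mean(axis=0, keepdims=True)
        marks.append(mat)
    return FeaturePair(
        seq=one_hot_encode(seq, expected_len=region.length),
        marks=marks,
        region=region,
        out_of_bounds=oob,
    )


def kmer_features(seq: str, k: int = 3) -> np.ndarray:
    """k-mer frequency vector over {A,C,G,T}^k in lexicographic order.

    Counts are divided by the number of *valid* windows (those containing only
    A/C/G/T); windows with ambiguous bases are excluded from numerator and
    denominator.  Length 4**k (64 for the 3-mer baseline).
    """
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    seq = seq.upper()
    counts = np.zeros(4 ** k, dtype=np.float64)
    valid = 0
    # map bases to digits; -1 marks ambiguity
    digits = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, j in _BASE_INDEX.items():
        digits[arr == ord(base)] = j
    powers = 4 ** np.arange(k - 1, -1, -1)
    for i in range(len(seq) - k + 1):
        window = digits[i:i + k]
        if (window < 0).any():
            continue
        counts[int((window * powers).sum())] += 1
        valid += 1
    if valid:
        counts /= valid
    return counts


def kmer_names(k: int = 3) -> List[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]
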