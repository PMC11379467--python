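"""Training-set construction: positives, GC-matched negatives, continuous
targets, differential labels and the cross-chromosomal split.

Positives are peak-caller hits at FDR < 0.05.  Negatives are background 1 kb
windows drawn near the positives (edge-to-edge gap <= 10 kb), GC-matched to
the positive set by decile-stratified sampling, one negative per positive.
Differential labels come from a consumed differential-analysis table:
FDR < 0.1 positive, FDR > 0.5 negative, the in-between dropped.  Splits are
by chromosome only: chr8/chr9 test, chr7 validation, the rest training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .features import PEAK_LEN, gc_fraction
from .intervals import GenomicInterval, ReadSet

__all__ = [
    "LabeledExample",
    "label_positives",
    "select_negatives",
    "make_continuous_targets",
    "label_dhmrs",
    "cross_chromosomal_split",
    "split_examples",
    "TEST_CHROMS",
    "VAL_CHROMS",
]

TEST_CHROMS = frozenset({"chr8", "chr9"})
VAL_CHROMS = frozenset({"chr7"})


@dataclass(frozen=True)
class LabeledExample:
    region: GenomicInterval
    label: float            # 0/1 for binary and diff tasks, log count otherwise
    task: str               # "binary" | "continuous" | "diff"

    def __post_init__(self):
        if self.task in ("binary", "diff") and self.label not in (0.0, 1.0):
            raise ValueError(f"{self.task} label must be 0 or 1, got {self.label}")
        if not np.isfinite(self.label):
            raise ValueError("label must be finite")


def _peaks_frame(peaks) -> pd.DataFrame:
    if isinstance(peaks, pd.DataFrame):
        return peaks
    raise TypeError("peaks must be a DataFrame with chrom/start/end + fdr columns")


def label_positives(
    peaks: pd.DataFrame, fdr_col: str = "fdr", alpha: float = 0.05
) -> List[LabeledExample]:
    """Keep peaks significant at ``fdr < alpha`` (strict) as label-1 examples.

    ``peaks`` is a DataFrame with ``chrom``, ``start``, ``end`` and the FDR
    column; rows are expected to be standardized already.
    """
    peaks = _peaks_frame(peaks)
    if fdr_col not in peaks.columns:
        raise KeyError(f"missing FDR column {fdr_col!r}")
    out = []
    for row in peaks.itertuples(index=False):
        if getattr(row, fdr_col) < alpha:
            region = GenomicInterval(row.chrom, int(row.start), int(row.end))
            out.append(LabeledExample(region, 1.0, "binary"))
    return out


class GCMatchWarning(UserWarning):
    """A GC bin had to borrow candidates from neighbouring bins."""


def select_negatives(
    positives: Sequence[GenomicInterval],
    genome: Dict[str, str],
    seed: int,
    max_dist: int = 10_000,
    gc_bins: int = 10,
    peak_len: int = PEAK_LEN,
    lattice: int = 100,
    exclude: Optional[Sequence[GenomicInterval]] = None,
) -> List[LabeledExample]:
    """Draw one GC-matched background window per positive.

    Candidates are ``peak_len`` windows on a ``lattice``-bp grid whose
    edge-to-edge gap to some positive is <= ``max_dist`` and which overlap no
    positive (nor any interval in ``exclude``, e.g. sub-threshold peaks).
    Sampling is stratified over ``gc_bins`` equal GC bins so the negative GC
    histogram equals the positive one; a bin short of candidates borrows from
    its nearest neighbouring bins with a warning, and errors only if the whole
    pool is exhausted.  Deterministic for a fixed seed.
    """
    if len(positives) == 0:
        raise ValueError("select_negatives requires a non-empty positive set")
    rng = np.random.default_rng(seed)

    blocked: Dict[str, List[Tuple[int, int]]] = {}
    for p in list(positives) + list(exclude or []):
        blocked.setdefault(p.chrom, []).append((p.start, p.end))
    blocked_arr = {
        c: (np.array(sorted(s for s, _ in v)), np.array([e for _, e in sorted(v)]))
        for c, v in blocked.items()
    }

    def overlaps_blocked(chrom: str, start: int, end: int) -> bool:
        starts, ends = blocked_arr[chrom]
        i = np.searchsorted(starts, end, "left")
        # any blocked interval with start < end and end > start?
        return bool((ends[:i] > start).any())

    # candidate windows, deduplicated on (chrom, start)
    seen: Set[Tuple[str, int]] = set()
    cand: List[GenomicInterval] = []
    for p in positives:
        chrom_len = len(genome[p.chrom])
        lo = p.start - max_dist - peak_len
        hi = p.end + max_dist
        s0 = max(0, -(-lo // lattice) * lattice)  # ceil to lattice
        for s in range(s0, min(hi, chrom_len - peak_len) + 1, lattice):
            key = (p.chrom, s)
            if key in seen:
                continue
            seen.add(key)
            if overlaps_blocked(p.chrom, s, s + peak_len):
                continue
            cand.append(GenomicInterval(p.chrom, s, s + peak_len))
    if not cand:
        raise ValueError("no candidate negatives found near the positives")
    cand.sort()

    edges = np.linspace(0.0, 1.0, gc_bins + 1)

    def gc_bin(iv: GenomicInterval) -> int:
        g = gc_fraction(genome[iv.chrom][iv.start:iv.end])
        return min(int(np.searchsorted(edges, g, "right")) - 1, gc_bins - 1)

    cand_by_bin: Dict[int, List[int]] = {b: [] for b in range(gc_bins)}
    for i, iv in enumerate(cand):
        cand_by_bin[gc_bin(iv)].append(i)

    need = np.zeros(gc_bins, dtype=int)
    for p in positives:
        need[gc_bin(p)] += 1

    chosen: List[int] = []
    taken = np.zeros(len(cand), dtype=bool)
    for b in range(gc_bins):
        if need[b] == 0:
            continue
        pool = [i for i in cand_by_bin[b] if not taken[i]]
        if len(pool) < need[b]:
            # widen: borrow from nearest bins outward
            for radius in range(1, gc_bins):
                for nb in (b - radius, b + radius):
                    if 0 <= nb < gc_bins:
                        pool.extend(i for i in cand_by_bin[nb] if not taken[i])
                if len(pool) >= need[b]:
                    break
            if len(pool) < need[b]:
                raise ValueError(
                    f"candidate pool exhausted for GC bin {b} "
                    f"({need[b]} needed, {len(pool)} available after widening)"
                )
            warnings.warn(
                f"GC bin {b} short of candidates; borrowed from neighbouring bins",
                GCMatchWarning,
                stacklevel=2,
            )
        pool = np.array(sorted(pool))
        pick = rng.choice(pool, size=need[b], replace=False)
        for i in pick:
            taken[i] = True
        chosen.extend(int(i) for i in pick)

    chosen.sort()
    return [LabeledExample(cand[i], 0.0, "binary") for i in chosen]


def make_continuous_targets(
    regions: Sequence[GenomicInterval],
    reads: ReadSet,
    norm_scale: Optional[float] = 1e7,
    mode: str = "midpoint",
) -> List[LabeledExample]:
    """Continuous targets: natural log of normalized read count plus one.

    ``target = log1p(count * norm_scale / total_reads)``, invariant to
    doubling counts and depth together.  ``norm_scale=None`` skips depth
    normalization.
    """
    out = []
    for r in regions:
        c = float(reads.count(r, mode=mode))
        if norm_scale is not None and reads.total_reads > 0:
            c *= norm_scale / reads.total_reads
        out.append(LabeledExample(r, float(np.log1p(c)), "continuous"))
    return out


def label_dhmrs(
    table: pd.DataFrame,
    pos_alpha: float = 0.1,
    neg_floor: float = 0.5,
    fdr_col: str = "fdr",
) -> List[LabeledExample]:
    """Differential labels from a consumed differential-analysis table.

    ``fdr < pos_alpha`` -> 1, ``fdr > neg_floor`` -> 0, anything in between is
    dropped as ambiguous.  ``table`` holds chrom/start/end + the FDR column.
    """
    if fdr_col not in table.columns:
        raise KeyError(f"missing FDR column {fdr_col!r}")
    bad = table[(table[fdr_col] < 0) | (table[fdr_col] > 1)]
    if len(bad):
        raise ValueError("FDR values must lie in [0, 1]")
    out = []
    for row in table.itertuples(index=False):
        fdr = getattr(row, fdr_col)
        if fdr < pos_alpha:
            lab = 1.0
        elif fdr > neg_floor:
            lab = 0.0
        else:
            continue
        out.append(
            LabeledExample(GenomicInterval(row.chrom, int(row.start), int(row.end)),
                           lab, "diff")
        )
    return out


def cross_chromosomal_split(
    examples: Sequence[LabeledExample],
    test_chroms: Iterable[str] = TEST_CHROMS,
    val_chroms: Iterable[str] = VAL_CHROMS,
) -> List[str]:
    """Assign each example to train/val/test purely by chromosome.

    Whole chromosomes are held out so no positional information leaks between
    sets: by default chr8+chr9 are the test set and chr7 the validation set.
    Returns one of ``{"train","val","test"}`` per example, aligned by index.
    """
    test_chroms, val_chroms = set(test_chroms), set(val_chroms)
    clash = test_chroms & val_chroms
    if clash:
        raise ValueError(f"test and validation chromosomes overlap: {sorted(clash)}")

    def assign(chrom: str) -> str:
        if chrom in test_chroms:
            return "test"
        if chrom in val_chroms:
            return "val"
        return "train"

    return [assign(ex.region.chrom) for ex in examples]


def split_examples(
    examples: Sequence[LabeledExample],
    test_chroms: Iterable[str] = TEST_CHROMS,
    val_chroms: Iterable[str] = VAL_CHROMS,
) -> Dict[str, List[int]]:
    """Index lists per split, a convenience wrapper over the assignment."""
    assignment = cross_chromosomal_split(examples, test_chroms, val_chroms)
    out: Dict[str, List[int]] = {"train": [], "val": [], "test": []}
    for i, s in enumerate(assignment):
        out[s].append(i)
    return out
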