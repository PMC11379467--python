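"""Applications of trained models: gene-expression surrogate, genome-wide
differential scanning, and SNP enrichment.

- *gene expression*: gene bodies are segmented into non-adjacent 1 kb windows
  (the last window padded downstream to full width), the continuous model
  predicts the 5hmC count of each window, and the back-transformed counts are
  summed per gene as a surrogate for expression.
- *differential scan*: the genome is tiled with non-overlapping 1 kb windows
  (partial terminal windows dropped); an epigenetics-only case/control model
  assigns each a probability of being differentially hydroxymethylated
  (DhMR), called at the 0.5 cutoff.
- *SNP enrichment*: noncoding positive SNPs are contrasted with 10:1 sampled
  noncoding controls in a 2x2 table of SNP class x region class; Fisher's
  exact test gives the odds ratio, 95% CI and p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .features import build_feature_pair
from .intervals import GenomicInterval
from .model import HmcResults

__all__ = [
    "GeneRecord",
    "DhmrCall",
    "EnrichmentTable",
    "segment_gene_body",
    "predict_gene_expression",
    "scan_genome_dhmr",
    "snp_enrichment",
    "summarize_feature_distribution",
    "FEATURE_PRIORITY",
]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    body: GenomicInterval
    observed_expression: Optional[float] = None

    def __post_init__(self):
        if self.observed_expression is not None and self.observed_expression < 0:
            raise ValueError("expression must be >= 0")


@dataclass(frozen=True)
class DhmrCall:
    window: GenomicInterval
    probability: float

    @property
    def call(self) -> str:
        return "DhMR" if self.probability > 0.5 else "non-DhMR"


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 contingency counts: SNP class (positive/negative control) by
    region class (DhMR / non-DhMR)."""

    a: int  # positive SNPs in DhMRs
    b: int  # positive SNPs in non-DhMRs
    c: int  # negative SNPs in DhMRs
    d: int  # negative SNPs in non-DhMRs

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    def odds_ratio(self, haldane: bool = True) -> float:
        a, b, c, d = self.a, self.b, self.c, self.d
        if haldane and 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


def segment_gene_body(g: GeneRecord, win: int = 1000) -> List[GenomicInterval]:
    """Non-overlapping ``win``-bp windows covering the gene body from its
    start; the last (or only) window is extended downstream to full width."""
    body = g.body
    n = -(-body.length // win)  # ceil
    out = []
    for i in range(n):
        s = body.start + i * win
        out.append(GenomicInterval(body.chrom, s, s + win, body.strand))
    return out


def predict_gene_expression(
    genes: Sequence[GeneRecord],
    results: HmcResults,
    genome: Dict[str, str],
    mark_signals: Dict[str, Sequence],
    win: int = 1000,
    mark_order: Optional[Sequence[str]] = None,
    batch_size: int = 256,
) -> Dict[str, float]:
    """Predicted expression per gene: the sum over its 1 kb windows of the
    back-transformed predicted 5hmC counts, ``sum(expm1(pred))``.

    The model predicts on the log1p scale used for training targets, so counts
    are recovered by ``expm1`` before aggregation.  Genes on chromosomes
    absent from the genome are skipped with a warning.
    """
    if results.spec.task != "continuous":
        raise ValueError("gene aggregation needs a continuous-task model")
    import warnings

    windows: List[GenomicInterval] = []
    owner: List[str] = []
    out: Dict[str, float] = {}
    for g in genes:
        if g.body.chrom not in genome:
            warnings.warn(f"gene {g.gene_id} on missing chromosome "
                          f"{g.body.chrom}; skipped", stacklevel=2)
            continue
        ws = segment_gene_body(g, win=win)
        if ws[-1].end > len(genome[g.body.chrom]):
            # padded window beyond contig end: zero-filled features downstream
            pass
        windows.extend(ws)
        owner.extend([g.gene_id] * len(ws))
        out[g.gene_id] = 0.0
    if not windows:
        return out
    pairs = [
        build_feature_pair(w, genome, mark_signals, mark_order=mark_order)
        if w.end <= len(genome[w.chrom])
        else build_feature_pair(
            GenomicInterval(w.chrom, len(genome[w.chrom]) - w.length,
                            len(genome[w.chrom])),
            genome, mark_signals, mark_order=mark_order)
        for w in windows
    ]
    preds = results.predict_pairs(pairs, batch_size=batch_size)
    counts = np.expm1(preds)
    for gene_id, c in zip(owner, counts):
        out[gene_id] += float(c)
    return out


def scan_genome_dhmr(
    results: HmcResults,
    genome: Dict[str, str],
    case_signals: Dict[str, Sequence],
    control_signals: Dict[str, Sequence],
    win: int = 1000,
    chroms: Optional[Sequence[str]] = None,
    mark_order: Optional[Sequence[str]] = None,
    batch_size: int = 512,
) -> List[DhmrCall]:
    """Tile each contig with non-overlapping ``win``-bp windows from position
    0 (terminal partial windows dropped) and score each with the differential
    model.  Case and control marks enter as separate modalities, case first.
    """
    if results.spec.modality != "epi_only":
        raise ValueError("the differential scan uses an epigenetics-only model")
    if mark_order is None:
        mark_order = sorted(case_signals)
    stacked = {f"case:{m}": case_signals[m] for m in mark_order}
    stacked.update({f"control:{m}": control_signals[m] for m in mark_order})
    order = [f"case:{m}" for m in mark_order] + [f"control:{m}" for m in mark_order]

    calls: List[DhmrCall] = []
    for chrom in (chroms if chroms is not None else sorted(genome)):
        n = len(genome[chrom]) // win
        pairs = []
        for i in range(n):
            w = GenomicInterval(chrom, i * win, (i + 1) * win)
            pairs.append(build_feature_pair(w, genome, stacked, mark_order=order))
        if not pairs:
            continue
        probs = results.predict_pairs(pairs, batch_size=batch_size)
        calls.extend(DhmrCall(p.region, float(pr)) for p, pr in zip(pairs, probs))
    return calls


def _membership(snps: Sequence[GenomicInterval],
                regions: Sequence[GenomicInterval]) -> np.ndarray:
    """Boolean per SNP: does its position fall in any region?"""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    arrs = {}
    for c, spans in by_chrom.items():
        spans.sort()
        arrs[c] = (np.array([s for s, _ in spans]), np.array([e for _, e in spans]))
    out = np.zeros(len(snps), dtype=bool)
    for i, s in enumerate(snps):
        if s.chrom not in arrs:
            continue
        starts, ends = arrs[s.chrom]
        j = np.searchsorted(starts, s.start, "right") - 1
        out[i] = j >= 0 and s.start < ends[j]
    return out


def snp_enrichment(
    pos_snps: Sequence[GenomicInterval],
    dhmrs: Sequence[GenomicInterval],
    non_dhmrs: Sequence[GenomicInterval],
    noncoding_mask: Sequence[GenomicInterval],
    seed: int,
    neg_ratio: int = 10,
) -> Tuple[EnrichmentTable, float, Tuple[float, float], float]:
    """Fisher's exact enrichment of positive SNPs in DhMR windows.

    Positive SNPs are first restricted to the noncoding mask.  Negative
    control SNPs are sampled uniformly from noncoding positions excluding the
    positive positions, at ``neg_ratio`` per positive, deterministically under
    ``seed``.  Returns the 2x2 table, the odds ratio (Haldane-corrected when a
    cell is empty), the Woolf 95% CI on the OR, and the two-sided Fisher p.
    """
    in_noncoding = _membership(pos_snps, noncoding_mask)
    pos = [s for s, keep in zip(pos_snps, in_noncoding) if keep]
    if not pos:
        raise ValueError("no positive SNPs remain after noncoding filtering")

    rng = np.random.default_rng(seed)
    mask = sorted(noncoding_mask)
    lens = np.array([iv.length for iv in mask], dtype=np.float64)
    taken = {(s.chrom, s.start) for s in pos}
    n_neg = neg_ratio * len(pos)
    neg: List[GenomicInterval] = []
    while len(neg) < n_neg:
        idx = rng.choice(len(mask), size=n_neg - len(neg), p=lens / lens.sum())
        offs = rng.random(len(idx))
        for j, u in zip(idx, offs):
            iv = mask[int(j)]
            p = iv.start + int(u * iv.length)
            if (iv.chrom, p) in taken:
                continue
            taken.add((iv.chrom, p))
            neg.append(GenomicInterval(iv.chrom, p, p + 1))
            if len(neg) == n_neg:
                break

    a = int(_membership(pos, dhmrs).sum())
    b = len(pos) - a
    c = int(_membership(neg, dhmrs).sum())
    d = len(neg) - c
    table = EnrichmentTable(a, b, c, d)
    odds = table.odds_ratio()
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    aa, bb, cc, dd = (x + 0.5 if 0 in (a, b, c, d) else x for x in (a, b, c, d))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (float(np.exp(np.log(odds) - 1.959963984540054 * se)),
          float(np.exp(np.log(odds) + 1.959963984540054 * se)))
    return table, float(odds), ci, float(p)


FEATURE_PRIORITY = [
    "Promoter", "5UTR", "Exon", "Intron", "3UTR", "Downstream", "Intergenic",
]


def summarize_feature_distribution(
    calls: Sequence[DhmrCall],
    annotations: Sequence[Tuple[GenomicInterval, str]],
) -> Dict[str, Dict[str, float]]:
    """Assign each call to the genomic feature class it overlaps most.

    Ties break by the fixed priority Promoter > 5UTR > Exon > Intron > 3UTR >
    Downstream > Intergenic; calls overlapping nothing are Intergenic.
    Returns counts and fractions per class.
    """
    rank = {cls: i for i, cls in enumerate(FEATURE_PRIORITY)}
    for _, cls in annotations:
        if cls not in rank:
            raise ValueError(f"unknown feature class {cls!r}")
    counts = {cls: 0 for cls in FEATURE_PRIORITY}
    for call in calls:
        best_cls, best_len = "Intergenic", 0
        for iv, cls in annotations:
            ov = call.window.overlap_length(iv)
            if ov > best_len or (ov == best_len and ov > 0
                                 and rank[cls] < rank[best_cls]):
                best_cls, best_len = cls, ov
        counts[best_cls] += 1
    total = max(len(calls), 1)
    return {
        cls: {"count": counts[cls], "fraction": counts[cls] / total}
        for cls in FEATURE_PRIORITY
    }
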