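"""Self-contained synthetic 5hmC datasets with planted, parameterized signal.

The generator emulates the statistical structure of an enrichment-sequencing
study so every other module is testable without downloads:

- an i.i.d. random genome (configurable GC) split into ``chr1..chrN``;
- 1 kb positive peaks, each carrying a planted sequence motif with a
  configurable insertion probability (the sequence-modality signal);
- per-mark read sets whose coverage shows a Gaussian enrichment bump either
  centered on the positives (enhancer-like, ``pos_up``) or on decoy sites
  between them (promoter-like, ``neg_up``) — the epigenetic-modality signal;
- 5hmC reads whose per-peak amplitude is gamma-distributed, so window counts
  are negative-binomial (gamma-Poisson) around the latent rate;
- genes whose expression is a noisy multiple of their gene-body 5hmC;
- a case/control pair of mark read sets with planted differential windows,
  plus the corresponding differential-analysis table (FDR column);
- positive SNPs enriched in the planted differential windows at configured
  odds, and the noncoding mask to sample controls from.

Everything is bit-exact reproducible from ``SynthConfig.seed``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ReadSet, write_bed
from .features import PEAK_LEN

__all__ = [
    "MarkProfile",
    "CountModel",
    "GeneModel",
    "DiffModel",
    "SnpModel",
    "SynthConfig",
    "SynthTruth",
    "SynthDataset",
    "generate_dataset",
    "generate_worked_micro_example",
]

READ_LEN = 100


@dataclass(frozen=True)
class MarkProfile:
    """One epigenetic mark: a Gaussian enrichment bump over a flat background.

    ``bump_height`` is the expected number of bump reads per anchored site and
    replicate; read midpoints fall Normal(center, ``bump_width``/2).
    ``baseline`` is background reads per kb.  ``noise_sd`` is the coefficient
    of variation of the per-site gamma amplitude (site-to-site variability).
    ``direction`` anchors bumps on positives (``pos_up``) or on decoy sites
    offset from them (``neg_up``).
    """

    name: str
    direction: str = "pos_up"
    bump_height: float = 25.0
    bump_width: float = 2000.0
    baseline: float = 15.0
    noise_sd: float = 0.5
    n_h: int = 1

    def __post_init__(self):
        if self.direction not in ("pos_up", "neg_up"):
            raise ValueError("direction must be pos_up or neg_up")
        if self.bump_height < 0 or self.baseline < 0 or self.noise_sd < 0:
            raise ValueError("heights/rates must be >= 0")


@dataclass(frozen=True)
class CountModel:
    """5hmC read generation: background rate (reads/kb), expected bump reads
    per peak, per-peak amplitude CV (gamma), and the bump spread (sd in bp)."""

    baseline_rate: float = 10.0
    signal_reads: float = 200.0
    amplitude_cv: float = 0.4
    bump_sd: float = 500.0
    subthreshold_scale: float = 0.3


@dataclass(frozen=True)
class GeneModel:
    """Genes with expression = alpha * gene-body 5hmC * lognormal noise."""

    n_genes: int = 300
    min_len: int = 2000
    max_len: int = 10000
    alpha: float = 1.0
    noise_sd: float = 0.3


@dataclass(frozen=True)
class DiffModel:
    """Case/control design: a fraction of peaks is differential, with the case
    bump scaled by ``effect``; the consumed differential table gets FDR < 0.1
    for planted windows, > 0.5 for the rest, and a small ambiguous fraction."""

    p_dhmr: float = 0.45
    effect: float = 2.5
    mark: MarkProfile = field(default_factory=lambda: MarkProfile(
        "acetyl_mark", "pos_up", bump_height=40.0, baseline=15.0, noise_sd=0.5))
    ambiguous_frac: float = 0.1


@dataclass(frozen=True)
class SnpModel:
    n_pos_snps: int = 400
    enrichment_odds: float = 4.0


@dataclass(frozen=True)
class SynthConfig:
    n_chroms: int = 10
    chrom_len: int = 3_000_000
    n_pos: int = 2000
    gc: float = 0.5
    motif: str = "TGACGTCA"
    motif_prob: float = 0.9
    cpg_boost: int = 35
    gc_skew: int = 25
    marks: Tuple[MarkProfile, ...] = (
        MarkProfile("enhancer_mark", "pos_up", bump_height=25.0,
                    baseline=15.0, noise_sd=0.5),
        MarkProfile("promoter_mark", "neg_up", bump_height=20.0,
                    baseline=15.0, noise_sd=0.5),
    )
    decoy_offset: int = 6000
    subthreshold_frac: float = 0.05
    count_model: CountModel = field(default_factory=CountModel)
    gene_model: GeneModel = field(default_factory=GeneModel)
    diff_model: DiffModel = field(default_factory=DiffModel)
    snp_model: SnpModel = field(default_factory=SnpModel)
    edge_margin: int = 21_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.motif_prob <= 1.0:
            raise ValueError("motif_prob must be in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        per_chrom = -(-self.n_pos // self.n_chroms)
        room = self.chrom_len - 2 * self.edge_margin
        if room <= 0 or room // per_chrom < 2 * PEAK_LEN:
            raise ValueError(
                f"cannot fit {self.n_pos} non-overlapping flanked peaks into "
                f"{self.n_chroms} x {self.chrom_len} bp"
            )


@dataclass
class SynthTruth:
    """Ground truth accompanying a generated dataset."""

    motif: str
    motif_present: np.ndarray          # bool per positive peak
    peak_amplitude: np.ndarray         # gamma amplitude per positive peak
    dhmr_mask: np.ndarray              # bool per peak: planted differential
    gene_hmc: Dict[str, float]         # normalized gene-body 5hmC
    gene_expression: Dict[str, float]
    snp_in_dhmr: np.ndarray            # bool per positive SNP

    def dhmr_windows(self, peaks: Sequence[GenomicInterval]) -> List[GenomicInterval]:
        return [p for p, m in zip(peaks, self.dhmr_mask) if m]

    def non_dhmr_windows(self, peaks: Sequence[GenomicInterval]) -> List[GenomicInterval]:
        return [p for p, m in zip(peaks, self.dhmr_mask) if not m]


@dataclass
class SynthDataset:
    config: SynthConfig
    genome: Dict[str, str]
    peaks: List[GenomicInterval]               # standardized significant peaks
    peaks_frame: pd.DataFrame                  # chrom/start/end/fdr incl. sub-threshold
    subthreshold: List[GenomicInterval]
    mark_reads: Dict[str, List[ReadSet]]       # mark -> replicates
    hmc_reads: ReadSet
    genes: pd.DataFrame                        # gene_id/chrom/start/end/expression
    diff_table: pd.DataFrame                   # chrom/start/end/fdr
    case_marks: Dict[str, List[ReadSet]]
    control_marks: Dict[str, List[ReadSet]]
    pos_snps: List[GenomicInterval]            # 1 bp intervals
    noncoding: List[GenomicInterval]
    truth: SynthTruth

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "genome.fa"), "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        self.peaks_frame.to_csv(os.path.join(out_dir, "peaks.tsv"),
                                sep="\t", index=False)
        write_bed(self.peaks, os.path.join(out_dir, "peaks.bed"))
        for name, reps in self.mark_reads.items():
            for i, rs in enumerate(reps):
                write_bed(rs.intervals(),
                          os.path.join(out_dir, f"mark_{name}_rep{i}.bed"))
        write_bed(self.hmc_reads.intervals(), os.path.join(out_dir, "hmc_reads.bed"))
        self.genes.to_csv(os.path.join(out_dir, "genes.tsv"), sep="\t", index=False)
        self.diff_table.to_csv(os.path.join(out_dir, "diff_table.tsv"),
                               sep="\t", index=False)
        for label, marks in (("case", self.case_marks), ("control", self.control_marks)):
            for name, reps in marks.items():
                for i, rs in enumerate(reps):
                    write_bed(rs.intervals(),
                              os.path.join(out_dir, f"{label}_{name}_rep{i}.bed"))
        write_bed(self.pos_snps, os.path.join(out_dir, "pos_snps.bed"))
        write_bed(self.noncoding, os.path.join(out_dir, "noncoding.bed"))
        light = {
            "motif": self.truth.motif,
            "motif_present": self.truth.motif_present.tolist(),
            "dhmr_mask": self.truth.dhmr_mask.tolist(),
            "gene_expression": self.truth.gene_expression,
            "snp_in_dhmr": self.truth.snp_in_dhmr.tolist(),
            "config_seed": self.config.seed,
        }
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(light, fh)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_genome(rng: np.random.Generator, n_chroms: int, chrom_len: int,
                   gc: float) -> Dict[str, bytearray]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for i in range(1, n_chroms + 1):
        idx = rng.choice(4, size=chrom_len, p=p)
        out[f"chr{i}"] = bytearray(lut[idx].tobytes())
    return out


def _bump_starts(rng: np.random.Generator, centers: np.ndarray,
                 expected: np.ndarray, sd: float, chrom_len: int) -> np.ndarray:
    """Read start positions for Gaussian bumps at ``centers`` with per-site
    expected read counts ``expected``."""
    n = rng.poisson(expected)
    if n.sum() == 0:
        return np.empty(0, dtype=np.int64)
    mids = np.repeat(centers, n).astype(np.float64)
    mids += rng.normal(0.0, sd, size=len(mids))
    starts = np.rint(mids).astype(np.int64) - READ_LEN // 2
    return np.clip(starts, 0, chrom_len - READ_LEN)


def _background_starts(rng: np.random.Generator, rate_per_kb: float,
                       chrom_len: int) -> np.ndarray:
    n = rng.poisson(rate_per_kb * chrom_len / 1000.0)
    return rng.integers(0, chrom_len - READ_LEN, size=n)


def _gamma_amp(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, 1.0 / shape, size=size)


def _mark_readsets(rng: np.random.Generator, profile: MarkProfile,
                   anchors: Dict[str, np.ndarray], chrom_len: int,
                   height_scale: Optional[Dict[str, np.ndarray]] = None
                   ) -> List[ReadSet]:
    """Replicate ReadSets for one mark; ``anchors`` maps chrom -> site centers,
    ``height_scale`` optionally scales the bump height per site."""
    reps = []
    sd = profile.bump_width / 2.0
    for _ in range(profile.n_h):
        per_chrom = {}
        for chrom, centers in anchors.items():
            amp = _gamma_amp(rng, profile.noise_sd, len(centers))
            heights = profile.bump_height * amp
            if height_scale is not None:
                heights = heights * height_scale[chrom]
            bump = _bump_starts(rng, centers, heights, sd, chrom_len)
            bg = _background_starts(rng, profile.baseline, chrom_len)
            per_chrom[chrom] = np.concatenate([bump, bg])
        reps.append(ReadSet.from_arrays(per_chrom, read_len=READ_LEN))
    return reps


def generate_dataset(cfg: SynthConfig, out_dir: Optional[str] = None) -> SynthDataset:
    """Generate the full dataset; optionally also write it to ``out_dir``."""
    rng_genome = np.random.default_rng([cfg.seed, 1])
    rng_peaks = np.random.default_rng([cfg.seed, 2])
    rng_marks = np.random.default_rng([cfg.seed, 3])
    rng_hmc = np.random.default_rng([cfg.seed, 4])
    rng_genes = np.random.default_rng([cfg.seed, 5])
    rng_diff = np.random.default_rng([cfg.seed, 6])
    rng_snps = np.random.default_rng([cfg.seed, 7])

    raw = _random_genome(rng_genome, cfg.n_chroms, cfg.chrom_len, cfg.gc)
    chroms = [f"chr{i}" for i in range(1, cfg.n_chroms + 1)]

    # ---- peak placement on a jittered lattice -----------------------------
    per_chrom = cfg.n_pos // cfg.n_chroms
    extra = cfg.n_pos - per_chrom * cfg.n_chroms
    centers: Dict[str, np.ndarray] = {}
    half = PEAK_LEN // 2
    for ci, chrom in enumerate(chroms):
        k = per_chrom + (1 if ci < extra else 0)
        room = cfg.chrom_len - 2 * cfg.edge_margin
        spacing = room // k
        jitter = rng_peaks.integers(-spacing // 6, spacing // 6 + 1, size=k)
        c = cfg.edge_margin + spacing * np.arange(k) + spacing // 2 + jitter
        centers[chrom] = np.sort(c)
    peaks: List[GenomicInterval] = []
    for chrom in chroms:
        for c in centers[chrom]:
            peaks.append(GenomicInterval(chrom, int(c) - half, int(c) + half))

    # ---- sequence-signal planting ----------------------------------------
    # A signal-carrying positive gets, with probability motif_prob:
    #  - the planted motif (one copy, away from the window edges);
    #  - cpg_boost "GC" dimers swapped to "CG": higher CpG-dinucleotide
    #    density at *identical* base composition, the hallmark of 5hmC
    #    target regions that survives GC matching;
    #  - gc_skew G bases converted to C: strand (GC) skew, also invisible to
    #    GC-content matching.
    motif = cfg.motif.encode("ascii")
    motif_present = rng_peaks.random(len(peaks)) < cfg.motif_prob
    C, G = ord("C"), ord("G")
    for i, p in enumerate(peaks):
        if not motif_present[i]:
            continue
        window = np.frombuffer(bytes(raw[p.chrom][p.start:p.end]), dtype=np.uint8).copy()
        if cfg.cpg_boost:
            gc_pos = np.nonzero((window[:-1] == G) & (window[1:] == C))[0]
            k = min(cfg.cpg_boost, len(gc_pos))
            if k:
                for q in rng_peaks.choice(gc_pos, size=k, replace=False):
                    window[q], window[q + 1] = C, G
        if cfg.gc_skew:
            g_pos = np.nonzero(window == G)[0]
            k = min(cfg.gc_skew, len(g_pos))
            if k:
                window[rng_peaks.choice(g_pos, size=k, replace=False)] = C
        off = int(rng_peaks.integers(100, PEAK_LEN - 100 - len(motif)))
        window[off:off + len(motif)] = np.frombuffer(motif, dtype=np.uint8)
        raw[p.chrom][p.start:p.end] = window.tobytes()
    genome = {c: bytes(s).decode("ascii") for c, s in raw.items()}

    # ---- sub-threshold peaks ---------------------------------------------
    n_sub = int(round(cfg.subthreshold_frac * len(peaks)))
    sub: List[GenomicInterval] = []
    if n_sub:
        pick = rng_peaks.choice(len(peaks), size=n_sub, replace=False)
        for i in sorted(pick):
            p = peaks[i]
            c = p.midpoint + cfg.decoy_offset // 2
            c = min(c, cfg.chrom_len - cfg.edge_margin)
            sub.append(GenomicInterval(p.chrom, c - half, c + half))
    fdr_pos = rng_peaks.uniform(0.0, 0.049, size=len(peaks))
    fdr_sub = rng_peaks.uniform(0.06, 0.4, size=len(sub))
    peaks_frame = pd.DataFrame({
        "chrom": [p.chrom for p in peaks] + [s.chrom for s in sub],
        "start": [p.start for p in peaks] + [s.start for s in sub],
        "end": [p.end for p in peaks] + [s.end for s in sub],
        "fdr": np.concatenate([fdr_pos, fdr_sub]),
    })

    # ---- epigenetic marks -------------------------------------------------
    decoys = {c: np.clip(v + cfg.decoy_offset, 0, cfg.chrom_len - 1)
              for c, v in centers.items()}
    mark_reads: Dict[str, List[ReadSet]] = {}
    for profile in cfg.marks:
        anchors = centers if profile.direction == "pos_up" else decoys
        mark_reads[profile.name] = _mark_readsets(
            rng_marks, profile, anchors, cfg.chrom_len)

    # ---- 5hmC reads (gamma-Poisson around the latent rate) ----------------
    cm = cfg.count_model
    peak_amp = _gamma_amp(rng_hmc, cm.amplitude_cv, len(peaks))
    amp_by_chrom: Dict[str, np.ndarray] = {}
    i = 0
    for chrom in chroms:
        k = len(centers[chrom])
        amp_by_chrom[chrom] = peak_amp[i:i + k]
        i += k
    hmc_per_chrom = {}
    sub_by_chrom: Dict[str, List[int]] = {}
    for s in sub:
        sub_by_chrom.setdefault(s.chrom, []).append(s.midpoint)
    for chrom in chroms:
        bump = _bump_starts(rng_hmc, centers[chrom],
                            cm.signal_reads * amp_by_chrom[chrom],
                            cm.bump_sd, cfg.chrom_len)
        parts = [bump, _background_starts(rng_hmc, cm.baseline_rate, cfg.chrom_len)]
        subs = np.array(sub_by_chrom.get(chrom, []), dtype=np.int64)
        if len(subs):
            amp = _gamma_amp(rng_hmc, cm.amplitude_cv, len(subs))
            parts.append(_bump_starts(
                rng_hmc, subs, cm.signal_reads * cm.subthreshold_scale * amp,
                cm.bump_sd, cfg.chrom_len))
        hmc_per_chrom[chrom] = np.concatenate(parts)
    hmc_reads = ReadSet.from_arrays(hmc_per_chrom, read_len=READ_LEN)

    # ---- genes ------------------------------------------------------------
    # genes may contain 5hmC peaks — gene bodies are 5hmC-enriched in vivo,
    # and that overlap is what makes expression predictable from 5hmC
    gm = cfg.gene_model
    gene_rows = []
    genes_per_chrom = -(-gm.n_genes // cfg.n_chroms)
    gid = 0
    for chrom in chroms:
        placed: List[Tuple[int, int]] = []
        attempts = 0
        while len(placed) < genes_per_chrom and gid + len(placed) < gm.n_genes \
                and attempts < 50 * genes_per_chrom:
            attempts += 1
            length = int(rng_genes.integers(gm.min_len, gm.max_len + 1))
            start = int(rng_genes.integers(
                cfg.edge_margin, cfg.chrom_len - cfg.edge_margin - length))
            end = start + length
            if any(s < end and start < e for s, e in placed):
                continue
            placed.append((start, end))
        for start, end in sorted(placed):
            gene_rows.append((f"gene{gid:04d}", chrom, start, end))
            gid += 1
    gene_hmc, gene_expr = {}, {}
    scale = 1e7 / max(hmc_reads.total_reads, 1)
    for gene_id, chrom, start, end in gene_rows:
        c = hmc_reads.count(GenomicInterval(chrom, start, end)) * scale
        gene_hmc[gene_id] = float(c)
        gene_expr[gene_id] = float(
            gm.alpha * (c + 1.0) * np.exp(rng_genes.normal(0.0, gm.noise_sd)))
    genes = pd.DataFrame(
        [(g, c, s, e, gene_expr[g]) for g, c, s, e in gene_rows],
        columns=["gene_id", "chrom", "start", "end", "expression"],
    )

    # ---- differential (case/control) design ------------------------------
    dm = cfg.diff_model
    dhmr_mask = rng_diff.random(len(peaks)) < dm.p_dhmr
    scale_case: Dict[str, np.ndarray] = {}
    scale_ctrl: Dict[str, np.ndarray] = {}
    i = 0
    for chrom in chroms:
        k = len(centers[chrom])
        m = dhmr_mask[i:i + k]
        scale_case[chrom] = np.where(m, dm.effect, 1.0)
        scale_ctrl[chrom] = np.ones(k)
        i += k
    case_marks = {dm.mark.name: _mark_readsets(
        rng_diff, dm.mark, centers, cfg.chrom_len, scale_case)}
    control_marks = {dm.mark.name: _mark_readsets(
        rng_diff, dm.mark, centers, cfg.chrom_len, scale_ctrl)}
    fdr = np.where(dhmr_mask,
                   rng_diff.uniform(0.0, 0.08, size=len(peaks)),
                   rng_diff.uniform(0.55, 0.98, size=len(peaks)))
    ambiguous = rng_diff.random(len(peaks)) < dm.ambiguous_frac
    fdr = np.where(ambiguous, rng_diff.uniform(0.12, 0.48, size=len(peaks)), fdr)
    diff_table = pd.DataFrame({
        "chrom": [p.chrom for p in peaks],
        "start": [p.start for p in peaks],
        "end": [p.end for p in peaks],
        "fdr": fdr,
    })
    # ambiguous rows carry no usable label; drop them from the planted truth
    dhmr_mask_eff = dhmr_mask & ~ambiguous

    # ---- SNPs and the noncoding mask --------------------------------------
    sm = cfg.snp_model
    noncoding: List[GenomicInterval] = []
    for chrom in chroms:
        spans = sorted((int(r.start), int(r.end))
                       for r in genes.itertuples(index=False) if r.chrom == chrom)
        pos = 0
        for s, e in spans:
            if s > pos:
                noncoding.append(GenomicInterval(chrom, pos, s))
            pos = max(pos, e)
        if pos < cfg.chrom_len:
            noncoding.append(GenomicInterval(chrom, pos, cfg.chrom_len))
    gene_spans: Dict[str, List[Tuple[int, int]]] = {}
    for r in genes.itertuples(index=False):
        gene_spans.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    dhmr_windows = [
        p for p, m in zip(peaks, dhmr_mask_eff)
        if m and not any(s < p.end and p.start < e
                         for s, e in gene_spans.get(p.chrom, []))
    ]  # planted enriched SNPs go to noncoding differential windows only
    nc_lens = np.array([iv.length for iv in noncoding], dtype=np.float64)
    nc_total = nc_lens.sum()
    dhmr_bp = sum(w.length for w in dhmr_windows)
    p0 = dhmr_bp / nc_total
    f = sm.enrichment_odds * p0 / (1.0 - p0 + sm.enrichment_odds * p0)
    snp_in_dhmr = rng_snps.random(sm.n_pos_snps) < f
    pos_snps: List[GenomicInterval] = []
    for in_d in snp_in_dhmr:
        if in_d and dhmr_windows:
            w = dhmr_windows[int(rng_snps.integers(0, len(dhmr_windows)))]
            pos = int(rng_snps.integers(w.start, w.end))
            pos_snps.append(GenomicInterval(w.chrom, pos, pos + 1))
        else:
            iv = noncoding[int(rng_snps.choice(len(noncoding), p=nc_lens / nc_total))]
            pos = int(rng_snps.integers(iv.start, iv.end))
            pos_snps.append(GenomicInterval(iv.chrom, pos, pos + 1))

    truth = SynthTruth(
        motif=cfg.motif,
        motif_present=motif_present,
        peak_amplitude=peak_amp,
        dhmr_mask=dhmr_mask_eff,
        gene_hmc=gene_hmc,
        gene_expression=gene_expr,
        snp_in_dhmr=snp_in_dhmr,
    )
    ds = SynthDataset(
        config=cfg, genome=genome, peaks=peaks, peaks_frame=peaks_frame,
        subthreshold=sub, mark_reads=mark_reads, hmc_reads=hmc_reads,
        genes=genes, diff_table=diff_table, case_marks=case_marks,
        control_marks=control_marks, pos_snps=pos_snps, noncoding=noncoding,
        truth=truth,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds


MICRO_SEED = 20240801


def micro_config() -> SynthConfig:
    """The fixed configuration behind the worked micro example."""
    return SynthConfig(
        n_chroms=3,
        chrom_len=64_000,
        n_pos=12,
        motif_prob=1.0,
        marks=(MarkProfile("enhancer_mark", "pos_up", bump_height=0.0,
                           baseline=0.0, noise_sd=0.0),),
        subthreshold_frac=0.0,
        count_model=CountModel(baseline_rate=0.0, signal_reads=0.0,
                               amplitude_cv=0.0),
        gene_model=GeneModel(n_genes=6, min_len=2000, max_len=4000),
        snp_model=SnpModel(n_pos_snps=30),
        edge_margin=21_000,
        seed=MICRO_SEED,
    )


def generate_worked_micro_example(out_dir: Optional[str] = None) -> SynthDataset:
    """A tiny, fully deterministic 3-chromosome / 12-peak dataset.

    Chromosomes are named chr1, chr7 and chr8 so the cross-chromosomal split
    is exercised.  Mark reads are laid out by hand: one read midpoint every
    100 bp genome-wide plus 20 extra reads centered on each peak, so every
    1 kb profile window counts exactly 10 background reads and the peak-
    centered window exactly 30 — verifiable by hand.  The 5hmC read set puts
    50 reads on each peak center over the same 10-per-kb background.
    Regeneration is byte-identical.
    """
    cfg = micro_config()
    ds = generate_dataset(cfg)

    # rename chr2/chr3 -> chr7/chr8 so the split has val and test examples
    rename = {"chr1": "chr1", "chr2": "chr7", "chr3": "chr8"}
    ds.genome = {rename[c]: s for c, s in ds.genome.items()}

    def _ren(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(rename[iv.chrom], iv.start, iv.end, iv.strand)

    ds.peaks = [_ren(p) for p in ds.peaks]
    ds.peaks_frame["chrom"] = [rename[c] for c in ds.peaks_frame["chrom"]]
    ds.diff_table["chrom"] = [rename[c] for c in ds.diff_table["chrom"]]
    ds.genes["chrom"] = [rename[c] for c in ds.genes["chrom"]]
    ds.noncoding = [_ren(iv) for iv in ds.noncoding]
    ds.pos_snps = [_ren(iv) for iv in ds.pos_snps]

    def _ren_rs(rs: ReadSet) -> ReadSet:
        return ReadSet.from_arrays(
            {rename[c]: rs._starts[c] for c in rs._starts}, READ_LEN)

    ds.case_marks = {k: [_ren_rs(r) for r in v] for k, v in ds.case_marks.items()}
    ds.control_marks = {k: [_ren_rs(r) for r in v]
                        for k, v in ds.control_marks.items()}

    # deterministic mark reads: midpoints on a 100 bp lattice (10 per kb
    # window) plus 20 reads on each peak center
    chrom_len = cfg.chrom_len
    lattice = np.arange(50, chrom_len - READ_LEN // 2, 100, dtype=np.int64)
    mark_starts, hmc_starts = {}, {}
    for chrom in ("chr1", "chr7", "chr8"):
        peak_centers = np.array(
            [p.midpoint for p in ds.peaks if p.chrom == chrom], dtype=np.int64)
        mark_starts[chrom] = np.concatenate(
            [lattice, np.repeat(peak_centers, 20)]) - READ_LEN // 2
        hmc_starts[chrom] = np.concatenate(
            [lattice, np.repeat(peak_centers, 50)]) - READ_LEN // 2
    ds.mark_reads = {"enhancer_mark": [ReadSet.from_arrays(mark_starts, READ_LEN)]}
    ds.hmc_reads = ReadSet.from_arrays(hmc_starts, READ_LEN)

    if out_dir is not None:
        ds.write(out_dir)
    return ds
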