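"""End-to-end experiment drivers built from the library pieces.

These functions wire the modules together for the standard experiments:
labeling + feature extraction over a dataset, the binary/continuous fits,
the unimodal-vs-multimodal ablation, the differential task, and gene-level
aggregation.  The command-line interface and the acceptance checks are thin
wrappers over this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import build_feature_pair
from .labeling import (
    LabeledExample,
    label_dhmrs,
    label_positives,
    make_continuous_targets,
    select_negatives,
)
from .model import HmcModel, HmcResults
from .synthetic import SynthDataset

__all__ = [
    "featurize",
    "binary_examples",
    "continuous_examples",
    "diff_examples",
    "fit_task",
    "run_ablation",
    "TrainSettings",
]


@dataclass(frozen=True)
class TrainSettings:
    """Problem-size knobs for the demonstration fits on synthetic data.

    Synthetic signal is planted and strong, so short schedules suffice; the
    full protocol (200 epochs, patience 10) remains the library default for
    real data.
    """

    max_epochs: int = 3
    patience: int = 10
    batch_size: int = 64
    lr: float = 1e-3


def featurize(
    ds: SynthDataset,
    examples: Sequence[LabeledExample],
    mark_signals: Optional[Dict[str, Sequence]] = None,
    mark_order: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[np.ndarray], np.ndarray, List[str]]:
    """Feature arrays for labeled examples: (seq, epi-per-mark, y, chroms)."""
    if mark_signals is None:
        mark_signals = ds.mark_reads
    if mark_order is None:
        mark_order = sorted(mark_signals)
    pairs = [
        build_feature_pair(ex.region, ds.genome, mark_signals, mark_order=mark_order)
        for ex in examples
    ]
    seq = np.stack([p.seq for p in pairs])
    epi = [np.stack([p.marks[m] for p in pairs]) for m in range(len(mark_order))]
    y = np.array([ex.label for ex in examples])
    chroms = [ex.region.chrom for ex in examples]
    return seq, epi, y, chroms


def binary_examples(ds: SynthDataset, seed: int = 0) -> List[LabeledExample]:
    """Positives (peak FDR < 0.05) plus GC-matched negatives, balanced."""
    pos = label_positives(ds.peaks_frame)
    neg = select_negatives(
        [ex.region for ex in pos], ds.genome, seed=seed,
        exclude=ds.subthreshold,
    )
    return pos + neg


def continuous_examples(ds: SynthDataset, seed: int = 0) -> List[LabeledExample]:
    """Log normalized 5hmC counts over peaks and the matched background."""
    regions = [ex.region for ex in binary_examples(ds, seed=seed)]
    return make_continuous_targets(regions, ds.hmc_reads)


def diff_examples(ds: SynthDataset) -> List[LabeledExample]:
    """Differential labels from the consumed differential table."""
    return label_dhmrs(ds.diff_table)


def fit_task(
    ds: SynthDataset,
    examples: Sequence[LabeledExample],
    task: str,
    modality: str = "both",
    seed: int = 0,
    settings: TrainSettings = TrainSettings(),
    mark_signals: Optional[Dict[str, Sequence]] = None,
    mark_order: Optional[Sequence[str]] = None,
    features: Optional[Tuple] = None,
) -> Tuple[HmcResults, Dict[str, float]]:
    """Featurize (unless given pre-built arrays), fit, and evaluate on the
    held-out chromosomes.  Returns the Results object and its test metrics."""
    if features is None:
        features = featurize(ds, examples, mark_signals, mark_order)
    seq, epi, y, chroms = features
    model = HmcModel(
        seq if modality != "epi_only" else None,
        epi if modality != "seq_only" else None,
        y, chroms=chroms, task=task, modality=modality,
    )
    res = model.fit(
        lr=settings.lr, max_epochs=settings.max_epochs,
        patience=settings.patience, batch_size=settings.batch_size, seed=seed,
    )
    metrics = dict(res.evaluate("test"))
    return res, metrics


def run_ablation(
    ds: SynthDataset,
    seeds: Sequence[int] = (0, 1, 2),
    settings: TrainSettings = TrainSettings(),
    mark_signals: Optional[Dict[str, Sequence]] = None,
) -> pd.DataFrame:
    """The unimodal-vs-multimodal comparison on the binary task.

    Fits sequence-only, epigenetics-only and fused models for each seed on
    the same labeled set and reports held-out AUROC/AUPRC per row.
    """
    examples = binary_examples(ds, seed=seeds[0])
    features = featurize(ds, examples, mark_signals)
    rows = []
    for seed in seeds:
        for modality in ("seq_only", "epi_only", "both"):
            _, met = fit_task(
                ds, examples, task="binary", modality=modality, seed=seed,
                settings=settings, features=features,
            )
            rows.append({
                "modality": modality, "seed": seed,
                "auroc": met["auroc"], "auprc": met["auprc"], "n": met["n"],
            })
    return pd.DataFrame(rows)
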