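"""The multimodal 5hmC network and its statsmodels-style Model/Results pair.

Architecture
------------
Two unimodal encoders feed a factorized bilinear fusion:

- *sequence encoder*: three valid 1-D convolutions (kernel 8, stride 1,
  filters 64/128/256), max pooling (kernel 4, stride 4) after the first two,
  flatten, then two fully connected layers.  For a 1 kb input the feature map
  entering the flatten is 256 x 53 = 13568.
- *epigenetic encoder*: one CNN per mark over its (n_h, 41) profile matrix —
  three padded 3x3 convolutions (filters 32/64/128), max pooling of kernel
  1x2 (n_h = 1) or 2x2 (n_h > 1) with stride equal to the kernel after the
  first two, flatten (128*10 = 1280 for n_h = 1), two fully connected layers;
  per-mark outputs are concatenated.
- *fusion*: MFB pooling of the two embeddings with signed-sqrt and l2
  normalization; unimodal configurations bypass fusion and feed the single
  embedding straight to the head.
- *head*: two fully connected layers, then 2 output nodes + softmax for the
  binary task (class-1 probability reported) or 1 linear node for the
  continuous task.

ReLU everywhere except the output; dropout 0.5 in the fully connected parts.
Training uses Adam (lr 1e-3), cross-entropy or MSE, minibatches, and early
stopping on validation loss with a patience of 10 epochs (200 epoch cap),
returning the parameters of the best validation epoch.

Usage follows the Model/Results convention::

    model = HmcModel(seq, epi, y, chroms=chroms, task="binary", modality="both")
    res = model.fit(seed=0)
    probs = res.predict(seq_test, epi_test)
    print(res.summary())
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .features import FeaturePair
from .labeling import TEST_CHROMS, VAL_CHROMS, LabeledExample
from .metrics import MetricReport, compute_binary_metrics, compute_continuous_metrics

__all__ = ["ModelSpec", "TrainConfig", "Network", "HmcModel", "HmcResults"]


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters fixing the full architecture.

    Convolutional shapes follow the published architecture; the fully
    connected widths and the MFB factors (k, o) are implementation defaults
    and freely configurable.
    """

    task: str = "binary"                 # "binary" | "continuous"
    modality: str = "both"               # "both" | "seq_only" | "epi_only"
    seq_len: int = 1000
    seq_kernel: int = 8
    seq_filters: Tuple[int, int, int] = (64, 128, 256)
    seq_pool: int = 4
    seq_fc: Tuple[int, int] = (512, 256)
    n_marks: int = 1
    n_h: Tuple[int, ...] = (1,)
    epi_width: int = 41
    epi_kernel: int = 3
    epi_pad: int = 1
    epi_filters: Tuple[int, int, int] = (32, 64, 128)
    epi_pool: int = 2
    epi_fc: Tuple[int, int] = (256, 128)
    mfb_k: int = 5
    mfb_o: int = 500
    head_fc: Tuple[int, int] = (256, 64)
    dropout: float = 0.5
    bias_init: float = 0.1

    def __post_init__(self):
        if self.task not in ("binary", "continuous"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.modality not in ("both", "seq_only", "epi_only"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if len(self.n_h) != self.n_marks:
            raise ValueError("n_h must list one replicate count per mark")

    # -- conv/pool arithmetic (floor((L - k + 2p)/s) + 1 chained) -----------

    def seq_map_len(self) -> int:
        L = self.seq_len
        L = nn.conv_out_len(L, self.seq_kernel)               # conv1
        L = nn.conv_out_len(L, self.seq_pool, self.seq_pool)  # pool1
        L = nn.conv_out_len(L, self.seq_kernel)               # conv2
        L = nn.conv_out_len(L, self.seq_pool, self.seq_pool)  # pool2
        L = nn.conv_out_len(L, self.seq_kernel)               # conv3
        if L < 1:
            raise ValueError(f"seq_len {self.seq_len} too short for the conv chain")
        return L

    def seq_flatten_size(self) -> int:
        return self.seq_filters[-1] * self.seq_map_len()

    def epi_pool_kernels(self, mark: int) -> List[Tuple[int, int]]:
        """Pool kernels (== strides) for the two pooling stages: 1x2 when the
        replicate dimension is 1, else 2x2, with the height clamped to the
        current map height so small replicate counts stay valid."""
        h = self.n_h[mark]
        kernels = []
        for _ in range(2):
            kh = 1 if h == 1 else min(self.epi_pool, h)
            kernels.append((kh, self.epi_pool))
            h = nn.conv_out_len(h, kh, kh)
        return kernels

    def epi_map_shape(self, mark: int) -> Tuple[int, int]:
        h, w = self.n_h[mark], self.epi_width
        for kh, kw in self.epi_pool_kernels(mark):  # conv preserves, pool shrinks
            h = nn.conv_out_len(h, kh, kh)
            w = nn.conv_out_len(w, kw, kw)
        if h < 1 or w < 1:
            raise ValueError("epigenetic profile too small for the conv chain")
        return h, w

    def epi_flatten_size(self, mark: int) -> int:
        h, w = self.epi_map_shape(mark)
        return self.epi_filters[-1] * h * w

    @property
    def seq_embedding_dim(self) -> int:
        return self.seq_fc[-1]

    @property
    def epi_embedding_dim(self) -> int:
        return self.epi_fc[-1] * self.n_marks

    @property
    def head_input_dim(self) -> int:
        if self.modality == "both":
            return self.mfb_o
        if self.modality == "seq_only":
            return self.seq_embedding_dim
        return self.epi_embedding_dim

    @property
    def n_out(self) -> int:
        return 2 if self.task == "binary" else 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for key in ("seq_filters", "seq_fc", "n_h", "epi_filters", "epi_fc", "head_fc"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, minibatches, early stopping)."""

    lr: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    batch_size: int = 64
    seed: int = 0
    warmup_steps: int = 0
    lr_decay: float = 1.0
    shuffle: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    """The assembled network with explicit forward/backward passes."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        drop = spec.dropout

        def dropout() -> nn.Dropout:
            d = nn.Dropout(drop)
            self._dropouts.append(d)
            return d

        self._dropouts: List[nn.Dropout] = []

        if spec.modality != "epi_only":
            k, f = spec.seq_kernel, spec.seq_filters
            self.seq_branch = nn.Sequential([
                nn.Conv1D(4, f[0], k, rng), nn.ReLU(), nn.MaxPool1D(spec.seq_pool),
                nn.Conv1D(f[0], f[1], k, rng), nn.ReLU(), nn.MaxPool1D(spec.seq_pool),
                nn.Conv1D(f[1], f[2], k, rng), nn.ReLU(), nn.Flatten(),
                nn.Dense(spec.seq_flatten_size(), spec.seq_fc[0], rng), nn.ReLU(),
                dropout(),
                nn.Dense(spec.seq_fc[0], spec.seq_fc[1], rng), nn.ReLU(),
            ])
        else:
            self.seq_branch = None

        if spec.modality != "seq_only":
            f = spec.epi_filters
            self.epi_branches = []
            for mark in range(spec.n_marks):
                (kh1, kw1), (kh2, kw2) = spec.epi_pool_kernels(mark)
                self.epi_branches.append(nn.Sequential([
                    nn.Conv2D(1, f[0], spec.epi_kernel, spec.epi_pad, rng),
                    nn.ReLU(), nn.MaxPool2D(kh1, kw1),
                    nn.Conv2D(f[0], f[1], spec.epi_kernel, spec.epi_pad, rng),
                    nn.ReLU(), nn.MaxPool2D(kh2, kw2),
                    nn.Conv2D(f[1], f[2], spec.epi_kernel, spec.epi_pad, rng),
                    nn.ReLU(), nn.Flatten(),
                    nn.Dense(spec.epi_flatten_size(mark), spec.epi_fc[0], rng),
                    nn.ReLU(), dropout(),
                    nn.Dense(spec.epi_fc[0], spec.epi_fc[1], rng), nn.ReLU(),
                ]))
        else:
            self.epi_branches = []

        if spec.modality == "both":
            self.fusion = nn.MFBFusion(
                spec.seq_embedding_dim, spec.epi_embedding_dim,
                spec.mfb_k, spec.mfb_o, rng,
            )
        else:
            self.fusion = None

        self.head = nn.Sequential([
            nn.Dense(spec.head_input_dim, spec.head_fc[0], rng), nn.ReLU(),
            dropout(),
            nn.Dense(spec.head_fc[0], spec.head_fc[1], rng), nn.ReLU(),
            dropout(),
            nn.Dense(spec.head_fc[1], spec.n_out, rng),
        ])

        # start every ReLU unit in its active region: He-initialized deep
        # ReLU stacks driven by Adam otherwise collapse whole layers to the
        # dead state within the first epochs
        if spec.bias_init:
            for name, w, _ in self.params():
                if name.endswith(".b"):
                    w += spec.bias_init

    # -- plumbing -----------------------------------------------------------

    def set_dropout_rng(self, rng: Optional[np.random.Generator]) -> None:
        for d in self._dropouts:
            d.rng = rng

    def params(self):
        out = []
        if self.seq_branch is not None:
            out += [("seq." + n, w, g) for n, w, g in self.seq_branch.params()]
        for i, br in enumerate(self.epi_branches):
            out += [(f"epi{i}." + n, w, g) for n, w, g in br.params()]
        if self.fusion is not None:
            out += [("mfb." + n, w, g) for n, w, g in self.fusion.params()]
        out += [("head." + n, w, g) for n, w, g in self.head.params()]
        return out

    def get_state(self) -> Dict[str, np.ndarray]:
        return {name: w.copy() for name, w, _ in self.params()}

    def set_state(self, state: Dict[str, np.ndarray]) -> None:
        for name, w, _ in self.params():
            w[...] = state[name]

    # -- forward / backward -------------------------------------------------

    def encode_seq(self, seq: np.ndarray, train: bool = False) -> np.ndarray:
        """Sequence embedding from a (B, L, 4) one-hot batch."""
        x = np.ascontiguousarray(seq.transpose(0, 2, 1), dtype=np.float32)
        return self.seq_branch.forward(x, train=train)

    def encode_epi(self, marks: Sequence[np.ndarray], train: bool = False) -> np.ndarray:
        """Concatenated epigenetic embedding from per-mark (B, n_h, W) batches."""
        outs = []
        for br, m in zip(self.epi_branches, marks):
            x = np.ascontiguousarray(m[:, None, :, :], dtype=np.float32)
            outs.append(br.forward(x, train=train))
        self._epi_dims = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def forward(self, seq: Optional[np.ndarray], marks: Optional[Sequence[np.ndarray]],
                train: bool = False) -> np.ndarray:
        spec = self.spec
        if spec.modality == "seq_only":
            z = self.encode_seq(seq, train)
        elif spec.modality == "epi_only":
            z = self.encode_epi(marks, train)
        else:
            e1 = self.encode_seq(seq, train)
            e2 = self.encode_epi(marks, train)
            z = self.fusion.forward((e1, e2), train=train)
        return self.head.forward(z, train=train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        spec = self.spec
        if spec.modality == "seq_only":
            self.seq_branch.backward(g)
            return
        if spec.modality == "epi_only":
            self._backward_epi(g)
            return
        g1, g2 = self.fusion.backward(g)
        self.seq_branch.backward(g1)
        self._backward_epi(g2)

    def _backward_epi(self, grad: np.ndarray) -> None:
        off = 0
        for br, d in zip(self.epi_branches, self._epi_dims):
            br.backward(grad[:, off:off + d])
            off += d

    def head_forward(self, z: np.ndarray) -> np.ndarray:
        """Prediction from a fused vector: class-1 probability (binary) or the
        raw linear output (continuous)."""
        single = z.ndim == 1
        if single:
            z = z[None, :]
        out = self.head.forward(z.astype(np.float32), train=False)
        out = _to_prediction(out, self.spec.task)
        return out[0] if single else out


def _to_prediction(logits: np.ndarray, task: str) -> np.ndarray:
    if task == "binary":
        return _softmax(logits)[:, 1]
    return logits[:, 0]


def _softmax(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grad(logits: np.ndarray, y: np.ndarray, task: str):
    B = len(y)
    if task == "binary":
        p = _softmax(logits.astype(np.float64))
        yi = y.astype(int)
        eps = 1e-12
        loss = -np.mean(np.log(p[np.arange(B), yi] + eps))
        grad = p.copy()
        grad[np.arange(B), yi] -= 1.0
        return loss, (grad / B).astype(np.float32)
    pred = logits[:, 0].astype(np.float64)
    diff = pred - y
    loss = float(np.mean(diff ** 2))
    grad = np.zeros_like(logits, dtype=np.float64)
    grad[:, 0] = 2.0 * diff / B
    return loss, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class HmcModel:
    """A 5hmC prediction model bound to a dataset and a chromosome-wise split.

    Parameters
    ----------
    seq : (N, L, 4) one-hot sequences (may be None for epi_only)
    epi : list of per-mark (N, n_h, W) profile arrays (None for seq_only)
    y : (N,) labels — 0/1 for binary, log counts for continuous
    chroms : (N,) chromosome names used for the cross-chromosomal split
        (chr8/chr9 test, chr7 validation by default); alternatively pass an
        explicit ``split`` array of "train"/"val"/"test" strings.
    """

    def __init__(
        self,
        seq: Optional[np.ndarray],
        epi: Optional[List[np.ndarray]],
        y: np.ndarray,
        chroms: Optional[Sequence[str]] = None,
        split: Optional[Sequence[str]] = None,
        task: str = "binary",
        modality: str = "both",
        spec: Optional[ModelSpec] = None,
        test_chroms=TEST_CHROMS,
        val_chroms=VAL_CHROMS,
        standardize_epi: bool = True,
    ):
        self.y = np.asarray(y, dtype=np.float64)
        N = len(self.y)
        self.seq = None if seq is None else np.asarray(seq, dtype=np.float32)
        self.epi = None if epi is None else [np.asarray(e, dtype=np.float32) for e in epi]
        if self.seq is not None and len(self.seq) != N:
            raise ValueError("seq and y disagree on N")
        if self.epi is not None and any(len(e) != N for e in self.epi):
            raise ValueError("epi and y disagree on N")

        if split is None:
            if chroms is None:
                raise ValueError("provide either chroms or an explicit split")
            # the split depends on chromosome only
            split = []
            test_chroms, val_chroms = set(test_chroms), set(val_chroms)
            if test_chroms & val_chroms:
                raise ValueError("test and validation chromosomes overlap")
            for c in chroms:
                split.append("test" if c in test_chroms
                             else "val" if c in val_chroms else "train")
        self.split = np.asarray(split)
        if not set(np.unique(self.split)) <= {"train", "val", "test"}:
            raise ValueError("split entries must be train/val/test")

        if spec is None:
            spec = ModelSpec(
                task=task,
                modality=modality,
                seq_len=self.seq.shape[1] if self.seq is not None else 1000,
                n_marks=len(self.epi) if self.epi is not None else 1,
                n_h=tuple(e.shape[1] for e in self.epi) if self.epi is not None else (1,),
                epi_width=self.epi[0].shape[2] if self.epi is not None else 41,
            )
        self.spec = spec
        self.standardize_epi = standardize_epi and self.epi is not None

        self.idx = {s: np.nonzero(self.split == s)[0] for s in ("train", "val", "test")}
        if len(self.idx["train"]) == 0 or len(self.idx["val"]) == 0:
            raise ValueError("training and validation sets must be non-empty")

    @classmethod
    def from_feature_pairs(
        cls,
        pairs: Sequence[FeaturePair],
        examples: Sequence[LabeledExample],
        **kwargs,
    ) -> "HmcModel":
        if len(pairs) != len(examples):
            raise ValueError("pairs and examples must align")
        seq = np.stack([p.seq for p in pairs])
        n_marks = len(pairs[0].marks)
        epi = [np.stack([p.marks[m] for p in pairs]) for m in range(n_marks)]
        y = np.array([ex.label for ex in examples])
        chroms = [p.region.chrom for p in pairs]
        task = kwargs.pop("task", None) or (
            "continuous" if examples[0].task == "continuous" else "binary")
        return cls(seq, epi, y, chroms=chroms, task=task, **kwargs)

    # -- data plumbing ------------------------------------------------------

    def _epi_stats(self, idx: np.ndarray):
        stats = []
        for e in self.epi:
            mu = float(e[idx].mean())
            sd = float(e[idx].std())
            stats.append((mu, sd if sd > 0 else 1.0))
        return stats

    def _batch(self, idx: np.ndarray, epi_stats):
        seq = self.seq[idx] if self.seq is not None and self.spec.modality != "epi_only" else None
        if self.epi is not None and self.spec.modality != "seq_only":
            marks = []
            for e, (mu, sd) in zip(self.epi, epi_stats):
                m = e[idx]
                if self.standardize_epi:
                    m = (m - mu) / sd
                marks.append(m)
        else:
            marks = None
        return seq, marks

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        lr: float = 1e-3,
        max_epochs: int = 200,
        patience: int = 10,
        batch_size: int = 64,
        seed: int = 0,
        warmup_steps: int = 0,
        lr_decay: float = 1.0,
        verbose: bool = False,
    ) -> "HmcResults":
        cfg = TrainConfig(lr=lr, max_epochs=max_epochs, patience=patience,
                          batch_size=batch_size, seed=seed,
                          warmup_steps=warmup_steps, lr_decay=lr_decay)
        rng_init = np.random.default_rng([seed, 0])
        rng_drop = np.random.default_rng([seed, 1])
        rng_shuffle = np.random.default_rng([seed, 2])

        net = Network(self.spec, rng_init)
        net.set_dropout_rng(rng_drop)
        opt = nn.Adam(net.params(), lr=lr, warmup_steps=warmup_steps, decay=lr_decay)

        epi_stats = self._epi_stats(self.idx["train"]) if self.epi is not None else None
        train_idx = self.idx["train"].copy()
        val_idx = self.idx["val"]

        log_rows = []
        best_val = np.inf
        best_state = net.get_state()
        best_epoch = -1
        stall = 0
        t0 = time.time()

        for epoch in range(max_epochs):
            if cfg.shuffle:
                rng_shuffle.shuffle(train_idx)
            tot, nb = 0.0, 0
            for s in range(0, len(train_idx), batch_size):
                bidx = train_idx[s:s + batch_size]
                seq, marks = self._batch(bidx, epi_stats)
                logits = net.forward(seq, marks, train=True)
                loss, grad = _loss_and_grad(logits, self.y[bidx], self.spec.task)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch {nb} "
                        f"(lr={lr}, task={self.spec.task}); aborting"
                    )
                net.backward(grad)
                opt.step()
                tot += loss * len(bidx)
                nb += 1
            train_loss = tot / len(train_idx)
            val_loss = self._eval_loss(net, val_idx, epi_stats, batch_size)
            if not np.isfinite(val_loss):
                raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
            log_rows.append((epoch, train_loss, val_loss))
            if verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}  "
                      f"({time.time() - t0:.1f}s)")
            if val_loss < best_val:
                best_val = val_loss
                best_state = net.get_state()
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break

        net.set_state(best_state)
        log = pd.DataFrame(log_rows, columns=["epoch", "train_loss", "val_loss"])
        return HmcResults(self, net, cfg, log, best_epoch, epi_stats)

    def _eval_loss(self, net: Network, idx: np.ndarray, epi_stats, batch_size: int) -> float:
        tot = 0.0
        for s in range(0, len(idx), batch_size):
            bidx = idx[s:s + batch_size]
            seq, marks = self._batch(bidx, epi_stats)
            logits = net.forward(seq, marks, train=False)
            loss, _ = _loss_and_grad(logits, self.y[bidx], self.spec.task)
            tot += loss * len(bidx)
        return tot / len(idx)


class HmcResults:
    """Fit results: learned parameters, training log and prediction API."""

    def __init__(self, model: HmcModel, net: Network, config: TrainConfig,
                 training_log: pd.DataFrame, best_epoch: int, epi_stats):
        self.model = model
        self.net = net
        self.config = config
        self.training_log = training_log
        self.best_epoch = best_epoch
        self.epi_stats = epi_stats

    @property
    def spec(self) -> ModelSpec:
        return self.net.spec

    # -- prediction ---------------------------------------------------------

    def predict(self, seq: Optional[np.ndarray] = None,
                epi: Optional[Sequence[np.ndarray]] = None,
                batch_size: int = 256) -> np.ndarray:
        """Predictions for raw feature arrays: class-1 probabilities for the
        binary task, log-scale counts for the continuous task."""
        spec = self.spec
        if spec.modality != "epi_only" and seq is None:
            raise ValueError("model uses the sequence modality: seq required")
        if spec.modality != "seq_only" and epi is None:
            raise ValueError("model uses the epigenetic modality: epi required")
        N = len(seq) if seq is not None else len(epi[0])
        out = np.empty(N, dtype=np.float64)
        for s in range(0, N, batch_size):
            sl = slice(s, min(s + batch_size, N))
            sb = None
            if spec.modality != "epi_only":
                sb = np.asarray(seq[sl], dtype=np.float32)
            mb = None
            if spec.modality != "seq_only":
                mb = []
                for e, (mu, sd) in zip(epi, self.epi_stats):
                    m = np.asarray(e[sl], dtype=np.float32)
                    if self.model.standardize_epi:
                        m = (m - mu) / sd
                    mb.append(m)
            logits = self.net.forward(sb, mb, train=False)
            out[sl] = _to_prediction(logits, spec.task)
        return out

    def predict_pairs(self, pairs: Sequence[FeaturePair], batch_size: int = 256) -> np.ndarray:
        seq = np.stack([p.seq for p in pairs]) if self.spec.modality != "epi_only" else None
        epi = None
        if self.spec.modality != "seq_only":
            epi = [np.stack([p.marks[m] for p in pairs])
                   for m in range(len(pairs[0].marks))]
        return self.predict(seq, epi, batch_size=batch_size)

    def predict_split(self, which: str = "test", batch_size: int = 256) -> np.ndarray:
        idx = self.model.idx[which]
        seq = self.model.seq[idx] if self.model.seq is not None else None
        epi = [e[idx] for e in self.model.epi] if self.model.epi is not None else None
        return self.predict(seq, epi, batch_size=batch_size)

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, which: str = "test", batch_size: int = 256) -> MetricReport:
        idx = self.model.idx[which]
        y = self.model.y[idx]
        pred = self.predict_split(which, batch_size=batch_size)
        rep = MetricReport(n=int(len(idx)), split=which)
        if self.spec.task == "binary":
            a, p = compute_binary_metrics(y, pred)
            rep["auroc"], rep["auprc"] = a, p
        else:
            r, mse = compute_continuous_metrics(y, pred)
            rep["spearman_r"], rep["mse"] = r, mse
        return rep

    # -- reporting / persistence -------------------------------------------

    def summary(self) -> str:
        spec = self.spec
        n_params = sum(w.size for _, w, _ in self.net.params())
        log = self.training_log
        lines = [
            "5hmC prediction model fit",
            "=" * 48,
            f"task:               {spec.task}",
            f"modality:           {spec.modality}",
            f"marks / replicates: {spec.n_marks} / {list(spec.n_h)}",
            f"parameters:         {n_params:,}",
            f"train/val/test n:   {len(self.model.idx['train'])}/"
            f"{len(self.model.idx['val'])}/{len(self.model.idx['test'])}",
            f"epochs run:         {len(log)} (best epoch {self.best_epoch})",
            f"best val loss:      {log['val_loss'].min():.6g}",
            f"final train loss:   {log['train_loss'].iloc[-1]:.6g}",
            f"seed:               {self.config.seed}",
        ]
        return "\n".join(lines)

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.npz`` (parameters) + ``<prefix>.json`` (spec,
        training config and log)."""
        np.savez_compressed(f"{prefix}.npz", **self.net.get_state())
        meta = {
            "spec": self.spec.to_dict(),
            "config": self.config.to_dict(),
            "best_epoch": int(self.best_epoch),
            "epi_stats": self.epi_stats,
            "standardize_epi": self.model.standardize_epi,
            "training_log": self.training_log.to_dict(orient="list"),
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix: str) -> "HmcResults":
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        spec = ModelSpec.from_dict(meta["spec"])
        net = Network(spec, np.random.default_rng(0))
        with np.load(f"{prefix}.npz") as data:
            net.set_state({k: data[k] for k in data.files})
        res = cls.__new__(cls)
        res.net = net
        res.config = TrainConfig(**meta["config"])
        res.training_log = pd.DataFrame(meta["training_log"])
        res.best_epoch = meta["best_epoch"]
        res.epi_stats = [tuple(s) for s in meta["epi_stats"]] if meta["epi_stats"] else None

        class _Shell:
            pass

        shell = _Shell()
        shell.standardize_epi = meta["standardize_epi"]
        res.model = shell
        return res
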