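"""Model-level behaviour: architecture arithmetic, prediction contracts,
early stopping, reproducibility and checkpoint round-trips."""

import numpy as np
import pandas as pd
import pytest

from hmcnet.model import (
    HmcModel,
    HmcResults,
    ModelSpec,
    Network,
    TrainConfig,
    _softmax,
)


def toy_binary(rng, n=400, L=320, n_marks=1, sep=2.0):
    """Separable toy data: the epigenetic center windows carry the label."""
    y = (rng.random(n) < 0.5).astype(float)
    seq = np.zeros((n, L, 4), np.float32)
    idx = rng.integers(0, 4, (n, L))
    seq[np.arange(n)[:, None], np.arange(L)[None, :], idx] = 1
    epi = []
    for _ in range(n_marks):
        e = rng.normal(10, 2, (n, 1, 41)).astype(np.float32)
        e[y == 1, :, 18:23] += sep
        epi.append(e)
    chroms = np.array(["chr1"] * n)
    chroms[: n // 5] = "chr7"
    chroms[n // 5: 2 * n // 5] = "chr8"
    return seq, epi, y, chroms


def tiny_spec(**kw):
    defaults = dict(task="binary", modality="both", seq_len=320,
                    seq_filters=(8, 12, 16), seq_fc=(32, 16),
                    epi_filters=(4, 6, 8), epi_fc=(16, 8),
                    mfb_k=2, mfb_o=12, head_fc=(16, 8))
    defaults.update(kw)
    return ModelSpec(**defaults)


class TestModelSpec:
    def test_sequence_branch_arithmetic(self):
        spec = ModelSpec()
        assert spec.seq_map_len() == 53
        assert spec.seq_flatten_size() == 13568

    def test_epigenetic_branch_arithmetic(self):
        spec = ModelSpec(n_marks=1, n_h=(1,))
        assert spec.epi_map_shape(0) == (1, 10)
        assert spec.epi_flatten_size(0) == 1280

    def test_pool_kernel_depends_on_replicates(self):
        spec = ModelSpec(n_marks=2, n_h=(1, 4))
        assert spec.epi_pool_kernels(0) == [(1, 2), (1, 2)]
        assert spec.epi_pool_kernels(1) == [(2, 2), (2, 2)]

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(seq_len=100).seq_flatten_size()

    def test_roundtrip_dict(self):
        spec = tiny_spec(task="continuous")
        assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ModelSpec(task="regression")
        with pytest.raises(ValueError):
            ModelSpec(n_marks=2, n_h=(1,))
        with pytest.raises(ValueError):
            TrainConfig(patience=0)


class TestForwardContracts:
    def test_flatten_sizes_realized_in_forward(self, rng):
        # the real architecture, one small batch: check actual shapes feed
        # the first dense layer with 13568 / 1280 inputs
        spec = ModelSpec()
        net = Network(spec, np.random.default_rng(0))
        assert net.seq_branch.layers[9].W.shape[0] == 13568
        assert net.epi_branches[0].layers[9].W.shape[0] == 1280
        seq = rng.random((2, 1000, 4)).astype(np.float32)
        epi = [rng.random((2, 1, 41)).astype(np.float32)]
        out = net.forward(seq, epi)
        assert out.shape == (2, 2)

    def test_zero_input_zero_bias_gives_zero_embedding(self):
        spec = tiny_spec(modality="seq_only", bias_init=0.0)
        net = Network(spec, np.random.default_rng(1))
        emb = net.encode_seq(np.zeros((3, 320, 4), np.float32))
        assert (emb == 0).all()

    def test_eval_determinism(self, rng):
        spec = tiny_spec()
        net = Network(spec, np.random.default_rng(2))
        seq = rng.random((4, 320, 4)).astype(np.float32)
        epi = [rng.random((4, 1, 41)).astype(np.float32)]
        a = net.forward(seq, epi, train=False)
        b = net.forward(seq, epi, train=False)
        assert (a == b).all()

    def test_binary_probabilities_normalized_and_monotone(self, rng):
        logits = rng.normal(size=(50, 2))
        p = _softmax(logits)
        assert np.allclose(p.sum(axis=1), 1.0)
        order = np.argsort(logits[:, 1] - logits[:, 0])
        assert (np.diff(p[order, 1]) > 0).all()

    def test_head_forward_probability_range(self, rng):
        net = Network(tiny_spec(), np.random.default_rng(3))
        z = rng.normal(size=12).astype(np.float32)
        p = net.head_forward(z)
        assert 0.0 <= p <= 1.0


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    seq, epi, y, chroms = toy_binary(rng)
    model = HmcModel(seq, epi, y, chroms=chroms, spec=tiny_spec())
    res = model.fit(max_epochs=6, patience=10, batch_size=32, seed=4)
    return model, res, (seq, epi, y, chroms)


class TestFitPredict:
    def test_learns_separable_task(self):
        """An easily separable task must be fit essentially perfectly."""
        rng = np.random.default_rng(10)
        _, epi, y, chroms = toy_binary(rng, n=600, sep=4.0)
        model = HmcModel(None, epi, y, chroms=chroms, task="binary",
                         modality="epi_only")
        res = model.fit(max_epochs=10, patience=10, batch_size=32, seed=1)
        assert res.evaluate("train")["auroc"] >= 0.99

    def test_predictions_in_range_and_deterministic(self, fitted):
        _, res, (seq, epi, y, _) = fitted
        p1 = res.predict(seq[:10], [e[:10] for e in epi])
        p2 = res.predict(seq[:10], [e[:10] for e in epi])
        assert ((p1 >= 0) & (p1 <= 1)).all()
        assert (p1 == p2).all()

    def test_batch_order_invariance(self, fitted):
        _, res, (seq, epi, y, _) = fitted
        perm = np.random.default_rng(1).permutation(30)
        p = res.predict(seq[:30], [e[:30] for e in epi])
        pp = res.predict(seq[:30][perm], [e[:30][perm] for e in epi])
        assert np.allclose(p[perm], pp, atol=1e-6)

    def test_best_epoch_is_validation_minimum(self, fitted):
        _, res, _ = fitted
        log = res.training_log
        assert res.best_epoch == int(log["val_loss"].idxmin())

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        seq, epi, y, chroms = toy_binary(rng, n=200)
        runs = []
        for _ in range(2):
            model = HmcModel(None, epi, y, chroms=chroms, task="binary",
                             modality="epi_only")
            res = model.fit(max_epochs=3, patience=5, batch_size=32, seed=11)
            runs.append((res.training_log, res.predict_split("test")))
        pd.testing.assert_frame_equal(runs[0][0], runs[1][0])
        assert (runs[0][1] == runs[1][1]).all()

    def test_checkpoint_roundtrip(self, fitted, tmp_path):
        _, res, (seq, epi, y, _) = fitted
        prefix = str(tmp_path / "ckpt")
        res.save(prefix)
        loaded = HmcResults.load(prefix)
        a = res.predict(seq[:8], [e[:8] for e in epi])
        b = loaded.predict(seq[:8], [e[:8] for e in epi])
        assert np.allclose(a, b, atol=1e-7)


class TestModalityMasks:
    def test_epi_only_ignores_sequence(self):
        rng = np.random.default_rng(2)
        seq, epi, y, chroms = toy_binary(rng, n=200)
        model = HmcModel(None, epi, y, chroms=chroms, task="binary",
                         modality="epi_only")
        res = model.fit(max_epochs=2, patience=5, batch_size=32, seed=0)
        p1 = res.predict(epi=[e[:40] for e in epi])
        # a model without the sequence modality cannot react to sequences
        p2 = res.predict(epi=[e[:40] for e in epi])
        assert (p1 == p2).all()

    def test_seq_only_requires_no_epi(self):
        rng = np.random.default_rng(3)
        seq, epi, y, chroms = toy_binary(rng, n=150)
        model = HmcModel(seq, None, y, chroms=chroms, task="binary",
                         modality="seq_only", spec=tiny_spec(modality="seq_only"))
        res = model.fit(max_epochs=1, patience=5, batch_size=32, seed=0)
        p = res.predict(seq=seq[:10])
        assert p.shape == (10,)

    def test_missing_modality_raises(self):
        rng = np.random.default_rng(4)
        seq, epi, y, chroms = toy_binary(rng, n=150)
        model = HmcModel(seq, epi, y, chroms=chroms, spec=tiny_spec())
        res = model.fit(max_epochs=1, patience=5, batch_size=64, seed=0)
        with pytest.raises(ValueError):
            res.predict(seq=seq[:5], epi=None)


class TestEarlyStopping:
    def test_scripted_loss_sequence_stops_on_schedule(self, monkeypatch):
        """With validation losses worsening strictly after epoch 5, patience
        10 must stop training by epoch 15 and restore epoch 5."""
        rng = np.random.default_rng(5)
        seq, epi, y, chroms = toy_binary(rng, n=120)
        model = HmcModel(None, epi, y, chroms=chroms, task="binary",
                         modality="epi_only")
        script = iter([1.0 - 0.1 * e if e <= 5 else 0.5 + 0.05 * e
                       for e in range(200)])
        monkeypatch.setattr(HmcModel, "_eval_loss",
                            lambda self, *a, **k: next(script))
        res = model.fit(max_epochs=200, patience=10, batch_size=64, seed=0)
        assert len(res.training_log) == 16  # epochs 0..15
        assert res.best_epoch == 5

    def test_max_epochs_cap(self):
        rng = np.random.default_rng(6)
        seq, epi, y, chroms = toy_binary(rng, n=120)
        model = HmcModel(None, epi, y, chroms=chroms, task="binary",
                         modality="epi_only")
        res = model.fit(max_epochs=2, patience=10, batch_size=64, seed=0)
        assert len(res.training_log) == 2


class TestContinuousTask:
    def test_fit_and_metrics(self):
        rng = np.random.default_rng(7)
        n = 300
        epi = [rng.normal(5, 1, (n, 1, 41)).astype(np.float32)]
        y = epi[0][:, 0, 18:23].mean(axis=1).astype(float)
        chroms = np.array(["chr1"] * n)
        chroms[:60] = "chr7"
        chroms[60:120] = "chr8"
        model = HmcModel(None, epi, y, chroms=chroms, task="continuous",
                         modality="epi_only")
        res = model.fit(max_epochs=40, patience=40, batch_size=16, seed=0)
        met = res.evaluate("test")
        assert met["spearman_r"] > 0.7
        assert np.isfinite(res.predict_split("test")).all()
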