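"""Parameter arithmetic, forward/backward correctness, training contracts."""

import dataclasses

import numpy as np
import pytest

from ppgnet import model as M
from ppgnet.errors import ValidationError


def _closed_form(cfg: M.PPGNetConfig) -> tuple[int, int]:
    """Independent layer-by-layer parameter sum (the oracle)."""
    k = cfg.kernel
    sep = lambda m, n: k * k * m + m * n
    core, bn = 0, 0
    c = cfg.input_size[2]
    for w in cfg.stem_widths:
        core += k * k * c * w
        bn += w
        c = w
    for w in cfg.entry_widths:
        core += sep(c, w) + sep(w, w) + c * w
        bn += 3 * w
        c = w
    mw = cfg.resolved_middle_width()
    for _ in range(cfg.middle_blocks):
        core += 3 * sep(mw, mw)
        bn += 3 * mw
    c = mw
    for w in cfg.exit_widths:
        core += sep(c, w)
        bn += w
        c = w
    core += c * 4 + 4
    return core, (2 * bn if cfg.use_batch_normalization else 0)


CONFIG_GRID = [
    M.PPGNetConfig.desk_scale(),
    M.PPGNetConfig(),  # full-size default
    M.PPGNetConfig(input_size=(32, 32, 3), stem_widths=(4, 8), entry_widths=(16,),
                   middle_blocks=0, exit_widths=(24,)),
    M.PPGNetConfig(input_size=(64, 64, 3), stem_widths=(8, 16), entry_widths=(16, 32),
                   middle_blocks=3, exit_widths=(48, 64)),
    M.PPGNetConfig(input_size=(32, 32, 3), stem_widths=(4, 8), entry_widths=(16,),
                   middle_blocks=1, exit_widths=(24,), use_batch_normalization=False),
]


class TestParameterArithmetic:
    def test_separable_block_example(self):
        assert M.separable_conv_params(3, 32, 64) == 3 * 3 * 32 + 32 * 64 == 2336
        assert M.standard_conv_params(3, 32, 64) == 3 * 3 * 32 * 64 == 18432

    @pytest.mark.parametrize("cfg", CONFIG_GRID)
    def test_closed_form_matches_config_count(self, cfg):
        core, norm = _closed_form(cfg)
        pc = M.count_parameters(cfg)
        assert (pc.core, pc.norm) == (core, norm)

    @pytest.mark.parametrize("cfg", CONFIG_GRID[:1] + CONFIG_GRID[2:])
    def test_built_model_matches_closed_form(self, cfg):
        net = M.build_ppgnet(cfg, seed=0)
        built = net.parameter_count()
        expect = M.count_parameters(cfg)
        assert (built.core, built.norm, built.total) == (
            expect.core, expect.norm, expect.total
        )

    def test_middle_block_additivity(self):
        base = CONFIG_GRID[2]
        plus2 = dataclasses.replace(base, middle_blocks=base.middle_blocks + 2)
        per_block = 3 * M.separable_conv_params(3, 16, 16)
        assert (
            M.count_parameters(plus2).core - M.count_parameters(base).core
            == 2 * per_block
        )

    @pytest.mark.parametrize("k,m,n", [(3, 8, 16), (3, 2, 2), (5, 4, 10)])
    def test_separable_cheaper_than_standard(self, k, m, n):
        assert M.separable_conv_params(k, m, n) < M.standard_conv_params(k, m, n)


class TestForward:
    def test_softmax_probabilities_sum_to_one(self, rng):
        cfg = CONFIG_GRID[2]
        net = M.build_ppgnet(cfg, seed=1)
        x = rng.random((3, 32, 32, 3))
        p = M.softmax(net.forward(x))
        assert p.shape == (3, 4)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_final_dimension_is_four_classes(self, rng):
        net = M.build_ppgnet(CONFIG_GRID[2], seed=0)
        assert net.forward(rng.random((1, 32, 32, 3))).shape == (1, 4)

    def test_wrong_input_shape_rejected(self):
        net = M.build_ppgnet(CONFIG_GRID[2], seed=0)
        with pytest.raises(ValidationError):
            net.forward(np.zeros((1, 16, 16, 3)))

    def test_input_smaller_than_downsampling_rejected(self):
        with pytest.raises(ValidationError):
            M.PPGNetConfig(input_size=(6, 6, 3), stem_widths=(4, 8),
                           entry_widths=(16,), middle_blocks=0, exit_widths=(24,))

    def test_gradients_match_numerical(self, rng):
        cfg = M.PPGNetConfig(input_size=(16, 16, 3), stem_widths=(3, 4),
                             entry_widths=(6,), middle_blocks=1, exit_widths=(8,))
        net = M.build_ppgnet(cfg, seed=2)
        x = rng.random((2, 16, 16, 3)).astype(np.float32)
        y = np.array([0, 3])
        net.zero_grad()
        loss, dl = M.softmax_cross_entropy(net.forward(x, training=True), y)
        net.backward(dl)
        ps = net.params()
        check = np.random.default_rng(5)
        for pi in check.choice(len(ps), 5, replace=False):
            p = ps[pi]
            j = int(check.integers(p.value.size))
            flat, gflat = p.value.reshape(-1), p.grad.reshape(-1)
            eps, old = 1e-3, flat[j]
            flat[j] = old + eps
            lp = M.softmax_cross_entropy(net.forward(x, training=True), y)[0]
            flat[j] = old - eps
            lm = M.softmax_cross_entropy(net.forward(x, training=True), y)[0]
            flat[j] = old
            assert gflat[j] == pytest.approx((lp - lm) / (2 * eps), abs=2e-3)


class TestPredict:
    def test_argmax_label(self):
        net = M.build_ppgnet(CONFIG_GRID[2], seed=0)
        probs = np.array([[0.1, 0.7, 0.1, 0.1]])
        assert int(probs.argmax(axis=1)[0]) == 1  # label P

    def test_tie_breaks_to_lowest_index(self):
        probs = np.array([[0.25, 0.25, 0.25, 0.25]])
        assert int(probs.argmax(axis=1)[0]) == 0

    def test_batch_of_n_gives_n_labels(self, rng):
        net = M.build_ppgnet(CONFIG_GRID[2], seed=0)
        labels, probs = M.predict(net, rng.random((7, 32, 32, 3)))
        assert labels.shape == (7,) and probs.shape == (7, 4)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))


def _toy_data(n=36, size=16, seed=0):
    """Tiny 4-class image set with obvious class structure."""
    rng = np.random.default_rng(seed)
    x = rng.random((n, size, size, 3)).astype(np.float32) * 0.1
    y = np.arange(n) % 4
    for i in range(n):
        q = y[i]
        x[i, (q // 2) * (size // 2):(q // 2 + 1) * (size // 2),
          (q % 2) * (size // 2):(q % 2 + 1) * (size // 2)] += 0.8
    return x, y


class TestTraining:
    CFG = M.PPGNetConfig(input_size=(16, 16, 3), stem_widths=(4, 6),
                         entry_widths=(8,), middle_blocks=1, exit_widths=(12,))

    def test_loss_decreases_on_toy_problem(self):
        x, y = _toy_data()
        net = M.build_ppgnet(self.CFG, seed=3)
        res = M.fit(net, x, y, x[:8], y[:8],
                    M.TrainConfig(epochs=15, batch_size=12, seed=3,
                                  early_stop_patience=15))
        assert res.history["train_loss"][-1] < res.history["train_loss"][0]

    def test_early_stopping_on_constant_validation(self, monkeypatch):
        x, y = _toy_data()
        net = M.build_ppgnet(self.CFG, seed=1)
        # validation accuracy constant by construction: a single-class val
        # set the net nails from epoch 1 cannot improve further
        monkeypatch.setattr(
            M, "predict", lambda model, imgs, batch_size=32: (np.zeros(len(imgs), dtype=int), None)
        )
        res = M.fit(net, x, y, x[:4], np.zeros(4, dtype=int),
                    M.TrainConfig(epochs=50, batch_size=12, seed=1, early_stop_patience=3))
        assert res.stopped_early
        assert len(res.history["val_acc"]) < 50

    def test_same_seed_identical_history(self):
        x, y = _toy_data()
        cfg = M.TrainConfig(epochs=3, batch_size=12, seed=7)
        h1 = M.fit(M.build_ppgnet(self.CFG, seed=7), x, y, x[:8], y[:8], cfg).history
        h2 = M.fit(M.build_ppgnet(self.CFG, seed=7), x, y, x[:8], y[:8], cfg).history
        assert h1 == h2

    def test_best_weights_not_from_later_than_best_epoch(self):
        x, y = _toy_data()
        net = M.build_ppgnet(self.CFG, seed=2)
        res = M.fit(net, x, y, x[:8], y[:8],
                    M.TrainConfig(epochs=6, batch_size=12, seed=2, early_stop_patience=6))
        assert res.best_epoch <= len(res.history["val_acc"]) - 1
        assert res.history["val_acc"][res.best_epoch] == max(res.history["val_acc"])

    def test_empty_sets_rejected(self):
        x, y = _toy_data()
        net = M.build_ppgnet(self.CFG, seed=0)
        with pytest.raises(ValidationError):
            M.fit(net, x[:0], y[:0], x[:4], y[:4], M.TrainConfig(epochs=1, seed=0))

    def test_train_config_defaults_match_published_protocol(self):
        cfg = M.TrainConfig()
        assert (cfg.learning_rate, cfg.batch_size, cfg.epochs, cfg.folds) == (
            0.01, 12, 100, 5
        )


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = CONFIG_GRID[2]
        net = M.build_ppgnet(cfg, seed=4)
        x = rng.random((2, 32, 32, 3))
        before = net.forward(x)
        M.save_model(net, tmp_path / "w.npz", seed=4)
        back = M.load_model(tmp_path / "w.npz")
        np.testing.assert_allclose(back.forward(x), before, rtol=1e-6)
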