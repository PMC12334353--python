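import numpy as np
import pytest

from usinr import (
    InrConfig,
    evaluate,
    init_model,
    load_checkpoint,
    positional_encode,
    save_checkpoint,
)


class TestPositionalEncoding:
    @pytest.mark.parametrize("bands", range(0, 21))
    def test_dimension_formula(self, bands):
        x = np.zeros((4, 3), dtype=np.float32)
        assert positional_encode(x, bands).shape == (4, 3 * (1 + 2 * bands))

    def test_default_config_gives_93_features(self):
        cfg = InrConfig()
        assert cfg.pe_bands == 15
        assert cfg.input_dim == 93
        assert positional_encode(np.zeros((1, 3), np.float32), 15).shape[1] == 93

    def test_origin_encodes_to_zeros_and_ones(self):
        f = positional_encode(np.zeros((1, 3), np.float32), 4)[0]
        block = 1 + 2 * 4
        for axis in range(3):
            chunk = f[axis * block:(axis + 1) * block]
            assert chunk[0] == 0.0            # raw coordinate
            assert np.allclose(chunk[1::2], 0.0, atol=1e-6)  # sines
            assert np.allclose(chunk[2::2], 1.0, atol=1e-6)  # cosines

    def test_zero_bands_is_identity(self):
        x = np.array([[0.1, -0.5, 0.9]], dtype=np.float32)
        assert np.allclose(positional_encode(x, 0), x)

    def test_frequencies_double_per_band(self):
        x = np.array([[0.3, 0.0, 0.0]], dtype=np.float32)
        f = positional_encode(x, 3)[0]
        # sin entries for axis 0 at k = 1, 2, 4
        sins = f[1:7:2]
        assert sins == pytest.approx(np.sin([0.3, 0.6, 1.2]), abs=1e-6)


class TestInit:
    def test_same_seed_bit_identical(self):
        cfg = InrConfig(pe_bands=4, n_layers=4, width=16)
        a, b = init_model(cfg, seed=9), init_model(cfg, seed=9)
        for wa, wb in zip(a.core.parameters(), b.core.parameters()):
            assert np.array_equal(wa, wb)

    def test_first_layer_fan_in_matches_encoding(self):
        m = init_model(InrConfig(), seed=0)
        assert m.core.W[0].shape[0] == 93

    def test_hidden_preactivation_scale_near_unity(self):
        # SIREN init keeps sine pre-activations at O(1) scale
        cfg = InrConfig(pe_bands=10, n_layers=8, width=64)
        m = init_model(cfg, seed=1)
        rng = np.random.default_rng(2)
        coords = rng.uniform(-1, 1, size=(4096, 3)).astype(np.float32)
        feats = positional_encode(coords, cfg.pe_bands)
        a = feats
        core = m.core
        acts = [a]
        for i in range(len(core.W) - 1):
            z = (a @ core.W[i] + core.b[i]) * core.omega
            if i >= 1:  # hidden pre-activations should stay at unit scale
                assert 0.5 <= z.std() <= 2.0
            a = np.sin(z)
            src = core._skip_source(i, acts, a.shape)
            if src is not None:
                a = a + acts[src]
            acts.append(a)

    def test_parameter_count_matches_architecture(self):
        cfg = InrConfig(pe_bands=2, n_layers=3, width=8)
        m = init_model(cfg, seed=0)
        d_in = cfg.input_dim
        expected = (d_in * 8 + 8) + (8 * 8 + 8) + (8 * 2 + 2)
        assert m.n_parameters() == expected


class TestEvaluate:
    @pytest.fixture(scope="class")
    def model(self):
        return init_model(InrConfig(pe_bands=6, n_layers=5, width=16), seed=4,
                          coord_scale=(55.0, 82.0))

    def test_single_point_gives_one_pair(self, model):
        i, p = evaluate(model, np.array([[10.0, 0.0, 0.0]]))
        assert i.shape == (1,) and p.shape == (1,)
        assert 0.0 <= p[0] <= 1.0

    def test_purity(self, model):
        pts = np.random.default_rng(0).uniform(-30, 50, (64, 3))
        a = evaluate(model, pts)
        b = evaluate(model, pts)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiled_equals_single_pass(self, model):
        pts = np.random.default_rng(1).uniform(-30, 50, (1000, 3))
        a = evaluate(model, pts, tile=64)
        b = evaluate(model, pts, tile=10 ** 6)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_non_finite_coords_rejected(self, model):
        with pytest.raises(ValueError, match="finite"):
            evaluate(model, np.array([[np.nan, 0.0, 0.0]]))

    def test_output_bounded_on_cube(self, model):
        # finite outputs with a finite sampled gradient bound (no blowups)
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1, 1, (2048, 3)) * np.array([27.5, 41.0, 41.0]) + \
            np.array([27.5, 0.0, 0.0])
        i, p = evaluate(model, pts)
        assert np.isfinite(i).all() and np.isfinite(p).all()
        d = rng.normal(scale=1e-3, size=pts.shape)
        i2, _ = evaluate(model, pts + d)
        slope = np.abs(i2 - i) / np.linalg.norm(d, axis=1)
        assert np.isfinite(slope).all()
        assert slope.max() < 1e4


class TestBackward:
    def test_parameter_gradients_match_finite_differences(self):
        # scalar loss = sum of outputs; checks matmuls, sine chain, omega
        # scaling and the additive skip routing all at once
        cfg = InrConfig(pe_bands=2, n_layers=6, width=10)
        m = init_model(cfg, seed=3)
        core = m.core
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (7, cfg.input_dim)).astype(np.float32)
        out = core.forward(X, want_cache=True)
        grads = core.backward(np.ones_like(out))
        n_w = len(core.W)
        h = 1e-3
        for layer, (i, j) in [(0, (1, 2)), (2, (4, 7)), (3, (0, 0)), (5, (9, 1))]:
            W = core.W[layer]
            W[i, j] += h
            up = core.forward(X).sum()
            W[i, j] -= 2 * h
            down = core.forward(X).sum()
            W[i, j] += h
            num = (up - down) / (2 * h)
            assert grads[layer][i, j] == pytest.approx(num, rel=2e-2, abs=1e-4)
        # bias gradient of a middle layer
        b = core.b[2]
        b[5] += h
        up = core.forward(X).sum()
        b[5] -= 2 * h
        down = core.forward(X).sum()
        b[5] += h
        assert grads[n_w + 2][5] == pytest.approx((up - down) / (2 * h),
                                                  rel=2e-2, abs=1e-4)


class TestCheckpoint:
    def test_round_trip_restores_exact_outputs(self, tmp_path):
        m = init_model(InrConfig(pe_bands=5, n_layers=4, width=12), seed=7,
                       coord_scale=(55.0, 82.0))
        pts = np.random.default_rng(5).uniform(0, 50, (128, 3))
        before = evaluate(m, pts)
        meta = save_checkpoint(m, tmp_path / "ckpt.npz")
        restored = load_checkpoint(tmp_path / "ckpt.npz")
        after = evaluate(restored, pts)
        assert np.array_equal(before[0], after[0])
        assert np.array_equal(before[1], after[1])
        assert meta["n_parameters"] == m.n_parameters()
        assert restored.coord_scale == (55.0, 82.0)

    def test_tampered_config_raises_shape_error(self, tmp_path):
        import json
        m = init_model(InrConfig(pe_bands=5, n_layers=4, width=12), seed=7)
        save_checkpoint(m, tmp_path / "ckpt.npz")
        sidecar = tmp_path / "ckpt.json"
        meta = json.loads(sidecar.read_text())
        meta["config"]["width"] = 99
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="shape"):
            load_checkpoint(tmp_path / "ckpt.npz")
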