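"""Dual-encoder contrastive pretraining and feature extraction."""

import numpy as np
import pytest

from fusemil.encoder import (EncoderConfig, augment_pair, build_encoder,
                             contrastive_loss, encode_tiles, momentum_update,
                             pretrain_encoder, sample_pretraining_tiles)
from fusemil.tissue import TileSet

TINY = dict(img_size=32, patch_size=8, d_model=16, n_layers=1, n_heads=2,
            d_ff=32, d=24, proj_hidden=16, proj_dim=8, batch_size=8)


def distinct_tiles(n, seed, size=32):
    """Each tile has its own base color and low-frequency pattern, so
    instance discrimination is learnable."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size] / size
    tiles = []
    for _ in range(n):
        base = rng.uniform(0.2, 0.8, size=3)
        pat = 0.2 * np.sin(2 * np.pi * (rng.uniform(0.5, 2) * xx +
                                        rng.uniform(0.5, 2) * yy))[..., None]
        tiles.append(np.clip(base + pat, 0, 1))
    return tiles


class TestSampling:
    def _tilesets(self, sizes):
        return [TileSet(slide_id=f"S{i}", tile_size=224, magnification=10.0,
                        coords=np.arange(2 * n).reshape(n, 2) * 224)
                for i, n in enumerate(sizes)]

    def test_clamped_to_available(self):
        out = sample_pretraining_tiles(self._tilesets([5]), per_slide=20, seed=0)
        assert len(out) == 5

    def test_total_arithmetic(self):
        out = sample_pretraining_tiles(self._tilesets([25] * 10), per_slide=20, seed=0)
        assert len(out) == 200

    def test_determinism_and_no_replacement(self):
        ts = self._tilesets([30])
        a = sample_pretraining_tiles(ts, per_slide=10, seed=5)
        b = sample_pretraining_tiles(ts, per_slide=10, seed=5)
        assert a == b and len(set(a)) == 10

    def test_empty_tileset_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="no tiles"):
            out = sample_pretraining_tiles(self._tilesets([0, 4]), per_slide=2, seed=0)
        assert len(out) == 2


class TestAugment:
    def test_zero_strength_is_identity(self):
        tile = distinct_tiles(1, 0)[0]
        v1, v2 = augment_pair(tile, seed=1, crop_scale=0, jitter=0, flip_prob=0)
        assert np.array_equal(v1, tile) and np.array_equal(v2, tile)

    def test_same_seed_same_pair(self):
        tile = distinct_tiles(1, 1)[0]
        p1 = augment_pair(tile, seed=9)
        p2 = augment_pair(tile, seed=9)
        assert np.array_equal(p1[0], p2[0]) and np.array_equal(p1[1], p2[1])

    def test_views_differ_at_positive_strength(self):
        tile = distinct_tiles(1, 2)[0]
        v1, v2 = augment_pair(tile, seed=3)
        assert np.linalg.norm(v1 - v2) > 0
        assert v1.shape == tile.shape == v2.shape


class TestMomentum:
    def _pair(self):
        cfg = EncoderConfig(**TINY, seed=0)
        state = build_encoder(cfg)
        for t in state.query_params.values():
            t.data = t.data + 1.0
        return state

    def test_m_one_keeps_key(self):
        state = self._pair()
        before = {k: t.data.copy() for k, t in state.key_params.items()}
        momentum_update(state.key_params, state.query_params, 1.0)
        assert all(np.array_equal(state.key_params[k].data, before[k])
                   for k in before)

    def test_m_zero_copies_query(self):
        state = self._pair()
        momentum_update(state.key_params, state.query_params, 0.0)
        assert all(np.array_equal(state.key_params[k].data,
                                  state.query_params[k].data)
                   for k in state.key_params)

    def test_analytic_value(self):
        state = self._pair()
        kp = state.key_params["embed.b"]
        qp = state.query_params["embed.b"]
        kp.data[:] = 1.0
        qp.data[:] = 0.0
        momentum_update(state.key_params, state.query_params, 0.99)
        assert np.allclose(kp.data, 0.99)

    def test_shape_mismatch_rejected(self):
        state = self._pair()
        state.key_params["embed.b"].data = np.zeros(3)
        with pytest.raises(ValueError, match="shape mismatch"):
            momentum_update(state.key_params, state.query_params, 0.5)


class TestContrastiveLoss:
    def test_hand_value_two_orthonormal_pairs(self):
        q = np.eye(2)
        assert contrastive_loss(q, q, 1.0) == pytest.approx(
            -np.log(np.e / (np.e + 1)))

    def test_degenerate_case_equals_log_batch(self):
        v = np.tile([1.0, 0.0], (6, 1))
        assert contrastive_loss(v, v, 0.2) == pytest.approx(np.log(6))

    def test_rotation_invariance(self, rng):
        q = rng.normal(size=(5, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        k = rng.normal(size=(5, 4))
        k /= np.linalg.norm(k, axis=1, keepdims=True)
        rot, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert contrastive_loss(q, k, 0.3) == pytest.approx(
            contrastive_loss(q @ rot, k @ rot, 0.3))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.eye(2), np.eye(2), 0.0)


class TestPretrain:
    def test_zero_lr_leaves_query_and_key_unchanged(self):
        cfg = EncoderConfig(**TINY, lr=0.0, momentum=1.0, steps=2, seed=0)
        tiles = distinct_tiles(10, 0)
        init = build_encoder(cfg)
        state = pretrain_encoder(tiles, cfg)
        for name in init.query_params:
            assert np.array_equal(state.query_params[name].data,
                                  init.query_params[name].data)
            assert np.array_equal(state.key_params[name].data,
                                  init.key_params[name].data)

    def test_loss_decreases_over_training(self):
        cfg = EncoderConfig(**TINY, lr=3e-3, steps=50, seed=0)
        traces = []
        for seed in range(2):
            cfg_s = EncoderConfig(**TINY, lr=3e-3, steps=50, seed=seed)
            state = pretrain_encoder(distinct_tiles(32, seed), cfg_s)
            traces.append(state.loss_trace)
        tr = np.mean(traces, axis=0)
        assert tr[-10:].mean() < tr[:10].mean()

    def test_key_params_replay_momentum_recursion(self):
        """The key trajectory equals the EMA recursion applied to the
        recorded query trajectory."""
        cfg = EncoderConfig(**{**TINY, "batch_size": 4}, lr=1e-3, momentum=0.9,
                            steps=4, seed=1)
        tiles = distinct_tiles(8, 1)
        # instrumented rerun: capture query params after each step
        import fusemil.encoder as enc
        history = []
        orig = enc.momentum_update

        def spy(key_params, query_params, m):
            history.append({k: t.data.copy() for k, t in query_params.items()})
            return orig(key_params, query_params, m)

        enc.momentum_update = spy
        try:
            state = pretrain_encoder(tiles, cfg)
        finally:
            enc.momentum_update = orig
        init = build_encoder(cfg)
        replay = {k: t.data.copy() for k, t in init.query_params.items()}
        for q in history:
            for k in replay:
                replay[k] = 0.9 * replay[k] + 0.1 * q[k]
        for k in replay:
            assert np.allclose(state.key_params[k].data, replay[k], atol=1e-12)


class TestEncode:
    def test_empty_bag(self):
        state = build_encoder(EncoderConfig(**TINY, seed=0))
        bag = encode_tiles(state, [])
        assert bag.features.shape == (0, 24)

    def test_repeat_call_bit_identical_and_params_untouched(self):
        state = build_encoder(EncoderConfig(**TINY, seed=0))
        tiles = distinct_tiles(3, 4)
        before = {k: t.data.copy() for k, t in state.query_params.items()}
        b1 = encode_tiles(state, tiles)
        b2 = encode_tiles(state, tiles)
        assert np.array_equal(b1.features, b2.features)
        assert all(np.array_equal(state.query_params[k].data, before[k])
                   for k in before)

    def test_row_order_matches_tiles(self):
        state = build_encoder(EncoderConfig(**TINY, seed=0))
        tiles = distinct_tiles(4, 5)
        full = encode_tiles(state, tiles).features
        flipped = encode_tiles(state, tiles[::-1]).features
        assert np.allclose(full, flipped[::-1])
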