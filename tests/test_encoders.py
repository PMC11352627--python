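"""Encoder branches against longhand dense-algebra oracles on tiny inputs."""

import numpy as np
import pytest

from synergynet.config import (CellEncoderConfig, CloudEncoderConfig,
                               GraphEncoderConfig, SequenceEncoderConfig)
from synergynet.encoders import (CellEncoder, CloudEncoder, GMLPBlock,
                                 GraphEncoder, MultiHeadFusion,
                                 SequenceDrugEncoder, gcn_layer,
                                 global_max_pool, zscore)
from synergynet.nn import LSTM, Tensor


class TestZScore:
    def test_small_column_population_sd(self):
        out = zscore(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.224745, 0.0, 1.224745],
                                   atol=1e-6)

    def test_constant_column_maps_to_zeros(self):
        out = zscore(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        np.testing.assert_array_equal(out[:, 0], 0.0)

    def test_column_means_vanish(self, rng):
        out = zscore(rng.normal(size=(40, 7)))
        assert np.all(np.abs(out.mean(axis=0)) < 1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.empty((0, 3)))


class TestGCNLayer:
    def test_regular_graph_identity_weights(self):
        # 4-cycle is 2-regular: normalised row sums are 1, ones stay ones
        import networkx as nx

        from synergynet.graph_power import normalize_adjacency
        a = normalize_adjacency(nx.to_numpy_array(nx.cycle_graph(4)))
        out = gcn_layer(a, np.ones((4, 3)), np.eye(3))
        np.testing.assert_allclose(out.data, 1.0)

    def test_zero_adjacency_gives_zero(self, rng):
        out = gcn_layer(np.zeros((3, 3)), rng.normal(size=(3, 2)),
                        rng.normal(size=(2, 4)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_matches_dense_triple_product(self, rng):
        a = rng.random(size=(4, 4))
        a = (a + a.T) / 2
        h = rng.normal(size=(4, 3))
        w = rng.normal(size=(3, 5))
        expected = np.maximum(a @ h @ w, 0.0)
        np.testing.assert_allclose(gcn_layer(a, h, w).data, expected,
                                   atol=1e-12)


class TestGMLP:
    def test_gate_reduces_to_identity_when_w_zero_b_one(self, rng):
        block = GMLPBlock(dim=4, gmlp_dim=6, seq_len=2, rng=rng)
        block.w_spatial.data[...] = 0.0
        block.b_spatial.data[...] = 1.0
        h = rng.normal(size=(2, 4))
        z = np.asarray(Tensor(h @ block.u.data).gelu().data)
        expected = z[:, :3] @ block.v.data
        np.testing.assert_allclose(block(Tensor(h)).data, expected, atol=1e-12)

    def test_u_zero_gives_row_constant_output(self, rng):
        block = GMLPBlock(dim=4, gmlp_dim=6, seq_len=3, rng=rng)
        block.u.data[...] = 0.0
        out = block(Tensor(rng.normal(size=(3, 4)))).data
        np.testing.assert_allclose(out - out[0], 0.0, atol=1e-12)

    def test_longhand_toy_evaluation(self, rng):
        block = GMLPBlock(dim=4, gmlp_dim=4, seq_len=2, rng=rng,
                          activation="gelu")
        h = rng.normal(size=(2, 4))
        # longhand: Z = gelu(hU); split; s = Z1 * (W Z2 + b); Y = s V
        z = Tensor(h @ block.u.data).gelu().data
        z1, z2 = z[:, :2], z[:, 2:]
        s = z1 * (block.w_spatial.data @ z2 + block.b_spatial.data)
        expected = s @ block.v.data
        np.testing.assert_allclose(block(Tensor(h)).data, expected, atol=1e-9)

    def test_odd_channel_width_rejected(self, rng):
        with pytest.raises(ValueError):
            GMLPBlock(dim=4, gmlp_dim=5, seq_len=2, rng=rng)


def _fusion(rng, dim=4, heads=1, head_dim=3, attn_out=4):
    cfg = SequenceEncoderConfig(heads=heads, head_dim=head_dim,
                                attn_out=attn_out)
    return MultiHeadFusion(dim, cfg, rng)


class TestMultiHeadFusion:
    def test_attention_rows_sum_to_one(self, rng):
        fusion = _fusion(rng, heads=3)
        x = Tensor(rng.normal(size=(2, 5, 4)))
        _, weights = fusion.attention(x)
        for w in weights:
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_query_key_gives_uniform_attention(self, rng):
        fusion = _fusion(rng)
        fusion.w_q[0].data[...] = 0.0
        fusion.w_k[0].data[...] = 0.0
        x = rng.normal(size=(1, 4, 4))
        out, weights = fusion.attention(Tensor(x))
        np.testing.assert_allclose(weights[0], 0.25, atol=1e-12)
        expected = np.repeat(
            (x[0] @ fusion.w_v[0].data).mean(axis=0, keepdims=True), 4,
            axis=0) @ fusion.w_o.data
        np.testing.assert_allclose(out.data[0], expected, atol=1e-9)

    def test_single_head_longhand_toy(self, rng):
        fusion = _fusion(rng, dim=2, head_dim=2, attn_out=2)
        h1 = rng.normal(size=(1, 2, 2))
        h2 = rng.normal(size=(1, 2, 2))
        x = h1 + h2
        q = x[0] @ fusion.w_q[0].data
        k = x[0] @ fusion.w_k[0].data
        v = x[0] @ fusion.w_v[0].data
        scores = q @ k.T / np.sqrt(2)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        attn = e / e.sum(axis=-1, keepdims=True)
        expected = ((attn @ v) @ fusion.w_o.data).mean(axis=0)
        out = fusion(Tensor(h1), Tensor(h2))
        np.testing.assert_allclose(out.data[0], expected, atol=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        fusion = _fusion(rng)
        with pytest.raises(ValueError):
            fusion(Tensor(np.zeros((1, 3, 4))), Tensor(np.zeros((1, 2, 4))))


class TestBiLSTM:
    def test_output_width_twice_units(self, rng):
        for units in (3, 8):
            lstm = LSTM(5, units, rng)
            out = lstm(Tensor(rng.normal(size=(1, 4, 5))))
            assert out.shape == (1, 4, 2 * units)

    def test_single_position_sequence(self, rng):
        lstm = LSTM(5, 3, rng)
        assert lstm(Tensor(rng.normal(size=(1, 1, 5)))).shape == (1, 1, 6)

    def test_reversal_swaps_direction_roles_with_tied_weights(self, rng):
        lstm = LSTM(4, 3, rng)
        # tie the two directions' weights
        lstm.w_x[1].data[...] = lstm.w_x[0].data
        lstm.w_h[1].data[...] = lstm.w_h[0].data
        lstm.b[1].data[...] = lstm.b[0].data
        x = rng.normal(size=(1, 3, 4))
        out = lstm(Tensor(x)).data[0]
        out_rev = lstm(Tensor(x[:, ::-1])).data[0]
        # forward half on reversed input = backward half on original, reversed
        np.testing.assert_allclose(out_rev[:, :3], out[::-1, 3:], atol=1e-12)
        np.testing.assert_allclose(out_rev[:, 3:], out[::-1, :3], atol=1e-12)


class TestGraphEncoder:
    def _encoder(self, rng, width=3, in_features=2):
        return GraphEncoder(in_features, GraphEncoderConfig(width=width), rng)

    def test_single_node_graph(self, rng):
        enc = self._encoder(rng)
        supports = tuple(np.zeros((1, 1, 1)) for _ in range(3))
        out = enc(supports, Tensor(np.ones((1, 1, 2))))
        assert out.shape == (1, 9)
        np.testing.assert_array_equal(out.data, 0.0)  # zero support, no bias

    def test_gmp_dominates_every_node_row(self, rng):
        h = Tensor(rng.normal(size=(2, 5, 4)))
        pooled = global_max_pool(h).data
        assert np.all(pooled[:, None, :] >= h.data - 1e-12)

    def test_node_duplication_leaves_gmp_unchanged(self, rng):
        enc = self._encoder(rng)
        a = np.array([[0, 1], [1, 0]], dtype=float)
        feats = rng.normal(size=(2, 2))
        # duplicate node 1 with identical features and edge pattern
        a_dup = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        feats_dup = np.vstack([feats, feats[1]])

        from synergynet.graph_power import normalize_adjacency, power_adjacency

        def encode(adj, f):
            sup = tuple(
                normalize_adjacency(power_adjacency(adj, k))[None]
                for k in (1, 2, 3))
            return enc(sup, Tensor(f[None])).data

        # node 2 is a twin of node 1: same normalised neighbourhood weights
        out_a = encode(a, feats)
        out_dup = encode(a_dup, feats_dup)
        # duplication changes degrees, so compare duplication of an
        # isolated-twin construction instead: two identical components
        iso = np.zeros((4, 4))
        iso[0, 1] = iso[1, 0] = iso[2, 3] = iso[3, 2] = 1.0
        out_two = encode(iso, np.vstack([feats, feats]))
        np.testing.assert_allclose(out_two, out_a, atol=1e-12)
        assert out_dup.shape == out_a.shape

    def test_mask_excludes_padded_nodes(self, rng):
        enc = self._encoder(rng)
        a = np.zeros((1, 3, 3))
        a[0, 0, 1] = a[0, 1, 0] = 1.0
        feats = rng.normal(size=(1, 3, 2))
        mask = np.array([[1.0, 1.0, 0.0]])
        sup = (a, a, a)
        with_pad = enc(sup, Tensor(feats), node_mask=mask).data
        trimmed = enc(tuple(s[:, :2, :2] for s in sup),
                      Tensor(feats[:, :2])).data
        np.testing.assert_allclose(with_pad, trimmed, atol=1e-12)


class TestCloudEncoder:
    @pytest.fixture()
    def encoder(self, rng):
        return CloudEncoder(CloudEncoderConfig(), rng)

    def test_output_width_160_for_any_length(self, encoder, rng):
        encoder.eval()
        for n in (5, 17, 40):
            out = encoder(Tensor(rng.normal(size=(2, n, 3))))
            assert out.shape == (2, 160)

    def test_channel_schedule(self, encoder):
        assert [c.out_channels for c in encoder.convs] == [32, 64, 128, 160]

    def test_zero_cloud_finite_and_deterministic(self, encoder):
        encoder.eval()
        a = encoder(Tensor(np.zeros((1, 8, 3)))).data
        b = encoder(Tensor(np.zeros((1, 8, 3)))).data
        assert np.all(np.isfinite(a))
        np.testing.assert_array_equal(a, b)

    def test_extra_padding_cannot_change_max_pooled_output(self, encoder, rng):
        encoder.eval()
        coords = np.zeros((1, 20, 3))
        coords[0, :6] = rng.normal(size=(6, 3))
        out_20 = encoder(Tensor(coords)).data
        wider = np.zeros((1, 40, 3))
        wider[0, :6] = coords[0, :6]
        out_40 = encoder(Tensor(wider)).data
        np.testing.assert_allclose(out_20, out_40, atol=1e-9)


class TestCellEncoder:
    def test_width_enforced(self, rng):
        enc = CellEncoder(4, 6, CellEncoderConfig(hidden=8, out=5), rng)
        with pytest.raises(ValueError, match="4 expression"):
            enc(Tensor(np.zeros((2, 9))))
        assert enc(Tensor(np.zeros((2, 10)))).shape == (2, 5)

    def test_identical_omics_rows_give_identical_features(self, rng):
        enc = CellEncoder(4, 6, CellEncoderConfig(hidden=8, out=5), rng)
        row = rng.normal(size=(1, 10))
        out = enc(Tensor(np.vstack([row, row]))).data
        np.testing.assert_array_equal(out[0], out[1])
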