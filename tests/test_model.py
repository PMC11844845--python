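"""The neural architecture: functional ops, encoders, training."""

import numpy as np
import pytest

import powerdta as pk
from conftest import (
    mhla_loop,
    permute_graph,
    reference_drug_encoder,
    reference_protein_encoder,
)

RNG = np.random.default_rng(321)


class TestGcnLayer:
    def test_zero_weights_zero_output(self):
        H = RNG.normal(size=(4, 3))
        M = np.eye(4)
        assert np.array_equal(pk.gcn_layer(H, M, np.zeros((3, 3))), np.zeros((4, 3)))

    def test_identity_relu_fixed_point(self):
        H = np.abs(RNG.normal(size=(5, 4)))
        out = pk.gcn_layer(H, np.eye(5), np.eye(4))
        assert np.array_equal(out, H)

    def test_matches_dense_oracle(self):
        H = RNG.normal(size=(5, 6))
        W = RNG.normal(size=(6, 4))
        M = RNG.normal(size=(5, 5))
        M = 0.5 * (M + M.T)
        expected = np.maximum(M.dot(H).dot(W), 0)
        assert np.allclose(pk.gcn_layer(H, M, W), expected, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pk.gcn_layer(np.ones((3, 2)), np.eye(4), np.ones((2, 2)))


class TestGatedSkip:
    @pytest.fixture
    def pair(self):
        return RNG.normal(size=(4, 6)), RNG.normal(size=(4, 6))

    def test_saturated_open_gate_returns_new(self, pair):
        h_new, h_old = pair
        gate = pk.GateParams(np.zeros((6, 6)), np.zeros((6, 6)), np.full(6, 20.0))
        assert np.max(np.abs(pk.gated_skip(h_new, h_old, gate) - h_new)) < 1e-8

    def test_saturated_closed_gate_returns_old(self, pair):
        h_new, h_old = pair
        gate = pk.GateParams(np.zeros((6, 6)), np.zeros((6, 6)), np.full(6, -20.0))
        assert np.max(np.abs(pk.gated_skip(h_new, h_old, gate) - h_old)) < 1e-8

    def test_zero_gate_gives_midpoint(self, pair):
        h_new, h_old = pair
        gate = pk.GateParams(np.zeros((6, 6)), np.zeros((6, 6)), np.zeros(6))
        assert np.allclose(pk.gated_skip(h_new, h_old, gate), (h_new + h_old) / 2)

    def test_output_is_convex_combination(self, pair):
        h_new, h_old = pair
        gate = pk.GateParams(RNG.normal(size=(6, 6)), RNG.normal(size=(6, 6)),
                             RNG.normal(size=6))
        out = pk.gated_skip(h_new, h_old, gate)
        lo = np.minimum(h_new, h_old)
        hi = np.maximum(h_new, h_old)
        assert np.all(out >= lo - 1e-12)
        assert np.all(out <= hi + 1e-12)

    def test_shape_mismatch_rejected(self):
        gate = pk.GateParams(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError):
            pk.gated_skip(np.ones((2, 2)), np.ones((3, 2)), gate)


class TestLinearAttentionWeights:
    def test_zero_weight_uniform(self):
        states = RNG.normal(size=(6, 4))
        mask = np.array([True] * 5 + [False])
        w = pk.linear_attention_weights(np.zeros(4), states, mask)
        assert np.allclose(w[:5], 0.2)
        assert w[5] == 0.0

    def test_single_unmasked_position(self):
        states = RNG.normal(size=(4, 3))
        mask = np.array([False, True, False, False])
        w = pk.linear_attention_weights(RNG.normal(size=3), states, mask)
        assert w[1] == 1.0
        assert np.array_equal(np.delete(w, 1), np.zeros(3))

    def test_matches_naive_softmax(self):
        states = RNG.normal(size=(7, 5))
        head = RNG.normal(size=5)
        mask = np.ones(7, dtype=bool)
        d_k = np.sqrt(5)
        scores = states @ head / d_k
        naive = np.exp(scores) / np.exp(scores).sum()  # unstabilized
        assert np.allclose(pk.linear_attention_weights(head, states, mask), naive,
                           atol=1e-9)

    def test_weights_sum_to_one_over_unmasked(self):
        for _ in range(20):
            m = int(RNG.integers(2, 15))
            states = RNG.normal(size=(m, 6)) * 10
            mask = RNG.random(m) < 0.7
            if not mask.any():
                mask[0] = True
            w = pk.linear_attention_weights(RNG.normal(size=6), states, mask)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.array_equal(w[~mask], np.zeros((~mask).sum()))

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            pk.linear_attention_weights(np.zeros(3), np.ones((4, 3)),
                                        np.zeros(4, dtype=bool))


class TestMhlaPool:
    def test_single_zero_head_is_mean(self):
        states = RNG.normal(size=(6, 4))
        mask = np.array([True] * 4 + [False] * 2)
        params = pk.MhlaParams([np.zeros(4)], n_heads=1, d_k=2.0)
        assert np.allclose(pk.mhla_pool(states, mask, params),
                           states[:4].mean(axis=0))

    def test_eight_zero_heads_is_eight_times_mean(self):
        states = RNG.normal(size=(5, 3))
        mask = np.ones(5, dtype=bool)
        params = pk.MhlaParams([np.zeros(3)] * 8, n_heads=8, d_k=1.7)
        assert np.allclose(pk.mhla_pool(states, mask, params),
                           8 * states.mean(axis=0))

    def test_matches_loop_oracle(self):
        states = RNG.normal(size=(9, 5))
        mask = RNG.random(9) < 0.8
        mask[0] = True
        heads = [RNG.normal(size=5) for _ in range(4)]
        params = pk.MhlaParams(heads, n_heads=4, d_k=np.sqrt(5))
        assert np.allclose(pk.mhla_pool(states, mask, params),
                           mhla_loop(states, mask, heads, params.d_k), atol=1e-8)


class TestPmgcnEncode:
    def test_output_length_is_embed_dim(self, tiny_model, sample_smiles):
        for s in sample_smiles[:5]:
            g = pk.smiles_to_graph(s)
            ps = pk.build_power_set(g)
            vec = pk.pmgcn_encode(g, ps, tiny_model)
            assert vec.shape == (tiny_model.config.embed_dim,)

    def test_atom_relabeling_invariance(self, tiny_model, sample_smiles):
        rng = np.random.default_rng(15)
        for s in sample_smiles[:8]:
            g = pk.smiles_to_graph(s)
            base = pk.pmgcn_encode(g, pk.build_power_set(g), tiny_model)
            perm = rng.permutation(g.n_atoms)
            gp = permute_graph(g, perm)
            out = pk.pmgcn_encode(gp, pk.build_power_set(gp), tiny_model)
            assert np.allclose(out, base, atol=1e-5)

    def test_matches_reference_encoder(self, tiny_model):
        g = pk.smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O")
        ps = pk.build_power_set(g)
        assert np.allclose(pk.pmgcn_encode(g, ps, tiny_model),
                           reference_drug_encoder(g, ps, tiny_model), atol=1e-6)


class TestAmcnnEncode:
    def test_output_length_is_embed_dim(self, tiny_model):
        prot = pk.encode_protein("MKVLAWHKWHACDEF", max_len=64)
        assert pk.amcnn_encode(prot, tiny_model).shape == (
            tiny_model.config.embed_dim,)

    def test_padding_extension_invariance(self, tiny_model):
        seq = "MKVLAWHKWHACDEFGHIKLMNP"
        short = pk.encode_protein(seq, max_len=40)
        long = pk.encode_protein(seq, max_len=64)
        assert np.allclose(pk.amcnn_encode(short, tiny_model),
                           pk.amcnn_encode(long, tiny_model), atol=1e-6)

    def test_matches_mhla_reference(self, tiny_model):
        prot = pk.encode_protein("MKVLAWHKWHACDEFGHIK", max_len=32)
        assert np.allclose(pk.amcnn_encode(prot, tiny_model),
                           reference_protein_encoder(prot, tiny_model, "mhla"),
                           atol=1e-8)

    @pytest.mark.parametrize("pool", ["max", "mean"])
    def test_matches_pool_reference(self, tiny_config, pool):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, pool=pool)
        model = pk.AffinityModel(cfg)
        prot = pk.encode_protein("MKVLAWHKWHACDEFGHIK", max_len=32)
        assert np.allclose(pk.amcnn_encode(prot, model),
                           reference_protein_encoder(prot, model, pool), atol=1e-6)


class TestPredictAffinity:
    def test_eval_mode_bitwise_determinism(self, tiny_model):
        d = RNG.normal(size=16)
        p = RNG.normal(size=16)
        a = pk.predict_affinity(d, p, tiny_model)
        b = pk.predict_affinity(d, p, tiny_model)
        assert a == b

    def test_batched_predictions(self, tiny_model, small_table):
        preds = tiny_model.predict(small_table, batch_size=7)
        assert preds.shape == (len(small_table),)
        single = tiny_model.predict(small_table[:1])
        assert preds[0] == pytest.approx(single[0], abs=1e-9)

    def test_zeroed_head_outputs_zero(self, tiny_config):
        model = pk.AffinityModel(tiny_config)
        for k, t in model.params.items():
            if k.startswith("head."):
                t.data[...] = 0.0
        assert pk.predict_affinity(np.ones(16), np.ones(16), model) == 0.0

    def test_dimension_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            pk.predict_affinity(np.ones(5), np.ones(16), tiny_model)


@pytest.fixture(scope="module")
def quick_cfg():
    return pk.ModelConfig.desk(
        embed_dim=16, hidden_dim=12, protein_embed_dim=8, conv_channels=10,
        n_heads=2, max_len=64, head_dims=(24, 12), batch_size=16, epochs=3,
        seed=21,
    )


class TestTraining:

    def test_zero_learning_rate_leaves_parameters(self, small_table, quick_cfg):
        import dataclasses

        cfg = dataclasses.replace(quick_cfg, learning_rate=0.0, epochs=2)
        before = pk.AffinityModel(cfg).state_copy()
        model, _ = pk.train_model(small_table, None, cfg)
        after = model.state_copy()
        for k in before:
            assert np.array_equal(before[k], after[k])

    def test_epoch_zero_log_is_untrained_mse(self, small_table, quick_cfg):
        import dataclasses

        cfg = dataclasses.replace(quick_cfg, epochs=1)
        model_init = pk.AffinityModel(cfg)
        # untrained predictions use the training labels' mean/sd scaling
        labels = np.array([r.label for r in small_table])
        model_init.label_mean = labels.mean()
        model_init.label_std = labels.std()
        expected = pk.mse(labels, model_init.predict(small_table))
        _, log = pk.train_model(small_table, None, cfg)
        assert log[0]["epoch"] == 0
        assert log[0]["train_mse"] == pytest.approx(expected, rel=1e-9)

    def test_seeded_training_reproducible(self, small_table, quick_cfg):
        m1, log1 = pk.train_model(small_table, None, quick_cfg)
        m2, log2 = pk.train_model(small_table, None, quick_cfg)
        assert log1 == log2
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data)

    def test_validation_selects_best_checkpoint(self, small_table, quick_cfg):
        plan = pk.random_split(small_table, seed=1)
        model, log = pk.train_model(small_table, plan, quick_cfg)
        val = [e["val_mse"] for e in log]
        test_recs = [small_table[i] for i in plan.test_indices]
        y = np.array([r.label for r in test_recs])
        achieved = pk.mse(y, model.predict(test_recs))
        assert achieved == pytest.approx(min(val), rel=1e-9)

    def test_training_reduces_loss(self, small_table, quick_cfg):
        import dataclasses

        cfg = dataclasses.replace(quick_cfg, epochs=15)
        _, log = pk.train_model(small_table, None, cfg)
        assert log[-1]["train_mse"] < log[0]["train_mse"]

    def test_empty_split_rejected(self, small_table, quick_cfg):
        plan = pk.SplitPlan(mode="random", train_indices=[],
                            test_indices=list(range(len(small_table))))
        with pytest.raises(ValueError):
            pk.train_model(small_table, plan, quick_cfg)

    def test_checkpoint_round_trip(self, small_table, quick_cfg, tmp_path):
        model, _ = pk.train_model(small_table, None, quick_cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        back = pk.AffinityModel.load(path)
        assert np.allclose(model.predict(small_table), back.predict(small_table),
                           atol=0)
        assert back.config == model.config
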