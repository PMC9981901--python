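import numpy as np
import pytest

from mogat import (
    GRUParams,
    HyperParams,
    build_graph,
    forward,
    gru_update,
    init_node_states,
    init_params,
    load_checkpoint,
    save_checkpoint,
)
from mogat.attention import leaky_relu
from mogat.model import count_params

from conftest import permute_graph
from reference import reference_forward


def _zero_tree(params):
    if isinstance(params, dict):
        return {k: _zero_tree(v) for k, v in params.items()}
    if isinstance(params, list):
        return [_zero_tree(v) for v in params]
    return np.zeros_like(params)


class TestGRU:
    def test_all_zero_parameters_halve_the_state(self):
        d = 4
        p = GRUParams(W_r=np.zeros((d, 2 * d)), W_z=np.zeros((d, 2 * d)),
                      W_h=np.zeros((d, 2 * d)))
        h = np.array([1.0, -2.0, 0.5, 3.0])
        st = gru_update(h, np.zeros(d), p)
        np.testing.assert_allclose(st.r, 0.5)
        np.testing.assert_allclose(st.z, 0.5)
        np.testing.assert_allclose(st.h_candidate, 0.0)
        np.testing.assert_allclose(st.h_new, 0.5 * h)

    def test_saturated_update_gate_keeps_previous_state(self):
        d = 3
        big = 1e4 * np.ones((d, 2 * d))
        p = GRUParams(W_r=np.zeros((d, 2 * d)), W_z=big, W_h=np.ones((d, 2 * d)))
        h, c = np.full(d, 0.5), np.full(d, 0.5)
        st = gru_update(h, c, p)
        np.testing.assert_allclose(st.h_new, h, atol=1e-6)

    def test_closed_update_gate_returns_candidate(self):
        d = 3
        p = GRUParams(W_r=np.zeros((d, 2 * d)), W_z=-1e4 * np.ones((d, 2 * d)),
                      W_h=np.ones((d, 2 * d)))
        h, c = np.full(d, 0.5), np.full(d, 0.5)
        st = gru_update(h, c, p)
        np.testing.assert_allclose(st.h_new, st.h_candidate, atol=1e-6)

    def test_dimension_mismatch(self):
        p = GRUParams(W_r=np.zeros((3, 5)), W_z=np.zeros((3, 5)),
                      W_h=np.zeros((3, 5)))
        with pytest.raises(ValueError, match="dimension"):
            gru_update(np.zeros(3), np.zeros(3), p)

    def test_gate_bounds_hold_for_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = int(rng.integers(1, 8))
            p = GRUParams(*(rng.normal(size=(d, 2 * d)) for _ in range(3)))
            st = gru_update(rng.normal(size=d), rng.normal(size=d), p)
            assert np.all((st.r > 0) & (st.r < 1))
            assert np.all((st.z > 0) & (st.z < 1))
            assert np.all(np.abs(st.h_candidate) < 1)


class TestInitNodeStates:
    def test_zero_projection(self, fixtures, small_hyper):
        params = init_params(small_hyper)
        params["proj"] = np.zeros_like(params["proj"])
        states = init_node_states(fixtures["CNN"], params)
        np.testing.assert_array_equal(states, 0.0)

    def test_matches_matrix_multiply_oracle(self, fixtures, small_params):
        g = fixtures["CNN"]
        states = init_node_states(g, small_params)
        X = g.atom_matrix()
        for v in range(g.n_atoms):
            expected = np.asarray(leaky_relu(small_params["proj"] @ X[v]))
            np.testing.assert_allclose(states[v], expected, atol=1e-8)


class TestForward:
    def test_single_atom_uses_self_loop(self, fixtures, small_hyper, small_params):
        res = forward(fixtures["C"], small_params, small_hyper)
        for S in res.trace.edge_attention:
            np.testing.assert_allclose(S, [[1.0]], atol=1e-12)
        for a in res.trace.atom_attention:
            np.testing.assert_allclose(a, [1.0], atol=1e-12)

    def test_symmetric_two_atom_graph_stays_symmetric(self, fixtures,
                                                      small_hyper, small_params):
        res = forward(fixtures["pair"], small_params, small_hyper)
        for H in res.trace.node_states:
            np.testing.assert_allclose(H[0], H[1], atol=1e-10)
        for a in res.trace.atom_attention:
            np.testing.assert_allclose(a, [0.5, 0.5], atol=1e-10)

    @pytest.mark.parametrize("name", ["CNN", "path3", "synthetic_path3"])
    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_straight_line_oracle(self, fixtures, name, seed):
        hyper = HyperParams(d_g=8, kappa=2, tau=2, dropout_rate=0.0, seed=seed)
        params = init_params(hyper)
        g = fixtures[name]
        got = forward(g, params, hyper)
        ref = reference_forward(g, params, hyper)
        assert got.prediction == pytest.approx(ref["prediction"], abs=1e-8)
        for a, b in zip(got.trace.atom_attention, ref["atom_attention"]):
            np.testing.assert_allclose(a, b, atol=1e-8)
        np.testing.assert_allclose(got.trace.layer_weights,
                                   ref["layer_weights"], atol=1e-8)

    def test_all_zero_params_predict_the_bias(self, fixtures, small_hyper,
                                              small_params):
        params = _zero_tree(small_params)
        params["fc"]["b"] = np.array(1.23)
        res = forward(fixtures["CNN"], params, small_hyper)
        assert res.prediction == pytest.approx(1.23, abs=1e-12)

    def test_single_layer_fusion_is_identity(self, fixtures):
        hyper = HyperParams(d_g=8, kappa=1, tau=2, dropout_rate=0.0, seed=4)
        params = init_params(hyper)
        res = forward(fixtures["CNN"], params, hyper)
        assert res.trace.layer_weights.shape == (1, 1)
        np.testing.assert_allclose(res.trace.layer_weights, [[1.0]])
        np.testing.assert_allclose(res.trace.final_embedding,
                                   res.trace.super_states[0], atol=1e-12)

    def test_attention_rows_normalized(self, fixtures, small_hyper, small_params):
        res = forward(fixtures["CNN"], small_params, small_hyper)
        for S in res.trace.edge_attention:
            np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-6)
        for a in res.trace.atom_attention:
            assert a.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(res.trace.layer_weights.sum(axis=1), 1.0,
                                   atol=1e-6)

    @pytest.mark.parametrize("smiles", ["CNN", "CC(N)C(=O)O", "c1ccccc1O"])
    def test_permutation_invariance(self, smiles, small_hyper, small_params):
        g = build_graph(smiles)
        base = forward(g, small_params, small_hyper).prediction
        rng = np.random.default_rng(0)
        for _ in range(3):
            perm = rng.permutation(g.n_atoms)
            gp = permute_graph(g, perm)
            assert forward(gp, small_params, small_hyper).prediction == \
                pytest.approx(base, abs=1e-5)

    def test_forward_is_bitwise_deterministic(self, fixtures, small_hyper,
                                              small_params):
        a = forward(fixtures["CNN"], small_params, small_hyper)
        b = forward(fixtures["CNN"], small_params, small_hyper)
        assert a.prediction == b.prediction
        for x, y in zip(a.trace.node_states, b.trace.node_states):
            assert np.array_equal(x, y)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, small_hyper, small_params):
        path = tmp_path / "model.npz"
        save_checkpoint(path, small_params, small_hyper,
                        metadata={"best_epoch": 7})
        params, hyper, meta = load_checkpoint(path)
        assert hyper == small_hyper
        assert meta["best_epoch"] == 7
        np.testing.assert_array_equal(params["proj"], small_params["proj"])
        np.testing.assert_array_equal(
            params["atom_layers"][0]["gru"]["W_r"],
            small_params["atom_layers"][0]["gru"]["W_r"],
        )

    def test_parameter_count_scales_with_hyperparams(self):
        small = count_params(init_params(HyperParams(d_g=8, kappa=1, tau=1)))
        bigger = count_params(init_params(HyperParams(d_g=8, kappa=3, tau=1)))
        assert bigger > small
        # tau adds no parameters: super-node updates share one block per layer
        same_tau = count_params(init_params(HyperParams(d_g=8, kappa=1, tau=5)))
        assert same_tau == small
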