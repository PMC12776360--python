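"""Core attention stack vs direct per-formula oracles on tiny graphs."""

import numpy as np
import pytest

from dcgat import core
from dcgat.autodiff import Tensor, constant
from dcgat.core import (
    cns_policy,
    dcgat_forward,
    gcn_norm_adjacency,
    gumbel_softmax_st,
    init_params,
    intra_attention_coeffs,
    cross_attention_coeffs,
    layer_update,
)
from dcgat.graphs import build_graph
from dcgat.io import EmbeddingMatrix


def _emb(values, modality="protein"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    prefix = "P" if modality == "protein" else "D"
    return EmbeddingMatrix(
        [f"{prefix}{i}" for i in range(len(values))], values, modality
    )


def _leaky(x, slope=0.2):
    return x if x > 0 else slope * x


def _elu(x):
    return np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1.0)


def _softmax(v):
    e = np.exp(v - np.max(v))
    return e / e.sum()


@pytest.fixture
def tiny(rng):
    """5 proteins, 4 drugs, shared width 3, with moderately dense graphs."""
    x = rng.standard_normal((5, 3))
    y = rng.standard_normal((4, 3))
    g_p = build_graph(_emb(x), {"percentile": 60.0})
    g_d = build_graph(_emb(y, "drug"), {"percentile": 60.0})
    params = init_params(3, 3, 3, n_layers=2, n_heads=2, cns_hidden=4,
                         head_hidden=(4,), seed=1)
    return x, y, g_p, g_d, params


class TestCNSPolicy:
    def test_rows_are_distributions(self, tiny):
        x, y, g_p, g_d, params = tiny
        rho = cns_policy(constant(x), constant(y), gcn_norm_adjacency(g_d),
                         params, "l0_cns_p")
        assert rho.shape == (5, 4, 2)
        np.testing.assert_allclose(rho.data.sum(axis=-1), 1.0, atol=1e-6)
        assert (rho.data > 0).all()

    def test_identical_candidates_get_identical_rows(self, rng):
        # two drugs with equal embeddings in an identical (complete) graph
        y = np.tile(rng.standard_normal(3), (3, 1))
        x = rng.standard_normal((2, 3))
        g_d = build_graph(_emb(y, "drug"), {"absolute": 1.0})
        params = init_params(3, 3, 3, 1, 1, cns_hidden=4, seed=0)
        rho = cns_policy(constant(x), constant(y), gcn_norm_adjacency(g_d),
                         params, "l0_cns_p")
        np.testing.assert_allclose(rho.data[:, 0], rho.data[:, 1], atol=1e-12)
        np.testing.assert_allclose(rho.data[:, 0], rho.data[:, 2], atol=1e-12)

    def test_gradient_matches_finite_difference(self, tiny, rng):
        x, y, g_p, g_d, params = tiny
        weights = rng.standard_normal((5, 4, 2))
        a_hat = gcn_norm_adjacency(g_d)

        def loss_value(x_arr):
            rho = cns_policy(constant(x_arr), constant(y), a_hat, params, "l0_cns_p")
            return float((rho.data * weights).sum())

        xt = Tensor(x, requires_grad=True)
        rho = cns_policy(xt, constant(y), a_hat, params, "l0_cns_p")
        (rho * constant(weights)).sum().backward()
        h = 1e-5
        for idx in [(0, 0), (2, 1), (4, 2)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (loss_value(xp) - loss_value(xm)) / (2 * h)
            assert xt.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_empty_cross_side_rejected(self, tiny):
        x, *_ , params = tiny
        with pytest.raises(ValueError, match="empty"):
            cns_policy(constant(x), constant(np.zeros((0, 3))),
                       np.zeros((0, 0)), params, "l0_cns_p")


class TestGumbelSoftmaxST:
    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            gumbel_softmax_st(constant([[0.5, 0.5]]), 0.0, np.random.default_rng(0))

    def test_noise_free_unit_temperature_recovers_distribution(self):
        rho = constant([[0.3, 0.7], [0.9, 0.1]])
        soft = gumbel_softmax_st(rho, 1.0, noise=False, hard=False)
        np.testing.assert_allclose(soft.data, [0.3, 0.9], atol=1e-9)

    def test_forward_values_exactly_binary(self, rng):
        rho = constant(np.full((50, 2), 0.5))
        a = gumbel_softmax_st(rho, 0.7, rng)
        assert set(np.unique(a.data)) <= {0.0, 1.0}

    def test_select_frequency_tracks_probability(self, rng):
        rho = constant(np.tile([0.999, 0.001], (1000, 1)))
        a = gumbel_softmax_st(rho, 0.1, rng)
        assert a.data.mean() >= 0.99

    def test_fair_row_frequency_near_half(self, rng):
        rho = constant(np.tile([0.5, 0.5], (10000, 1)))
        a = gumbel_softmax_st(rho, 1.0, rng)
        assert a.data.mean() == pytest.approx(0.5, abs=0.02)

    def test_soft_selection_increases_with_temperature(self, rng):
        # policy favoring "not select": hard frequency stays at rho_select,
        # the expected soft selection rises toward 0.5 with temperature
        rho = constant(np.tile([0.2, 0.8], (300, 1)))
        cold = gumbel_softmax_st(rho, 0.1, np.random.default_rng(1), hard=False)
        hot = gumbel_softmax_st(rho, 5.0, np.random.default_rng(1), hard=False)
        assert hot.data.mean() > cold.data.mean()

    def test_straight_through_gradient_matches_soft_path(self):
        logits = Tensor(np.array([[0.4, -0.3]]), requires_grad=True)
        values = np.array([2.0, 0.0])

        def run(hard):
            rho = core._softmax_last(logits)
            a = gumbel_softmax_st(rho, 0.8, np.random.default_rng(3), hard=hard)
            return (a * constant(values[:1])).sum()

        run(True).backward()
        grad_hard = logits.grad.copy()
        logits.grad = None
        run(False).backward()
        np.testing.assert_allclose(grad_hard, logits.grad, atol=1e-12)
        assert np.abs(grad_hard).max() > 0

        # soft path agrees with finite differences (same Gumbel draws)
        def scalar(arr):
            t = Tensor(arr)
            rho = core._softmax_last(t)
            a = gumbel_softmax_st(rho, 0.8, np.random.default_rng(3), hard=False)
            return float((a.data * values[:1]).sum())

        h = 1e-6
        base = logits.data.copy()
        for idx in [(0, 0), (0, 1)]:
            xp, xm = base.copy(), base.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (scalar(xp) - scalar(xm)) / (2 * h)
            assert logits.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_probability_floor_applied(self, rng):
        rho = constant([[1.0, 0.0]])
        a = gumbel_softmax_st(rho, 1.0, rng)
        assert np.isfinite(a.data).all()


class TestAttentionCoefficients:
    def test_single_neighbor_gets_full_weight(self, rng):
        d = 3
        alpha = intra_attention_coeffs(
            rng.standard_normal(d), rng.standard_normal((1, d)),
            rng.standard_normal((d, d)), rng.standard_normal(2 * d),
        )
        np.testing.assert_allclose(alpha, [1.0])

    def test_identical_neighbors_share_weight(self, rng):
        d = 3
        nbr = rng.standard_normal(d)
        alpha = intra_attention_coeffs(
            rng.standard_normal(d), np.tile(nbr, (2, 1)),
            rng.standard_normal((d, d)), rng.standard_normal(2 * d),
        )
        np.testing.assert_allclose(alpha, [0.5, 0.5], atol=1e-12)

    def test_matches_direct_formula(self, rng):
        d = 4
        xi = rng.standard_normal(d)
        nbrs = rng.standard_normal((3, d))
        w = 0.3 * rng.standard_normal((d, d))
        phi = 0.3 * rng.standard_normal(2 * d)
        alpha = intra_attention_coeffs(xi, nbrs, w, phi)
        scores = [
            _leaky(np.concatenate([xi @ w, xr @ w]) @ phi) for xr in nbrs
        ]
        np.testing.assert_allclose(alpha, _softmax(np.array(scores)), atol=1e-6)

    def test_cross_coeffs_match_direct_formula(self, rng):
        d = 4
        pi = rng.standard_normal(d)
        sel = rng.standard_normal((4, d))
        w = 0.3 * rng.standard_normal((d, d))
        phi = 0.3 * rng.standard_normal(2 * d)
        beta = cross_attention_coeffs(pi, sel, w, phi)
        scores = [
            _leaky(np.concatenate([pi @ w, dj @ w]) @ phi) for dj in sel
        ]
        np.testing.assert_allclose(beta, _softmax(np.array(scores)), atol=1e-6)
        assert beta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_over_identical_selected_candidates(self, rng):
        d = 3
        cand = np.tile(rng.standard_normal(d), (5, 1))
        beta = cross_attention_coeffs(
            rng.standard_normal(d), cand,
            rng.standard_normal((d, d)), rng.standard_normal(2 * d),
        )
        np.testing.assert_allclose(beta, np.full(5, 0.2), atol=1e-12)


def gat_intra_oracle(x, adj, w, phi, w1):
    """Plain graph-attention aggregation, evaluated neighbor-by-neighbor."""
    m = len(x)
    out = np.zeros((m, w1.shape[1]))
    for i in range(m):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) == 0:
            continue
        scores = np.array(
            [_leaky(np.concatenate([x[i] @ w, x[r] @ w]) @ phi) for r in nbrs]
        )
        a = _softmax(scores)
        out[i] = sum(ar * (x[r] @ w1) for ar, r in zip(a, nbrs))
    return _elu(out)


class TestLayerUpdate:
    def test_empty_selection_reduces_to_intra_only_gat(self, tiny):
        x, y, g_p, g_d, params = tiny
        p_new, d_new = layer_update(
            constant(x), constant(y), g_p, g_d, None, None,
            params, layer=0, n_heads=1, include_self=True,
        )
        pre = "l0_h0"
        expected_p = gat_intra_oracle(
            x, g_p.adjacency(include_self=True),
            params[f"{pre}_Wp"].data, params[f"{pre}_phip"].data,
            params[f"{pre}_W1p"].data,
        )
        expected_d = gat_intra_oracle(
            y, g_d.adjacency(include_self=True),
            params[f"{pre}_Wd"].data, params[f"{pre}_phid"].data,
            params[f"{pre}_W1d"].data,
        )
        np.testing.assert_allclose(p_new.data, expected_p, atol=1e-6)
        np.testing.assert_allclose(d_new.data, expected_d, atol=1e-6)

    def test_all_zero_selection_equals_no_selection(self, tiny):
        x, y, g_p, g_d, params = tiny
        zero_p = constant(np.zeros((5, 4)))
        zero_d = constant(np.zeros((4, 5)))
        with_zeros = layer_update(
            constant(x), constant(y), g_p, g_d, zero_p, zero_d,
            params, 0, 1,
        )
        without = layer_update(
            constant(x), constant(y), g_p, g_d, None, None, params, 0, 1
        )
        np.testing.assert_allclose(with_zeros[0].data, without[0].data, atol=1e-12)
        np.testing.assert_allclose(with_zeros[1].data, without[1].data, atol=1e-12)

    def test_zero_state_maps_to_zero_output(self, tiny):
        x, y, g_p, g_d, params = tiny
        ones_p = constant(np.ones((5, 4)))
        ones_d = constant(np.ones((4, 5)))
        p_new, d_new = layer_update(
            constant(np.zeros_like(x)), constant(np.zeros_like(y)),
            g_p, g_d, ones_p, ones_d, params, 0, 2,
        )
        np.testing.assert_allclose(p_new.data, 0.0, atol=1e-12)
        np.testing.assert_allclose(d_new.data, 0.0, atol=1e-12)

    def test_identical_heads_equal_single_head(self, tiny, rng):
        x, y, g_p, g_d, _ = tiny
        params3 = init_params(3, 3, 3, 1, 3, cns_hidden=4, seed=5)
        for head in (1, 2):
            for side in ("p", "d"):
                for name in ("W", "phi", "Wcr", "phicr", "W1", "W2"):
                    params3[f"l0_h{head}_{name}{side}"].data = params3[
                        f"l0_h0_{name}{side}"
                    ].data.copy()
        sel_p = constant((rng.uniform(size=(5, 4)) < 0.5).astype(float))
        sel_d = constant((rng.uniform(size=(4, 5)) < 0.5).astype(float))
        multi = layer_update(constant(x), constant(y), g_p, g_d,
                             sel_p, sel_d, params3, 0, 3)
        single = layer_update(constant(x), constant(y), g_p, g_d,
                              sel_p, sel_d, params3, 0, 1)
        np.testing.assert_allclose(multi[0].data, single[0].data, atol=1e-10)
        np.testing.assert_allclose(multi[1].data, single[1].data, atol=1e-10)

    def test_full_update_matches_direct_formula_oracle(self, tiny, rng):
        """Protein update: ELU over intra + cross sums, per the displayed update."""
        x, y, g_p, g_d, params = tiny
        sel = (rng.uniform(size=(5, 4)) < 0.6).astype(float)
        p_new, _ = layer_update(
            constant(x), constant(y), g_p, g_d,
            constant(sel), constant(np.zeros((4, 5))), params, 0, 1,
        )
        pre = "l0_h0"
        w, phi = params[f"{pre}_Wp"].data, params[f"{pre}_phip"].data
        wcr, phicr = params[f"{pre}_Wcrp"].data, params[f"{pre}_phicrp"].data
        w1, w2 = params[f"{pre}_W1p"].data, params[f"{pre}_W2p"].data
        adj = g_p.adjacency(include_self=True)
        for i in range(5):
            nbrs = np.flatnonzero(adj[i])
            scores = np.array(
                [_leaky(np.concatenate([x[i] @ w, x[r] @ w]) @ phi) for r in nbrs]
            )
            alpha = _softmax(scores)
            agg = sum(a * (x[r] @ w1) for a, r in zip(alpha, nbrs))
            chosen = np.flatnonzero(sel[i])
            if len(chosen):
                cs = np.array(
                    [_leaky(np.concatenate([x[i] @ wcr, y[j] @ wcr]) @ phicr)
                     for j in chosen]
                )
                beta = _softmax(cs)
                agg = agg + sum(b * (y[j] @ w2) for b, j in zip(beta, chosen))
            np.testing.assert_allclose(p_new.data[i], _elu(agg), atol=1e-6)


class TestDcgatForward:
    def test_zero_layers_returns_projections(self, tiny, rng):
        x, y, g_p, g_d, params = tiny
        p, d, log = dcgat_forward(x, y, g_p, g_d, params, 0, 2, 1.0,
                                  np.random.default_rng(0))
        np.testing.assert_allclose(p.data, x @ params["proj_p"].data)
        np.testing.assert_allclose(d.data, y @ params["proj_d"].data)
        assert log == []

    def test_same_seed_bitwise_identical(self, tiny):
        x, y, g_p, g_d, params = tiny
        runs = [
            dcgat_forward(x, y, g_p, g_d, params, 2, 2, 1.0,
                          np.random.default_rng(42))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0][0].data, runs[1][0].data)
        np.testing.assert_array_equal(runs[0][1].data, runs[1][1].data)

    def test_selection_log_fractions_are_means_of_bits(self, tiny):
        x, y, g_p, g_d, params = tiny
        _, _, log = dcgat_forward(x, y, g_p, g_d, params, 2, 1, 1.0,
                                  np.random.default_rng(7))
        assert len(log) == 2
        for entry in log:
            for key, n_candidates in (
                ("protein_selected_fraction", 4),
                ("drug_selected_fraction", 5),
            ):
                frac = entry[key]
                assert ((frac >= 0) & (frac <= 1)).all()
                # hard bits: fraction * candidate count is an integer
                np.testing.assert_allclose(
                    frac * n_candidates, np.round(frac * n_candidates), atol=1e-9
                )

    def test_eval_mode_deterministic_without_rng(self, tiny):
        x, y, g_p, g_d, params = tiny
        a = dcgat_forward(x, y, g_p, g_d, params, 2, 2, 1.0, None,
                          train_mode=False)
        b = dcgat_forward(x, y, g_p, g_d, params, 2, 2, 1.0, None,
                          train_mode=False)
        np.testing.assert_array_equal(a[0].data, b[0].data)

    def test_permutation_equivariance_over_drugs(self, rng):
        x = rng.standard_normal((6, 4))
        y = rng.standard_normal((5, 4))
        g_p = build_graph(_emb(x), {"percentile": 50.0})
        g_d = build_graph(_emb(y, "drug"), {"percentile": 50.0})
        params = init_params(4, 4, 4, 2, 2, cns_hidden=4, seed=3)
        p1, d1, _ = dcgat_forward(x, y, g_p, g_d, params, 2, 2, 1.0, None,
                                  train_mode=False)
        perm = rng.permutation(5)
        y_perm = y[perm]
        g_d_perm = build_graph(_emb(y_perm, "drug"), {"percentile": 50.0})
        p2, d2, _ = dcgat_forward(x, y_perm, g_p, g_d_perm, params, 2, 2, 1.0,
                                  None, train_mode=False)
        np.testing.assert_allclose(p2.data, p1.data, atol=1e-8)
        np.testing.assert_allclose(d2.data, d1.data[perm], atol=1e-8)

    def test_end_to_end_gradient_reaches_policy_parameters(self, tiny):
        x, y, g_p, g_d, params = tiny
        rng = np.random.default_rng(11)
        p, d, _ = dcgat_forward(x, y, g_p, g_d, params, 1, 1, 1.0, rng)
        (p.sum() + d.sum()).backward()
        g = params["l0_cns_p_out"].grad
        assert g is not None and np.abs(g).max() > 0
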