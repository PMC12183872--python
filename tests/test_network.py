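import numpy as np
import pytest
import scipy.sparse as sp

from spotview.config import RunConfig
from spotview.network import (BatchDesign, apply_batch_correction, attend,
                              decode, encode, forward, fuse, init_params,
                              project_cluster, project_instance,
                              restore_batch)


def _small_config(**kw):
    defaults = dict(n_pcs=3, d1=4, d=3, d2=4, d3=2, f=3, n_domains=2)
    defaults.update(kw)
    return RunConfig(**defaults)


def _random_setup(rng, m=6, n=3, L=1, config=None):
    config = config or _small_config()
    X = rng.standard_normal((m, n))
    A = sp.random(m, m, density=0.4, random_state=1, format="csr")
    A = A + sp.identity(m)
    A2 = sp.random(m, m, density=0.4, random_state=2, format="csr")
    A2 = A2 + sp.identity(m)
    idx = np.sort(rng.integers(1, L + 1, size=m)) if L > 1 else np.ones(m, int)
    idx[:L] = np.arange(1, L + 1)  # every slice populated
    E = BatchDesign.from_slice_index(np.sort(idx)).E
    params = init_params(n, E.shape[1], config, rng)
    return params, X, sp.csr_matrix(A), sp.csr_matrix(A2), E, config


class TestBatchCorrection:
    def test_zero_prompts_are_identity(self, rng):
        X = rng.standard_normal((4, 3))
        E = np.eye(4)[:, :2][:, [0, 0, 1, 1]].T.T
        E = np.zeros((4, 2)); E[:2, 0] = 1; E[2:, 1] = 1
        np.testing.assert_array_equal(
            apply_batch_correction(X, np.zeros((2, 3)), E), X)

    def test_single_slice_constant_shift(self, rng):
        X = rng.standard_normal((5, 3))
        c = rng.standard_normal((1, 3))
        out = apply_batch_correction(X, c, np.ones((5, 1)))
        np.testing.assert_allclose(out, X - c, atol=1e-12)

    def test_known_shifts_inverted_exactly(self, rng):
        base = rng.standard_normal((6, 4))
        shifts = rng.standard_normal((2, 4))
        E = np.zeros((6, 2)); E[:3, 0] = 1; E[3:, 1] = 1
        shifted = base + E @ shifts
        np.testing.assert_allclose(
            apply_batch_correction(shifted, shifts, E), base, atol=1e-12)


class TestEncode:
    def test_identity_network_passes_nonneg_input(self, rng):
        m, n = 4, 3
        X = rng.random((m, n))  # nonneg -> ELU is identity
        I = sp.identity(m, format="csr")
        W11 = np.eye(n)
        W12 = np.eye(n)
        Z = encode((I, I), X, W11, W12)
        np.testing.assert_allclose(Z, X, atol=1e-12)

    def test_matches_dense_reference(self, rng):
        m, n, d1, d = 4, 3, 2, 2
        A = rng.random((m, m))
        X = rng.standard_normal((m, n))
        W11, W12 = rng.standard_normal((n, d1)), rng.standard_normal((d1, d))

        def elu_ref(x):
            return np.where(x > 0, x, np.expm1(np.minimum(x, 0)))

        expected = elu_ref(A @ elu_ref(A @ X @ W11) @ W12)
        Z = encode((sp.csr_matrix(A), sp.csr_matrix(A)), X, W11, W12)
        np.testing.assert_allclose(Z, expected, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        m, n = 6, 3
        A = sp.csr_matrix(rng.random((m, m)))
        X = rng.standard_normal((m, n))
        W11, W12 = rng.standard_normal((n, 4)), rng.standard_normal((4, 2))
        perm = rng.permutation(m)
        P = np.eye(m)[perm]
        Ap = sp.csr_matrix(P @ A.toarray() @ P.T)
        Z = np.asarray(encode((A, A), X, W11, W12))
        Zp = np.asarray(encode((Ap, Ap), X[perm], W11, W12))
        np.testing.assert_allclose(Zp, Z[perm], atol=1e-8)


class TestProjections:
    def test_cluster_head_rows_on_simplex(self, rng):
        Z = rng.standard_normal((5, 3))
        Q = project_cluster(Z, rng.standard_normal((3, 4)),
                            rng.standard_normal((4, 3)))
        assert np.all(Q >= 0)
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_output_weights_give_uniform(self, rng):
        Z = rng.standard_normal((4, 3))
        Q = project_cluster(Z, rng.standard_normal((3, 4)), np.zeros((4, 5)))
        np.testing.assert_allclose(Q, 1 / 5, atol=1e-12)

    def test_instance_head_matches_dense_reference(self, rng):
        Z = rng.standard_normal((3, 2))
        W21, W22 = rng.standard_normal((2, 3)), rng.standard_normal((3, 2))
        expected = np.maximum(Z @ W21, 0) @ W22
        np.testing.assert_allclose(project_instance(Z, W21, W22), expected,
                                   atol=1e-6)


class TestAttention:
    def test_equal_views_give_half(self, rng):
        Z = rng.standard_normal((4, 3))
        a_spa, a_expr = attend(Z, Z, rng.standard_normal((3, 2)),
                               rng.standard_normal((2, 1)))
        np.testing.assert_allclose(a_spa, 0.5, atol=1e-12)
        np.testing.assert_allclose(a_spa + a_expr, 1.0, atol=1e-12)

    def test_saturation_toward_dominant_view(self):
        # huge positive score on the spatial view drives its weight to 1
        Z_spa = np.full((2, 2), 50.0)
        Z_expr = np.full((2, 2), -50.0)
        W41 = np.ones((2, 1)) * 10
        W42 = np.ones((1, 1)) * 10
        a_spa, _ = attend(Z_spa, Z_expr, W41, W42)
        np.testing.assert_allclose(a_spa, 1.0, atol=1e-8)

    def test_two_spot_scalar_softmax_hand_case(self):
        Z_spa = np.array([[1.0, 0.0], [0.0, 1.0]])
        Z_expr = np.array([[0.0, 1.0], [1.0, 0.0]])
        W41 = np.array([[1.0], [2.0]])
        W42 = np.array([[1.0]])
        att_s = np.tanh(Z_spa @ W41) @ W42
        att_e = np.tanh(Z_expr @ W41) @ W42
        expect = np.exp(att_s) / (np.exp(att_s) + np.exp(att_e))
        a_spa, _ = attend(Z_spa, Z_expr, W41, W42)
        np.testing.assert_allclose(a_spa[:, :1], expect, atol=1e-8)
        assert np.allclose(a_spa, a_spa[:, :1])  # constant across columns


class TestFuseDecode:
    def test_fuse_limits_and_mean(self, rng):
        Zs, Ze = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        ones = np.ones_like(Zs)
        np.testing.assert_array_equal(fuse(Zs, Ze, ones, 0 * ones), Zs)
        np.testing.assert_allclose(fuse(Zs, Ze, ones / 2, ones / 2),
                                   (Zs + Ze) / 2, atol=1e-8)

    def test_fuse_matches_elementwise_loop(self, rng):
        Zs, Ze = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        a = rng.random((3, 2))
        out = fuse(Zs, Ze, a, 1 - a)
        for i in range(3):
            for j in range(2):
                assert out[i, j] == pytest.approx(
                    a[i, j] * Zs[i, j] + (1 - a[i, j]) * Ze[i, j], abs=1e-8)

    def test_identity_chain_decodes_input(self, rng):
        Z = rng.random((4, 3))  # nonneg
        I3 = np.eye(3)
        out = decode(restore_batch(Z, np.zeros((1, 3)), np.ones((4, 1))),
                     I3, I3)
        np.testing.assert_allclose(out, Z, atol=1e-12)

    def test_decoder_matches_dense_reference(self, rng):
        Z = rng.standard_normal((3, 2))
        W12 = rng.standard_normal((4, 2))
        W11 = rng.standard_normal((5, 4))
        expected = np.maximum(Z @ W12.T, 0) @ W11.T
        np.testing.assert_allclose(decode(Z, W12, W11), expected, atol=1e-6)


class TestForward:
    def test_invariants_over_random_configs(self, rng):
        for _ in range(100):
            m = int(rng.integers(4, 9))
            n = int(rng.integers(2, 5))
            params, X, A, A2, E, cfg = _random_setup(
                rng, m=m, n=n,
                config=_small_config(n_pcs=n, n_domains=int(rng.integers(2, 5))))
            params = {k: (v if k.startswith("B") else rng.standard_normal(v.shape))
                      for k, v in params.items()}
            out = forward(params, X, A, A2, E)
            np.testing.assert_allclose(np.asarray(out.Q_spa).sum(axis=1), 1,
                                       atol=1e-6)
            assert np.all(np.asarray(out.Q_expr) >= 0)
            np.testing.assert_allclose(
                np.asarray(out.alpha_spa) + np.asarray(out.alpha_expr), 1,
                atol=1e-6)
            # fused embedding is a per-entry convex combination
            lo = np.minimum(out.Z_spa, out.Z_expr) - 1e-9
            hi = np.maximum(out.Z_spa, out.Z_expr) + 1e-9
            assert np.all(out.Z >= lo) and np.all(out.Z <= hi)

    def test_single_slice_reduces_bitwise_without_batch_module(self, rng):
        params, X, A, A2, E, cfg = _random_setup(rng, L=1)
        out = forward(params, X, A, A2, E)
        # manual chain without the batch ops
        Z_spa = encode((A, A), X, params["W11"], params["W12"])
        Z_expr = encode((A2, A2), X, params["W11"], params["W12"])
        a_s, a_e = attend(Z_spa, Z_expr, params["W41"], params["W42"])
        Z = fuse(Z_spa, Z_expr, a_s, a_e)
        X_hat = decode(Z, params["W12"], params["W11"])
        np.testing.assert_array_equal(np.asarray(out.Z), np.asarray(Z))
        np.testing.assert_array_equal(np.asarray(out.X_hat), np.asarray(X_hat))

    def test_forward_deterministic(self, rng):
        params, X, A, A2, E, cfg = _random_setup(rng)
        o1 = forward(params, X, A, A2, E)
        o2 = forward(params, X, A, A2, E)
        np.testing.assert_array_equal(np.asarray(o1.X_hat),
                                      np.asarray(o2.X_hat))

    def test_full_permutation_equivariance(self, rng):
        params, X, A, A2, E, cfg = _random_setup(rng, m=7, L=1)
        perm = rng.permutation(7)
        P = np.eye(7)[perm]
        Ap = sp.csr_matrix(P @ A.toarray() @ P.T)
        A2p = sp.csr_matrix(P @ A2.toarray() @ P.T)
        out = forward(params, X, A, A2, E)
        outp = forward(params, X[perm], Ap, A2p, E[perm])
        for field in ("Z_spa", "Z_expr", "Q_spa", "H_expr", "Z", "X_hat"):
            np.testing.assert_allclose(np.asarray(getattr(outp, field)),
                                       np.asarray(getattr(out, field))[perm],
                                       atol=1e-8)


def test_gradient_matches_finite_differences(rng):
    """Autodiff gradient of the full objective vs central differences."""
    from autograd import grad

    from spotview import losses

    # wide enough heads that no ReLU output row dies under random weights
    params, X, A, A2, E, cfg = _random_setup(
        rng, m=5, n=3, L=2, config=_small_config(d2=16, f=4))

    def objective(p):
        out = forward(p, X, A, A2, E)
        L_cs, L_ce, _, _ = losses.cluster_loss(out.Q_spa, out.Q_expr, 1.0)
        return (losses.recon_loss(X, out.X_hat)
                + losses.instance_loss(out.H_spa, out.H_expr, 0.5)
                + L_cs + L_ce)

    g = grad(objective)(params)
    h = 1e-6
    for key in ("W11", "W42", "B1", "B2"):
        W = params[key]
        i = tuple(rng.integers(0, s) for s in W.shape)
        for delta, sign in ((h, +1), (-h, -1)):
            pass
        up = {k: v.copy() for k, v in params.items()}
        dn = {k: v.copy() for k, v in params.items()}
        up[key][i] += h
        dn[key][i] -= h
        fd = (objective(up) - objective(dn)) / (2 * h)
        scale = max(abs(fd), abs(g[key][i]), 1e-8)
        assert abs(fd - g[key][i]) / scale < 1e-4, key


def test_checkpoint_round_trip(tmp_path, rng):
    from spotview.network import load_checkpoint, save_checkpoint

    cfg = _small_config()
    params = init_params(3, 2, cfg, rng)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(params, cfg, path)
    params2, cfg2 = load_checkpoint(path)
    assert cfg2 == cfg
    for k in params:
        np.testing.assert_array_equal(params2[k], params[k])


def test_batch_design_validation():
    with pytest.raises(ValueError, match="one-hot"):
        BatchDesign(E=np.array([[1.0, 1.0]]), slice_order=["a", "b"])
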