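import numpy as np
import pytest

from drfs.core_io import one_hot, standardize
from drfs.feature_graphs import (
    build_class_graphs,
    build_global_graph,
    laplacian,
)
from drfs.selection import feature_scores
from drfs.solver import (
    SolverConfig,
    SolverState,
    fit,
    init_state,
    kkt_residual,
    l21_norm,
    objective_value,
    _solve_Z_unprojected,
    update_reweight,
    update_W,
    update_Z,
)
from tests.conftest import random_data_matrix


def w_subproblem_objective(W, X, Y, Z, Lam, mu, alpha, diag):
    """Frozen-reweight surrogate: regression + penalty + alpha tr(W^T D W)."""
    return (
        np.linalg.norm(X @ W - Y) ** 2
        + mu * np.linalg.norm(W - Z + Lam / mu) ** 2
        + alpha * float(np.einsum("i,ij,ij->", diag, W, W))
    )


def random_state(rng, d, r, mu=1.0, eps=1e-10):
    W = rng.uniform(0.1, 1.0, (d, r))
    return SolverState(
        W=W,
        Z=rng.uniform(0.0, 1.0, (d, r)),
        Lambda=rng.standard_normal((d, r)),
        mu=mu,
        reweight_diag=update_reweight(W, eps),
    )


class TestConfig:
    def test_defaults_match_protocol(self):
        c = SolverConfig()
        assert c.mu0 == 1.0 and c.rho == 1.1 and c.mu_max == 1e8
        assert c.k == 10
        assert c.lam1 == c.beta and c.lam2 == c.beta

    def test_lambda_override(self):
        c = SolverConfig(beta=2.0, lambda1=0.5, lambda2=3.0)
        assert c.lam1 == 0.5 and c.lam2 == 3.0

    def test_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(alpha=0.0)
        with pytest.raises(ValueError):
            SolverConfig(rho=1.0)
        with pytest.raises(ValueError):
            SolverConfig(mu0=10.0, mu_max=1.0)

    def test_yaml_roundtrip(self, tmp_path):
        c = SolverConfig(alpha=3.0, beta=0.5, lambda2=7.0, k=4, seed=9)
        p = tmp_path / "cfg.yaml"
        c.to_yaml(p)
        assert SolverConfig.from_yaml(p) == c


class TestInitState:
    def test_deterministic(self):
        c = SolverConfig(seed=42)
        a, b = init_state(10, 3, c), init_state(10, 3, c)
        np.testing.assert_array_equal(a.W, b.W)

    def test_support_and_copies(self):
        s = init_state(50, 4, SolverConfig(seed=0))
        assert np.all(s.W > 0.1) and np.all(s.W < 1.0)
        np.testing.assert_array_equal(s.Z, s.W)
        np.testing.assert_array_equal(s.Lambda, 0.0)
        assert s.mu == 1.0


class TestUpdateReweight:
    def test_hand_norm(self):
        W = np.array([[3.0, 4.0]])
        assert update_reweight(W, 1e-30)[0] == pytest.approx(0.1)

    def test_zero_row_guard(self):
        eps = 1e-10
        d = update_reweight(np.zeros((2, 3)), eps)
        assert np.all(np.isfinite(d))
        np.testing.assert_allclose(d, 1.0 / (2 * np.sqrt(eps)))

    def test_surrogate_recovers_l21(self, rng):
        # 2 tr(W^T D W) -> ||W||_{2,1} as eps -> 0
        W = rng.uniform(0.5, 2.0, (8, 3))
        diag = update_reweight(W, 1e-16)
        surrogate = 2.0 * float(np.einsum("i,ij,ij->", diag, W, W))
        assert surrogate == pytest.approx(l21_norm(W), rel=1e-6)


class TestUpdateW:
    def test_fixed_point_unchanged(self, rng):
        # engineer B = A W so the multiplicative factor is exactly 1
        d, r, n = 6, 2, 9
        X = rng.standard_normal((n, d))
        c = SolverConfig(alpha=0.5, eps_denominator=1e-300)
        s = random_state(rng, d, r, eps=c.eps_reweight)
        A = X.T @ X + s.mu * np.eye(d) + c.alpha * np.diag(s.reweight_diag)
        B = A @ s.W
        # choose Z, Lambda consistent with that B: mu Z - Lambda = B - X^T Y
        Y = one_hot(np.array([1, 2] * 4 + [1]), r)
        s.Z = (B - X.T @ Y) / s.mu
        s.Lambda = np.zeros((d, r))
        W_new = update_W(s, X, Y, c)
        np.testing.assert_allclose(W_new, s.W, rtol=1e-12)

    def test_zeros_stay_zero(self, rng):
        d, r, n = 7, 3, 10
        X = rng.standard_normal((n, d))
        Y = one_hot(np.array([1, 2, 3] * 3 + [1]), r)
        s = random_state(rng, d, r)
        s.W[2, 1] = 0.0
        s.W[5, :] = 0.0
        W_new = update_W(s, X, Y, SolverConfig())
        assert W_new[2, 1] == 0.0
        np.testing.assert_array_equal(W_new[5, :], 0.0)
        assert np.all(W_new >= 0)

    def test_monotone_on_frozen_subproblem(self):
        # one update never increases the frozen-reweight surrogate, 20 seeds
        n, d, r = 40, 25, 3
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((n, d))
            labels = np.array([1 + i % r for i in range(n)])
            Y = one_hot(labels, r)
            c = SolverConfig(alpha=1.0)
            s = random_state(rng, d, r)
            before = w_subproblem_objective(
                s.W, X, Y, s.Z, s.Lambda, s.mu, c.alpha, s.reweight_diag
            )
            W_new = update_W(s, X, Y, c)
            after = w_subproblem_objective(
                W_new, X, Y, s.Z, s.Lambda, s.mu, c.alpha, s.reweight_diag
            )
            assert after <= before + 1e-8


class TestUpdateZ:
    def _setup(self, rng, beta=1.0):
        X = random_data_matrix(rng, n=20, d=10, r=3)
        laps = [laplacian(g) for g in build_class_graphs(X, k=3)]
        M = build_global_graph(X, k=3)
        c = SolverConfig(alpha=1.0, beta=beta)
        s = random_state(rng, 10, 3, mu=2.0)
        return X, laps, M, c, s

    def test_beta_zero_collapses_to_shifted_W(self, rng):
        X, laps, M, c, s = self._setup(rng, beta=0.0)
        Z_pre = _solve_Z_unprojected(s, laps, M, c)
        np.testing.assert_allclose(Z_pre, s.W + s.Lambda / s.mu, atol=1e-12)

    def test_stationarity_residual(self, rng):
        # plug pre-projection columns back into the linear stationarity eqn,
        # matching the Gauss-Seidel discipline (fresh columns before l only)
        X, laps, M, c, s = self._setup(rng, beta=1.3)
        Z_init = s.Z.copy()
        Z = _solve_Z_unprojected(s, laps, M, c)
        r = 3
        d = 10
        Msim = M.dense()
        for l in range(r):
            lhs = ((c.lam1 / r) * laps[l].dense() + s.mu * np.eye(d)) @ Z[:, l]
            others = sum(Z[:, q] for q in range(l)) + sum(
                Z_init[:, q] for q in range(l + 1, r)
            )
            rhs = (
                s.mu * s.W[:, l]
                + s.Lambda[:, l]
                - (c.lam2 / (r * (r - 1))) * (Msim @ others)
            )
            assert np.linalg.norm(lhs - rhs) < 1e-8

    def test_projection_nonnegative(self, rng):
        X, laps, M, c, s = self._setup(rng)
        s.Lambda -= 5.0  # push the unconstrained solution negative
        Z = update_Z(s, laps, M, c)
        assert np.all(Z >= 0)


class TestObjective:
    def test_zero_weights(self, rng):
        X = random_data_matrix(rng, n=10, d=6, r=2)
        Y = one_hot(X.labels, 2)
        laps = [laplacian(g) for g in build_class_graphs(X, k=2)]
        M = build_global_graph(X, k=2)
        W = np.zeros((6, 2))
        val = objective_value(W, X.values, Y, SolverConfig(), laps, M)
        assert val == pytest.approx(10.0)  # ||Y||_F^2 = n for one-hot Y

    def test_least_squares_oracle(self, rng):
        # alpha, beta -> 0: residual term matches the normal-equations fit
        n, d, r = 5, 3, 2
        X = rng.standard_normal((n, d))
        labels = np.array([1, 2, 1, 2, 1])
        Y = one_hot(labels, r)
        W_ls, res, *_ = np.linalg.lstsq(X, Y, rcond=None)
        from drfs.core_io import DataMatrix

        dm = DataMatrix(values=X, labels=labels)
        laps = [laplacian(g) for g in build_class_graphs(dm, k=2)]
        M = build_global_graph(dm, k=2)
        c = SolverConfig(alpha=1e-12, beta=0.0)
        val = objective_value(W_ls, X, Y, c, laps, M)
        expect = np.linalg.norm(X @ W_ls - Y) ** 2
        assert val == pytest.approx(expect, abs=1e-9)

    def test_identity_instance(self, rng):
        # X = I, Y = I, W = I, beta = 0: residual 0, l2,1 norm = r
        d = 4
        labels = np.arange(1, d + 1)
        from drfs.core_io import DataMatrix

        dm = DataMatrix(values=np.eye(d) + 0.01 * rng.standard_normal((d, d)),
                        labels=labels)
        laps = [
            laplacian(g) for g in build_class_graphs(
                DataMatrix(values=rng.standard_normal((8, d)),
                           labels=[1, 2, 3, 4, 1, 2, 3, 4]), k=2)
        ]
        M = build_global_graph(dm, k=2)
        alpha = 0.7
        c = SolverConfig(alpha=alpha, beta=0.0)
        val = objective_value(np.eye(d), np.eye(d), np.eye(d), c, laps, M)
        assert val == pytest.approx(alpha * d)


class TestKKTResidual:
    def test_zero_at_fixed_point(self, rng):
        d, r, n = 5, 2, 8
        X = rng.standard_normal((n, d))
        Y = one_hot(np.array([1, 2] * 4), r)
        c = SolverConfig()
        s = random_state(rng, d, r)
        A = X.T @ X + s.mu * np.eye(d) + c.alpha * np.diag(s.reweight_diag)
        s.Z = (A @ s.W - X.T @ Y) / s.mu
        s.Lambda = np.zeros((d, r))
        assert kkt_residual(s, X, Y, c) < 1e-10

    def test_quadratic_scaling(self, rng):
        # scaling W, Z, Lambda by c (reweight frozen) scales the residual c^2
        d, r, n = 6, 2, 9
        X = rng.standard_normal((n, d))
        Y = one_hot(np.array([1, 2] * 4 + [1]), r)
        cfg = SolverConfig()
        s = random_state(rng, d, r)
        base = kkt_residual(s, X, Y, cfg)
        c = 3.0
        s2 = SolverState(
            W=c * s.W, Z=c * s.Z, Lambda=c * s.Lambda, mu=s.mu,
            reweight_diag=s.reweight_diag,
        )
        # B also needs X^T Y scaled; absorb by scaling Y
        scaled = kkt_residual(s2, X, c * Y, cfg)
        assert scaled == pytest.approx(c**2 * base, rel=1e-10)


class TestFit:
    def test_reference_converges(self, reference_fit):
        state, config, Xs, gt = reference_fit
        assert state.converged
        assert state.iteration <= 100
        last = state.trace[-1]
        assert last["primal_residual"] < 1e-4
        assert np.all(state.W >= 0)
        assert np.all(state.Z >= 0)

    def test_mu_schedule(self, reference_fit):
        state, config, Xs, gt = reference_fit
        mus = [rec["mu"] for rec in state.trace]
        assert all(b >= a for a, b in zip(mus, mus[1:]))
        assert mus[0] == config.mu0
        assert mus[-1] <= config.mu_max

    def test_huge_alpha_kills_weights(self, reference_std):
        Xs, _ = reference_std
        state = fit(Xs, SolverConfig(alpha=1e6, beta=1.0, seed=0))
        assert np.all(feature_scores(state.W) < 1e-3)

    def test_kkt_residual_decreases(self, reference_fit):
        state, *_ = reference_fit
        first = state.trace[0]["kkt_residual"]
        last = state.trace[-1]["kkt_residual"]
        assert last < first / 10

    def test_seed_robust_top10(self, reference_std):
        Xs, _ = reference_std
        tops = []
        for seed in range(5):
            state = fit(Xs, SolverConfig(alpha=100.0, beta=1.0, seed=seed))
            scores = feature_scores(state.W)
            tops.append(frozenset(np.argsort(-scores, kind="stable")[:10].tolist()))
        assert len(set(tops)) == 1

    def test_trace_columns(self, reference_fit):
        state, *_ = reference_fit
        expected = {
            "iteration", "objective", "augmented_objective", "primal_residual",
            "omega_local", "omega_global", "mu", "kkt_residual",
        }
        assert set(state.trace[0]) == expected

    def test_trace_tsv(self, tmp_path, reference_fit):
        state, *_ = reference_fit
        p = tmp_path / "trace.tsv"
        state.write_trace(p)
        header = p.read_text().splitlines()[0]
        assert header.startswith("iteration\tobjective")
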