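"""Augmented-Lagrangian solver for the dual-regularized selection objective.

The target problem is

    min_{W >= 0}  ||X W - Y||_F^2 + alpha ||W||_{2,1}
                  + (lambda1 / r) Omega_local(W)
                  + (lambda2 / (r (r-1))) Omega_global(W)

with Y the one-hot label indicator.  A slack copy Z of W carries the two
graph penalties; the coupling constraint W = Z is enforced by an augmented
Lagrangian with multiplier Lambda and growing penalty mu.  Per iteration:

  1. refresh the l2,1 reweighting diagonal D from W,
  2. multiplicative non-negative update of W (NMF-style, KKT-derived),
  3. per-class closed-form solve for the columns of Z (Gauss-Seidel sweep
     over classes, using fresh columns within the sweep) followed by
     projection onto the non-negative orthant,
  4. Lambda <- Lambda + mu (W - Z),  mu <- min(rho mu, mu_max).

Stops when the relative change of the augmented objective falls below
``tol_obj`` and the scaled primal residual ||W - Z||_F / max(1, ||W||_F)
falls below ``tol_primal``, or after ``max_iter`` iterations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.linalg import cho_factor, cho_solve

from drfs.core_io import DataMatrix, one_hot
from drfs.feature_graphs import (
    FeatureGraph,
    GraphLaplacian,
    build_class_graphs,
    build_global_graph,
    laplacian,
)
from drfs.regularizers import omega_global, omega_local


class NumericalError(RuntimeError):
    """Raised when the iteration produces a non-finite objective."""


@dataclass
class SolverConfig:
    """Hyperparameters and schedule for the ALM solver.

    ``lambda1``/``lambda2`` default to ``None`` meaning "inherit beta", which
    recovers the single-beta objective exactly; setting them separately
    enables the generalized two-parameter variant.
    """

    alpha: float = 1.0
    beta: float = 1.0
    lambda1: float | None = None
    lambda2: float | None = None
    k: int = 10
    mu0: float = 1.0
    rho: float = 1.1
    mu_max: float = 1e8
    max_iter: int = 100
    tol_obj: float = 1e-5
    tol_primal: float = 1e-4
    eps_reweight: float = 1e-10
    eps_denominator: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")
        if not (0 < self.mu0 <= self.mu_max):
            raise ValueError("need 0 < mu0 <= mu_max")
        for name in ("tol_obj", "tol_primal", "eps_reweight", "eps_denominator"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def lam1(self) -> float:
        return self.beta if self.lambda1 is None else self.lambda1

    @property
    def lam2(self) -> float:
        return self.beta if self.lambda2 is None else self.lambda2

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SolverConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SolverState:
    """Optimization state (W, Z, Lambda, mu) plus the per-iteration trace."""

    W: np.ndarray
    Z: np.ndarray
    Lambda: np.ndarray
    mu: float
    reweight_diag: np.ndarray
    iteration: int = 0
    converged: bool = False
    trace: list[dict] = field(default_factory=list)

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trace)

    def write_trace(self, path: str | Path) -> None:
        self.trace_frame().to_csv(path, sep="\t", index=False)


def init_state(d: int, r: int, config: SolverConfig) -> SolverState:
    """Seeded strictly-positive initialization.

    W entries are uniform(0.1, 1): multiplicative updates preserve zeros, so
    the start must avoid them, and a constant start would create persistent
    ties between rows.
    """
    rng = np.random.default_rng(config.seed)
    W = rng.uniform(0.1, 1.0, size=(d, r))
    return SolverState(
        W=W,
        Z=W.copy(),
        Lambda=np.zeros((d, r)),
        mu=config.mu0,
        reweight_diag=update_reweight(W, config.eps_reweight),
    )


def update_reweight(W: np.ndarray, eps: float) -> np.ndarray:
    """Diagonal of the l2,1 reweighting matrix: 1 / (2 sqrt(||w^i||^2 + eps))."""
    row_sq = np.einsum("ij,ij->i", W, W)
    return 1.0 / (2.0 * np.sqrt(row_sq + eps))


def _split_pos_neg(O: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """O = O+ - O- with O+ = (|O| + O)/2 and O- = (|O| - O)/2, both >= 0."""
    absO = np.abs(O)
    return (absO + O) / 2.0, (absO - O) / 2.0


def update_W(
    state: SolverState, X: np.ndarray, Y: np.ndarray, config: SolverConfig
) -> np.ndarray:
    """Multiplicative KKT update of W with the reweight diagonal frozen.

    With A = X^T X + mu I + alpha D and B = X^T Y + mu Z - Lambda:
        W <- W * (A- W + B+) / (A+ W + B- + eps).
    Entry-wise; preserves non-negativity and leaves exact zeros in place.
    """
    d = state.W.shape[0]
    A = X.T @ X + state.mu * np.eye(d) + config.alpha * np.diag(state.reweight_diag)
    B = X.T @ Y + state.mu * state.Z - state.Lambda
    Ap, An = _split_pos_neg(A)
    Bp, Bn = _split_pos_neg(B)
    numer = An @ state.W + Bp
    denom = Ap @ state.W + Bn + config.eps_denominator
    return state.W * (numer / denom)


def update_Z(
    state: SolverState,
    class_laps: Sequence[GraphLaplacian],
    M_global: FeatureGraph,
    config: SolverConfig,
) -> np.ndarray:
    """Per-class closed-form solve for Z, then projection onto Z >= 0.

    Column l solves the SPD system
        ((lam1 / r) L^(l) + mu I) z_l
            = mu w_l + Lambda_l - (lam2 / (r (r-1))) sum_{q != l} M z_q,
    sweeping classes in order and using already-updated columns on the
    right-hand side (Gauss-Seidel).  The system matrix is PSD + mu I, hence
    always positive definite.
    """
    d, r = state.W.shape
    Z = state.Z.copy()
    mu = state.mu
    lam1, lam2 = config.lam1, config.lam2
    cross_coef = lam2 / (r * (r - 1)) if r > 1 else 0.0
    M = M_global.sim
    for l in range(r):
        S = (lam1 / r) * class_laps[l].dense() + mu * np.eye(d)
        rhs = mu * state.W[:, l] + state.Lambda[:, l]
        if cross_coef:
            others = Z.sum(axis=1) - Z[:, l]
            rhs = rhs - cross_coef * (M @ others)
        z = cho_solve(cho_factor(S, lower=True), rhs)
        Z[:, l] = np.maximum(z, 0.0)
    return Z


def _solve_Z_unprojected(
    state: SolverState,
    class_laps: Sequence[GraphLaplacian],
    M_global: FeatureGraph,
    config: SolverConfig,
) -> np.ndarray:
    """Gauss-Seidel sweep without the projection step (stationarity checks)."""
    d, r = state.W.shape
    Z = state.Z.copy()
    mu = state.mu
    lam1, lam2 = config.lam1, config.lam2
    cross_coef = lam2 / (r * (r - 1)) if r > 1 else 0.0
    M = M_global.sim
    for l in range(r):
        S = (lam1 / r) * class_laps[l].dense() + mu * np.eye(d)
        rhs = mu * state.W[:, l] + state.Lambda[:, l]
        if cross_coef:
            others = Z.sum(axis=1) - Z[:, l]
            rhs = rhs - cross_coef * (M @ others)
        Z[:, l] = cho_solve(cho_factor(S, lower=True), rhs)
    return Z


def l21_norm(W: np.ndarray) -> float:
    """Sum of row l2-norms."""
    return float(np.sqrt(np.einsum("ij,ij->i", W, W)).sum())


def objective_value(
    W: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    config: SolverConfig,
    class_laps: Sequence[GraphLaplacian],
    M: FeatureGraph,
) -> float:
    """Exact objective (true l2,1 norm, not the smoothed surrogate)."""
    r = W.shape[1]
    val = float(np.linalg.norm(X @ W - Y) ** 2) + config.alpha * l21_norm(W)
    val += (config.lam1 / r) * omega_local(W, class_laps)
    if r > 1:
        val += (config.lam2 / (r * (r - 1))) * omega_global(W, M)
    return val


def augmented_objective(
    state: SolverState,
    X: np.ndarray,
    Y: np.ndarray,
    config: SolverConfig,
    class_laps: Sequence[GraphLaplacian],
    M: FeatureGraph,
) -> float:
    """Augmented Lagrangian value: regression + sparsity on W, graph terms
    on the slack Z, plus the penalty mu ||W - Z + Lambda/mu||_F^2."""
    W, Z, Lam, mu = state.W, state.Z, state.Lambda, state.mu
    r = W.shape[1]
    val = float(np.linalg.norm(X @ W - Y) ** 2) + config.alpha * l21_norm(W)
    val += mu * float(np.linalg.norm(W - Z + Lam / mu) ** 2)
    val += (config.lam1 / r) * omega_local(Z, class_laps)
    if r > 1:
        val += (config.lam2 / (r * (r - 1))) * omega_global(Z, M)
    return val


def kkt_residual(
    state: SolverState, X: np.ndarray, Y: np.ndarray, config: SolverConfig
) -> float:
    """Complementarity residual max_ij |(A W - B)_ij W_ij| of the W subproblem."""
    d = state.W.shape[0]
    A = X.T @ X + state.mu * np.eye(d) + config.alpha * np.diag(state.reweight_diag)
    B = X.T @ Y + state.mu * state.Z - state.Lambda
    return float(np.abs((A @ state.W - B) * state.W).max())


def primal_residual(state: SolverState) -> float:
    """Scaled coupling residual ||W - Z||_F / max(1, ||W||_F)."""
    return float(
        np.linalg.norm(state.W - state.Z) / max(1.0, np.linalg.norm(state.W))
    )


def fit(
    X: DataMatrix,
    config: SolverConfig | None = None,
    *,
    class_graphs: Sequence[FeatureGraph] | None = None,
    global_graph: FeatureGraph | None = None,
) -> SolverState:
    """Run the full ALM loop on a labeled data matrix.

    Graphs are built from the data with ``config.k`` neighbors unless
    precomputed ones are passed in.  Returns the final state with W >= 0 and
    a populated per-iteration trace.
    """
    config = config or SolverConfig()
    if class_graphs is None:
        class_graphs = build_class_graphs(X, k=config.k)
    if global_graph is None:
        global_graph = build_global_graph(X, k=config.k)
    class_laps = [laplacian(g) for g in class_graphs]

    r = X.n_classes
    Y = one_hot(X.labels, r)
    V = X.values
    state = init_state(X.n_features, r, config)

    prev_aug = np.inf
    for it in range(1, config.max_iter + 1):
        state.reweight_diag = update_reweight(state.W, config.eps_reweight)
        state.W = update_W(state, V, Y, config)
        state.Z = update_Z(state, class_laps, global_graph, config)
        state.Lambda = state.Lambda + state.mu * (state.W - state.Z)
        state.iteration = it

        aug = augmented_objective(state, V, Y, config, class_laps, global_graph)
        if not np.isfinite(aug):
            raise NumericalError(f"non-finite augmented objective at iteration {it}")
        obj = objective_value(state.W, V, Y, config, class_laps, global_graph)
        res = primal_residual(state)
        rel = abs(prev_aug - aug) / max(1.0, abs(prev_aug))
        state.trace.append(
            {
                "iteration": it,
                "objective": obj,
                "augmented_objective": aug,
                "primal_residual": res,
                "omega_local": omega_local(state.W, class_laps),
                "omega_global": omega_global(state.W, global_graph)
                if r > 1
                else 0.0,
                "mu": state.mu,
                "kkt_residual": kkt_residual(state, V, Y, config),
            }
        )
        state.mu = min(config.rho * state.mu, config.mu_max)
        if rel < config.tol_obj and res < config.tol_primal:
            state.converged = True
            break
        prev_aug = aug
    return state
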