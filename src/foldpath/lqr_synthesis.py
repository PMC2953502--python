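"""Infinite-horizon LQR synthesis for the folding model.

The overdamped coarse-grained dynamics per Cartesian axis is

    dx/dt = (Gamma / beta) x + (1 / beta) u,

with ``x`` the deviation of the Cα positions from the native state,
``Gamma`` the Gaussian-network connectivity matrix and ``beta`` the
friction coefficient.  The controller minimises

    J = ∫ ( xᵀ Q x  +  alpha uᵀ P u ) dt,

whose first term is the harmonic excess energy over the native state and
whose second term penalises large control forces — the proxy for routes
with high entropy loss.  ``alpha`` trades the two against each other.

The optimal law is the constant feedback ``u = -K x`` with
``K = (alpha P)⁻¹ Bᵀ S`` and ``S`` the stabilising solution of the
continuous algebraic Riccati equation.  Because ``Gamma`` and ``Q`` share
the all-ones vector as an eigenvector (``Gamma·1 = 0``, ``Q·1 = eps·1``)
and ``P = I``, the Riccati equation restricted to span{1} collapses to a
scalar quadratic, giving the exact row-sum identity ``K·1 = sqrt(eps/alpha)·1``.
This yields the gain decomposition ``K = K' + k I`` with a zero-row-sum
spring matrix ``K'`` (pairwise springs synthesised by the controller) and
the uniform anchoring constant ``k = sqrt(eps/alpha)`` tying every bead
to its native position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_continuous_are, solve_continuous_lyapunov

__all__ = [
    "LQRProblem",
    "GainDecomposition",
    "RiccatiError",
    "solve_lqr",
    "closed_loop_matrix",
    "lqr_cost_integrals",
]

RICCATI_RTOL = 1e-8  # relative residual bound, in units of ||Q||


class RiccatiError(RuntimeError):
    """No stabilizing solution of the algebraic Riccati equation was found."""


@dataclass(frozen=True)
class LQRProblem:
    """Data of one LQR synthesis step.

    ``A = gamma / beta`` and ``B = I / beta`` are implied; only the model
    matrices and scalars are stored.
    """

    gamma: np.ndarray
    Q: np.ndarray
    alpha: float = 1.0
    beta: float = 1.0
    epsilon: float = 1e-2
    P: np.ndarray | None = None  # None means identity

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.epsilon <= 0:
            raise ValueError("alpha, beta and epsilon must all be positive")
        gamma = np.asarray(self.gamma, dtype=float)
        Q = np.asarray(self.Q, dtype=float)
        if gamma.shape != Q.shape or gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
            raise ValueError("gamma and Q must be square matrices of equal size")
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "Q", Q)

    @property
    def n(self) -> int:
        return self.gamma.shape[0]

    @property
    def A(self) -> np.ndarray:
        return self.gamma / self.beta

    @property
    def B(self) -> np.ndarray:
        return np.eye(self.n) / self.beta

    @property
    def P_matrix(self) -> np.ndarray:
        return np.eye(self.n) if self.P is None else np.asarray(self.P, dtype=float)


@dataclass(frozen=True)
class GainDecomposition:
    """Optimal gain ``K`` split as ``K = K' + k I``.

    ``K_prime`` has zero row sums and is read as the harmonic spring
    constant matrix the controller adds to the network; the scalar ``k``
    anchors every residue to its native position with identical strength.
    """

    K: np.ndarray
    K_prime: np.ndarray
    k: float
    riccati_residual: float = field(default=0.0, compare=False)

    @property
    def n(self) -> int:
        return self.K.shape[0]


def solve_lqr(problem: LQRProblem) -> GainDecomposition:
    """Solve the algebraic Riccati equation and decompose the optimal gain.

    Raises :class:`RiccatiError` when no stabilising solution exists
    (e.g. ``Q`` not positive definite) or the residual exceeds
    ``1e-8 * ||Q||``.
    """
    A, B, Q = problem.A, problem.B, problem.Q
    R = problem.alpha * problem.P_matrix
    try:
        S = solve_continuous_are(A, B, Q, R)
    except Exception as exc:  # scipy raises LinAlgError or ValueError
        raise RiccatiError(f"no stabilizing solution: {exc}") from exc
    S = 0.5 * (S + S.T)
    if np.linalg.eigvalsh(S).min() <= 0:
        raise RiccatiError("no stabilizing solution: Riccati solution not positive definite")
    residual = A.T @ S + S @ A - S @ B @ np.linalg.solve(R, B.T @ S) + Q
    rel_residual = np.linalg.norm(residual) / np.linalg.norm(Q)
    if rel_residual > RICCATI_RTOL:
        raise RiccatiError(
            f"Riccati residual {rel_residual:.2e} exceeds {RICCATI_RTOL:.0e} * ||Q||"
        )
    K = np.linalg.solve(R, B.T @ S)
    K = 0.5 * (K + K.T)  # symmetric whenever P = I (K = S / (alpha*beta))

    k = float(np.sqrt(problem.epsilon / problem.alpha))
    K_prime = K - k * np.eye(problem.n)
    ones = np.ones(problem.n)
    structured = (
        problem.P is None
        and np.abs(problem.gamma @ ones).max() <= 1e-9 * max(np.abs(problem.gamma).max(), 1.0)
        and np.abs(Q @ ones - problem.epsilon).max() <= 1e-9 * max(np.abs(Q).max(), 1.0)
    )
    if structured:
        # exactness of the decomposition is a theorem here, not a fit
        row_dev = np.abs(K.sum(axis=1) - k).max()
        if row_dev > 1e-8 * max(np.linalg.norm(K), 1e-300):
            raise RiccatiError(
                f"gain row sums deviate from sqrt(eps/alpha) by {row_dev:.2e}; "
                "model structure violated (Gamma·1 != 0 or Q·1 != eps·1?)"
            )
    return GainDecomposition(K=K, K_prime=K_prime, k=k, riccati_residual=rel_residual)


def closed_loop_matrix(
    gamma: np.ndarray, gain: GainDecomposition, beta: float = 1.0
) -> np.ndarray:
    """Closed-loop network matrix ``A_cl = (Gamma - K' - k I) / beta``.

    Under the optimal control the folding dynamics is again a Gaussian
    network: the open-chain connectivity plus the springs synthesised by
    the controller plus the uniform native anchors.  A_cl must be stable
    (all eigenvalues negative) so the native state attracts.
    """
    a_cl = (np.asarray(gamma, dtype=float) - gain.K) / beta
    lam_max = np.linalg.eigvalsh(a_cl).max()
    if lam_max >= 0:
        raise RiccatiError(f"closed loop unstable: max eigenvalue {lam_max:.3e} >= 0")
    return a_cl


def lqr_cost_integrals(
    A_cl: np.ndarray,
    K: np.ndarray,
    Q: np.ndarray,
    P: np.ndarray,
    alpha: float,
    x0: np.ndarray,
) -> tuple[float, float]:
    """Closed-form cost integrals along ``x(t) = exp(A_cl t) x0``.

    Returns ``(state_cost, control_cost)`` with

        state_cost   = ∫₀^∞ xᵀ Q x dt,
        control_cost = ∫₀^∞ alpha uᵀ P u dt,   u = -K x,

    each evaluated via the Lyapunov equation ``A_clᵀ X + X A_cl + M = 0``
    and ``cost = x0ᵀ X x0``.  ``x0`` may be a vector (one axis) or an
    ``(n, m)`` matrix of stacked axes, in which case costs sum over axes.
    """
    A_cl = np.asarray(A_cl, dtype=float)
    if np.real(np.linalg.eigvals(A_cl)).max() >= 0:
        raise ValueError("A_cl is not stable: cost integrals diverge")
    x0 = np.atleast_2d(np.asarray(x0, dtype=float).T).T  # (n, m)
    M_state = np.asarray(Q, dtype=float)
    M_ctrl = alpha * K.T @ np.asarray(P, dtype=float) @ K
    costs = []
    for M in (M_state, M_ctrl):
        X = solve_continuous_lyapunov(A_cl.T, -M)
        costs.append(float(np.einsum("im,ij,jm->", x0, X, x0)))
    return costs[0], costs[1]
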