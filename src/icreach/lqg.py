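"""LQG gain synthesis: stationary and time-varying feedback/observer gains.

Gains are always designed from the *internal model*, i.e. as if the plant were
accurately modeled.  The stationary gains solve the two algebraic Riccati
equations; the time-varying feedback gain integrates the control Riccati ODE
backward from the stationary terminal condition, and the time-varying observer
gain integrates the filter Riccati ODE forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_continuous_are

from .plant import CostSpec, LinearModel, SynthesisError

__all__ = [
    "GainSchedule",
    "lqr_gain_infinite",
    "kalman_gain_infinite",
    "feedback_schedule",
    "observer_schedule",
    "design_lti_gains",
]


def lqr_gain_infinite(
    model: LinearModel, Q_inf: np.ndarray, R_inf: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary feedback gain ``K = R^-1 B' S`` from the control ARE."""
    R = np.atleast_2d(R_inf)
    try:
        S = solve_continuous_are(model.A, model.B, Q_inf, R)
    except Exception as exc:
        raise SynthesisError(f"control ARE failed: {exc}") from exc
    K = np.linalg.solve(R, model.B.T @ S)
    return K, S


def kalman_gain_infinite(model: LinearModel) -> tuple[np.ndarray, np.ndarray]:
    """Stationary Kalman gain ``L = P C' V^-1`` from the filter ARE."""
    try:
        P = solve_continuous_are(model.A.T, model.C.T, model.W, model.V)
    except Exception as exc:
        raise SynthesisError(f"filter ARE failed: {exc}") from exc
    L = P @ model.C.T @ np.linalg.inv(model.V)
    return L, P


@dataclass(frozen=True)
class GainSchedule:
    """Feedback gain K(t) and observer gain L(t) on a uniform time grid.

    Stored as zero-order-hold samples; ``stationary`` builds a schedule that is
    constant in time.  ``K(t) = K(T)`` for ``t`` past the grid end.
    """

    t: np.ndarray            # (n_t,) uniform grid
    K: np.ndarray            # (n_t, 1, 4) or broadcastable (1, 1, 4)
    L: np.ndarray            # (n_t, 4, 2) or broadcastable (1, 4, 2)
    S: np.ndarray | None = None
    P: np.ndarray | None = None

    @staticmethod
    def stationary(K: np.ndarray, L: np.ndarray) -> "GainSchedule":
        return GainSchedule(
            t=np.zeros(1), K=np.asarray(K)[None, :, :], L=np.asarray(L)[None, :, :]
        )

    @property
    def is_stationary(self) -> bool:
        return self.K.shape[0] == 1 and self.L.shape[0] == 1

    def _index(self, t: float) -> int:
        if self.t.size == 1:
            return 0
        dt = self.t[1] - self.t[0]
        return min(int(np.floor((t - self.t[0]) / dt + 1e-9)), self.t.size - 1)

    def K_at(self, t: float) -> np.ndarray:
        return self.K[min(self._index(t), self.K.shape[0] - 1)]

    def L_at(self, t: float) -> np.ndarray:
        return self.L[min(self._index(t), self.L.shape[0] - 1)]


def _riccati_rhs_control(A: np.ndarray, BRB: np.ndarray):
    def rhs(_s: float, y: np.ndarray) -> np.ndarray:
        S = y.reshape(A.shape)
        dS = A.T @ S + S @ A - S @ BRB @ S  # Q(t<T) = 0 on the open interval
        return dS.ravel()

    return rhs


def feedback_schedule(
    model: LinearModel,
    cost: CostSpec,
    grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-varying feedback gain K(t) on ``grid``.

    The control Riccati ODE ``-S' = A'S + SA - S B R^-1 B' S + Q(t)`` is
    integrated backward from ``S(T) = S_T`` (the stationary solution), with
    ``Q(t) = 0`` before the reaching time.  For grid points past ``T`` the gain
    is held at its terminal (stationary) value.

    Returns ``(K_arr, S_arr)`` with shapes ``(n_t, 1, 4)`` and ``(n_t, 4, 4)``.
    """
    grid = np.asarray(grid, dtype=float)
    A, B = model.A, model.B
    Rinv = 1.0 / cost.R_inf
    BRB = B @ B.T * Rinv
    T = cost.T
    # integrate in reversed time sigma = T - t over [0, T]
    rhs = _riccati_rhs_control(A, BRB)
    sol = solve_ivp(
        rhs,
        (0.0, T),
        cost.S_T.ravel(),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise SynthesisError(f"backward Riccati integration failed: {sol.message}")
    n = A.shape[0]
    S_arr = np.empty((grid.size, n, n))
    for i, t in enumerate(grid):
        if t >= T:
            S = cost.S_T
        else:
            S = sol.sol(T - t).reshape(n, n)
            S = 0.5 * (S + S.T)
        S_arr[i] = S
    K_arr = Rinv * np.einsum("ij,tjk->tik", B.T, S_arr)
    return K_arr, S_arr


def observer_schedule(
    model: LinearModel,
    P0: np.ndarray,
    grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-varying Kalman gain L(t) = P(t) C' V^-1 on ``grid``.

    The filter Riccati ODE ``P' = AP + PA' - P C'V^-1 C P + W`` is integrated
    forward from ``P0``.
    """
    grid = np.asarray(grid, dtype=float)
    A, C, W = model.A, model.C, model.W
    Vinv = np.linalg.inv(model.V)
    CVC = C.T @ Vinv @ C

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        P = y.reshape(A.shape)
        dP = A @ P + P @ A.T - P @ CVC @ P + W
        return dP.ravel()

    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1] if grid.size > 1 else grid[0] + 1e-12),
        np.asarray(P0, dtype=float).ravel(),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise SynthesisError(f"filter Riccati integration failed: {sol.message}")
    n = A.shape[0]
    P_arr = np.empty((grid.size, n, n))
    for i, t in enumerate(grid):
        P = sol.sol(t).reshape(n, n)
        P_arr[i] = 0.5 * (P + P.T)
    L_arr = np.einsum("tij,jk->tik", P_arr, C.T @ Vinv)
    return L_arr, P_arr


def design_lti_gains(
    internal: LinearModel, Q_inf: np.ndarray, R_inf: float
) -> GainSchedule:
    """Stationary LQG design from the internal model (separation principle)."""
    K, S = lqr_gain_infinite(internal, Q_inf, R_inf)
    L, P = kalman_gain_infinite(internal)
    sched = GainSchedule.stationary(K, L)
    return GainSchedule(t=sched.t, K=sched.K, L=sched.L, S=S, P=P)
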