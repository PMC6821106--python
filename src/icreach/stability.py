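"""Closed-loop transition matrices and stability criteria.

Four regimes are covered, all with time-invariant gains:

* ``cc_delayfree`` — continuous control, no delay: an autonomous 8-dim linear
  system on [plant state; estimate]; stable iff every eigenvalue of ``A_ov``
  has negative real part.
* ``ic_delayfree`` — periodic intermittent control with system-matched hold:
  an 8-dim discrete map (monodromy matrix ``A_p``) from one trigger to the
  next, built in closed form from one Sylvester equation; stable iff the
  spectral radius is below one.
* ``ic_delayed`` — periodic IC with measurement delay ``tau < h``: a 12-dim
  discrete map ``A_tot`` on [x_ov; previous predicted state], built from three
  Sylvester equations.
* ``cc_delayed`` — continuous control with delay, analyzed through the
  zero-order-hold discrete equivalent ``A_ex`` of dimension ``8 + 4*k_tau``
  (shift register of past predicted states).

Each closed-form construction has an independent numerical oracle (a block
matrix exponential for the delay-free map, a method-of-steps Runge-Kutta
integration for the delayed one) used in the test suite to validate it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import eigvals, expm, solve_sylvester

from .plant import LinearModel

__all__ = [
    "sylvester_solve",
    "hold_coupling",
    "stacked_open_loop",
    "ic_monodromy_delayfree",
    "ic_monodromy_delayfree_oracle",
    "ic_monodromy_delayed",
    "ic_monodromy_delayed_oracle",
    "cc_closedloop_delayfree",
    "cc_discrete_delayed",
    "zoh_discretize",
    "spectral_radius",
    "spectral_abscissa",
    "StabilityReport",
    "stability_report",
    "ThresholdResult",
    "stability_threshold",
    "mass_threshold",
    "threshold_table",
    "eigenvalue_growth",
]

_SYLVESTER_RESID_TOL = 1e-10


class SingularSylvesterError(np.linalg.LinAlgError):
    """gamma and -beta share spectrum: the Sylvester equation is singular."""


def sylvester_solve(gamma: np.ndarray, beta: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Solve ``gamma S + S beta + alpha = 0``.

    Unique solvability requires that ``gamma`` and ``-beta`` share no
    eigenvalue; a residual check guards against near-singular instances.
    One pass of iterative refinement keeps the residual small even when the
    right-hand side carries the large feedback-gain magnitudes.
    """
    S = solve_sylvester(gamma, beta, -alpha)
    resid = gamma @ S + S @ beta + alpha
    if np.isfinite(resid).all() and np.abs(resid).max() > 0:
        S = S + solve_sylvester(gamma, beta, -resid)
        resid = gamma @ S + S @ beta + alpha
    scale = max(1.0, np.abs(alpha).max())
    if not np.isfinite(S).all() or np.abs(resid).max() > _SYLVESTER_RESID_TOL * scale * 1e4:
        raise SingularSylvesterError(
            "Sylvester equation ill-conditioned (spectra of gamma and -beta overlap?); "
            "use the simulation oracle for this parameter set"
        )
    return S


def hold_coupling(G: np.ndarray, BK: np.ndarray, A_F: np.ndarray, s: float) -> np.ndarray:
    """Inter-sample coupling integral ``Phi(s) = int_0^s e^{-G r} BK e^{A_F r} dr``.

    Differentiating the integrand shows Phi solves the Sylvester equation
    ``G Phi + Phi (-A_F) + (e^{-G s} BK e^{A_F s} - BK) = 0``, which is how it
    is computed here (no quadrature).
    """
    alpha = expm(-G * s) @ BK @ expm(A_F * s) - BK
    return sylvester_solve(G, -A_F, alpha)


def stacked_open_loop(
    plant: LinearModel, internal: LinearModel, L: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked plant+observer matrices ``A_o`` (8x8) and ``B_o`` (8x1).

    Top-left block is the true plant, bottom-right the observer error dynamics
    ``A - LC`` of the internal model, coupled through the innovation ``LC``.
    """
    A_bar, B_bar = plant.A, plant.B
    A, B, C = internal.A, internal.B, internal.C
    n = A.shape[0]
    A_o = np.block([[A_bar, np.zeros((n, n))], [L @ C, A - L @ C]])
    B_o = np.vstack([B_bar, B])
    return A_o, B_o


def _estimate_projector(n: int) -> np.ndarray:
    return np.hstack([np.zeros((n, n)), np.eye(n)])


def ic_monodromy_delayfree(
    plant: LinearModel,
    internal: LinearModel,
    K: np.ndarray,
    L: np.ndarray,
    h: float,
) -> np.ndarray:
    """Trigger-to-trigger map ``A_p`` of delay-free periodic IC.

    Between triggers the hold state follows the internal-model closed loop
    ``A_F = A - BK`` from its reset value (the current estimate), driving the
    stacked system through ``-B_o K``.  The inter-sample convolution collapses
    to a single Sylvester solution ``S``:

        ``A_p = e^{A_o h} (I - S [0 I])``
    """
    if h <= 0:
        raise ValueError("sampling period h must be positive")
    A, B = internal.A, internal.B
    A_F = A - B @ K
    A_o, B_o = stacked_open_loop(plant, internal, L)
    n = A.shape[0]
    S = hold_coupling(A_o, B_o @ K, A_F, h)
    return expm(A_o * h) @ (np.eye(2 * n) - S @ _estimate_projector(n))


def ic_monodromy_delayfree_oracle(
    plant: LinearModel,
    internal: LinearModel,
    K: np.ndarray,
    L: np.ndarray,
    h: float,
) -> np.ndarray:
    """Independent construction of ``A_p`` from one block matrix exponential.

    Augment [x_ov; x_h] into a 12-dim LTI system over one inter-trigger
    interval, take its exact flow, and apply the trigger reset
    ``x_h(t_m+) = [0 I] x_ov(t_m)``.
    """
    A, B = internal.A, internal.B
    A_F = A - B @ K
    A_o, B_o = stacked_open_loop(plant, internal, L)
    n = A.shape[0]
    M = np.block([[A_o, -B_o @ K], [np.zeros((n, 2 * n)), A_F]])
    E = expm(M * h)
    return E[: 2 * n, : 2 * n] + E[: 2 * n, 2 * n :] @ _estimate_projector(n)


def ic_monodromy_delayed(
    plant: LinearModel,
    internal: LinearModel,
    K: np.ndarray,
    L: np.ndarray,
    h: float,
    tau: float,
) -> np.ndarray:
    """Trigger-to-trigger map ``A_tot`` of periodic IC with delay ``0 < tau < h``.

    State is ``x_tot[m] = [x_ov[m]; x_p[m-1]]`` (12-dim).  At each trigger the
    predictor propagates the delayed estimate through the internal model over
    the delay, accumulating the held control from the tail of the previous
    interval; the construction combines the difference equations for ``x_p[m]``
    and ``x_ov[m]`` using three Sylvester solutions:

    * ``Phi(h)``, ``Phi(tau)``: hold couplings of the stacked system,
    * ``Phi_1(tau)``: hold coupling of the internal model alone (predictor).
    """
    if not 0 < tau < h:
        raise ValueError(f"delay must satisfy 0 < tau < h, got tau={tau}, h={h}")
    A, B = internal.A, internal.B
    A_F = A - B @ K
    A_o, B_o = stacked_open_loop(plant, internal, L)
    n = A.shape[0]
    J = _estimate_projector(n)

    Phi_h = hold_coupling(A_o, B_o @ K, A_F, h)      # 8x4
    Phi_tau = hold_coupling(A_o, B_o @ K, A_F, tau)  # 8x4
    Phi1_tau = hold_coupling(A, B @ K, A_F, tau)     # 4x4

    eAtau = expm(A * tau)
    eAoh = expm(A_o * h)
    eAF_ht = expm(A_F * (h - tau))

    # x_p[m] = M1 x_ov[m] + M2 x_p[m-1]
    M1 = eAtau @ J @ expm(-A_o * tau)
    M2 = (eAtau @ J @ Phi_tau - eAtau @ Phi1_tau) @ eAF_ht
    # x_ov[m+1] = e^{A_o h} (x_ov[m] - Phi(h) x_p[m])
    TL = eAoh @ (np.eye(2 * n) - Phi_h @ M1)
    TR = -eAoh @ Phi_h @ M2
    return np.block([[TL, TR], [M1, M2]])


def _rk4_mat(f, Y: np.ndarray, t0: float, t1: float, n_steps: int) -> np.ndarray:
    dt = (t1 - t0) / n_steps
    t = t0
    for _ in range(n_steps):
        k1 = f(t, Y)
        k2 = f(t + dt / 2, Y + dt / 2 * k1)
        k3 = f(t + dt / 2, Y + dt / 2 * k2)
        k4 = f(t + dt, Y + dt * k3)
        Y = Y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return Y


def ic_monodromy_delayed_oracle(
    plant: LinearModel,
    internal: LinearModel,
    K: np.ndarray,
    L: np.ndarray,
    h: float,
    tau: float,
    step: float = 1e-5,
) -> np.ndarray:
    """Method-of-steps simulation oracle for the delayed IC monodromy.

    Integrates the hybrid dynamics over one period with fixed-step RK4,
    column-by-column in matrix form: reconstruct ``x_ov`` at the delayed
    trigger instant by integrating backward over the tail of the previous
    interval, run the predictor ODE forward over the delay, then integrate the
    new interval.  Entirely independent of the Sylvester construction.
    """
    if not 0 < tau < h:
        raise ValueError("requires 0 < tau < h")
    A, B = internal.A, internal.B
    A_F = A - B @ K
    A_o, B_o = stacked_open_loop(plant, internal, L)
    n = A.shape[0]
    J = _estimate_projector(n)
    E_ov = np.hstack([np.eye(2 * n), np.zeros((2 * n, n))])
    E_p = np.hstack([np.zeros((n, 2 * n)), np.eye(n)])

    def n_steps(span: float) -> int:
        return max(1, int(np.ceil(span / step)))

    # hold state over the previous interval, from its reset value x_p[m-1]
    Xh_end = _rk4_mat(lambda _t, Y: A_F @ Y, E_p, 0.0, h, n_steps(h))

    def coupled(_t, Z):
        X_ov, X_h = Z[: 2 * n], Z[2 * n :]
        return np.vstack([A_o @ X_ov - B_o @ K @ X_h, A_F @ X_h])

    # backward from the trigger to the delayed instant t_m - tau
    Z = _rk4_mat(coupled, np.vstack([E_ov, Xh_end]), h, h - tau, n_steps(tau))
    X_ov_del, X_h_del = Z[: 2 * n], Z[2 * n :]

    # predictor ODE xi' = A xi + B u over the delay, xi(t_m - tau) = estimate
    def predictor(_t, Z):
        Xi, X_h = Z[:n], Z[n:]
        return np.vstack([A @ Xi - B @ K @ X_h, A_F @ X_h])

    Z = _rk4_mat(predictor, np.vstack([J @ X_ov_del, X_h_del]), h - tau, h, n_steps(tau))
    X_p_new = Z[:n]

    # new interval with the freshly reset hold
    Z = _rk4_mat(coupled, np.vstack([E_ov, X_p_new]), 0.0, h, n_steps(h))
    return np.vstack([Z[: 2 * n], X_p_new])


def cc_closedloop_delayfree(
    plant: LinearModel,
    internal: LinearModel,
    K: np.ndarray,
    L: np.ndarray,
) -> np.ndarray:
    """Autonomous delay-free CC closed loop ``A_ov`` (8x8)."""
    A_bar, B_bar = plant.A, plant.B
    A, B, C = internal.A, internal.B, internal.C
    return np.block([[A_bar, -B_bar @ K], [L @ C, A - B @ K - L @ C]])


def zoh_discretize(A: np.ndarray, B: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact zero-order-hold discretization via the augmented exponential.

    Valid for singular ``A`` (the hand plant has a zero first column), unlike
    the ``A^{-1}(e^{A dt}-I)B`` formula.
    """
    n, m = A.shape[0], B.shape[1]
    M = np.zeros((n + m, n + m))
    M[:n, :n] = A * dt
    M[:n, n:] = B * dt
    E = expm(M)
    return E[:n, :n], E[:n, n:]


def cc_discrete_delayed(
    plant: LinearModel,
    internal: LinearModel,
    K: np.ndarray,
    L: np.ndarray,
    tau: float,
    delta: float,
) -> np.ndarray:
    """ZOH discrete equivalent ``A_ex`` of delayed CC, dimension ``8 + 4 k_tau``.

    Extended state ``[x(k-k_tau); xhat(k-k_tau); x_p(k-1); ...; x_p(k-k_tau)]``.
    The observer innovation is treated as a held input over each step, so the
    discrete observer gain is ``L_d = (int_0^delta e^{A s} ds) L``.
    """
    k_tau = tau / delta
    if abs(k_tau - round(k_tau)) > 1e-9 or round(k_tau) < 1:
        raise ValueError(f"tau/delta must be an integer >= 1, got {k_tau}")
    k_tau = int(round(k_tau))
    A_bar, B_bar = plant.A, plant.B
    A, B, C = internal.A, internal.B, internal.C
    n = A.shape[0]

    Abar_d, Bbar_d = zoh_discretize(A_bar, B_bar, delta)
    A_d, B_d = zoh_discretize(A, B, delta)
    _, L_d = zoh_discretize(A, L, delta)
    K_d = K

    N = 2 * n + n * k_tau
    M = np.zeros((N, N))
    last = 2 * n + n * (k_tau - 1)
    # plant and observer rows, driven by the oldest predicted state
    M[:n, :n] = Abar_d
    M[:n, last:] = -Bbar_d @ K_d
    M[n : 2 * n, :n] = L_d @ C
    M[n : 2 * n, n : 2 * n] = A_d - L_d @ C
    M[n : 2 * n, last:] = -B_d @ K_d
    # predictor row: propagate the delayed estimate and the buffered controls
    M[2 * n : 3 * n, n : 2 * n] = np.linalg.matrix_power(A_d, k_tau)
    A_pow = np.eye(n)
    for i in range(1, k_tau + 1):
        col = 2 * n + n * (i - 1)
        M[2 * n : 3 * n, col : col + n] += -A_pow @ B_d @ K_d
        A_pow = A_pow @ A_d
    # shift register of past predicted states
    for i in range(1, k_tau):
        r = 2 * n + n * i
        M[r : r + n, r - n : r] = np.eye(n)
    return M


# ---------------------------------------------------------------------------
# decision statistics and threshold location


def spectral_radius(M: np.ndarray, sparse_above: int = 100) -> float:
    """Largest eigenvalue modulus; ARPACK on large matrices, dense otherwise."""
    if M.shape[0] > sparse_above:
        vals = spla.eigs(sp.csr_matrix(M), k=8, return_eigenvectors=False)
        return float(np.max(np.abs(vals)))
    return float(np.max(np.abs(eigvals(M))))


def spectral_abscissa(M: np.ndarray) -> float:
    """Largest eigenvalue real part."""
    return float(np.max(eigvals(M).real))


_REGIMES = ("cc_delayfree", "cc_delayed", "ic_delayfree", "ic_delayed")


@dataclass(frozen=True)
class StabilityReport:
    regime: str
    statistic: float      # max |eig| (discrete regimes) or max Re eig (continuous)
    stable: bool
    params: dict

    @property
    def limit(self) -> float:
        return 0.0 if self.regime == "cc_delayfree" else 1.0


def _regime_statistic(
    regime: str,
    plant: LinearModel,
    internal: LinearModel,
    K: np.ndarray,
    L: np.ndarray,
    h: float,
    tau: float,
    delta: float,
) -> float:
    if regime == "ic_delayfree":
        return spectral_radius(ic_monodromy_delayfree(plant, internal, K, L, h))
    if regime == "ic_delayed":
        return spectral_radius(ic_monodromy_delayed(plant, internal, K, L, h, tau))
    if regime == "cc_delayfree":
        return spectral_abscissa(cc_closedloop_delayfree(plant, internal, K, L))
    if regime == "cc_delayed":
        return spectral_radius(cc_discrete_delayed(plant, internal, K, L, tau, delta))
    raise ValueError(f"unknown regime {regime!r}; expected one of {_REGIMES}")


def stability_report(
    regime: str,
    plant: LinearModel,
    internal: LinearModel,
    K: np.ndarray,
    L: np.ndarray,
    h: float = 0.2,
    tau: float = 0.0,
    delta: float = 1e-3,
) -> StabilityReport:
    """Decision statistic and verdict for one (regime, parameter) point."""
    stat = _regime_statistic(regime, plant, internal, K, L, h, tau, delta)
    limit = 0.0 if regime == "cc_delayfree" else 1.0
    return StabilityReport(
        regime=regime,
        statistic=stat,
        stable=bool(stat < limit),
        params={
            "m_pl": plant.params.m if plant.params else None,
            "gamma_pl": plant.params.gamma if plant.params else None,
            "h": h,
            "tau": tau,
            "delta": delta,
        },
    )


@dataclass(frozen=True)
class ThresholdResult:
    """Smallest stable plant mass in a bracket, or a sentinel.

    ``status`` is ``"crossing"`` (value holds the threshold), ``"stable"``
    (stable over the whole bracket; value is the bracket minimum) or
    ``"unstable"`` (unstable over the whole bracket; value is the maximum).
    """

    value: float
    status: str
    bracket: tuple[float, float]

    def __str__(self) -> str:
        if self.status == "stable":
            return f"< {self.bracket[0]:g}"
        if self.status == "unstable":
            return f"> {self.bracket[1]:g}"
        return f"{self.value:.3f}"


def stability_threshold(
    statistic,
    limit: float,
    bracket: tuple[float, float] = (0.2, 4.0),
    coarse_step: float = 0.02,
    resolution: float = 1e-3,
) -> ThresholdResult:
    """Locate the smallest scan value whose statistic is below ``limit``.

    Scans a coarse grid downward from the top of the bracket, then bisects the
    first stable/unstable pair to ``resolution``.  The statistic is assumed
    monotone near the crossing (it is, for the mass scans analyzed here).
    """
    lo, hi = bracket
    grid = np.arange(hi, lo - 1e-12, -coarse_step)
    prev = None
    for m in grid:
        if statistic(m) >= limit:
            if prev is None:
                return ThresholdResult(value=hi, status="unstable", bracket=bracket)
            a, b = m, prev
            while b - a > resolution:
                mid = 0.5 * (a + b)
                if statistic(mid) >= limit:
                    a = mid
                else:
                    b = mid
            return ThresholdResult(value=0.5 * (a + b), status="crossing", bracket=bracket)
        prev = m
    return ThresholdResult(value=lo, status="stable", bracket=bracket)


def mass_threshold(
    regime: str,
    m_im: float,
    gamma_im: float,
    Q_inf: np.ndarray | None = None,
    R_inf: float | None = None,
    noise_scale: float = 1.0,
    h: float = 0.2,
    tau: float = 0.0,
    delta: float = 1e-3,
    gamma_pl: float | None = None,
    bracket: tuple[float, float] = (0.2, 4.0),
    coarse_step: float | None = None,
    resolution: float = 1e-3,
) -> ThresholdResult:
    """Minimum stable plant mass for a regime, with gains from the internal model.

    Scans ``m_PL`` over ``bracket`` with the plant damping fixed at
    ``gamma_pl`` (defaults to the internal model's).  The delayed-CC regime
    uses a coarser default scan (its statistic is a large-matrix eigenvalue).
    """
    from .plant import PlantParams, Q_INF_NOMINAL, R_INF, build_plant
    from .lqg import design_lti_gains

    Q_inf = Q_INF_NOMINAL if Q_inf is None else Q_inf
    R_val = R_INF if R_inf is None else R_inf
    if gamma_pl is None:
        gamma_pl = gamma_im
    internal = build_plant(PlantParams(m=m_im, gamma=gamma_im), noise_scale=noise_scale)
    gains = design_lti_gains(internal, Q_inf, R_val)
    K, L = gains.K[0], gains.L[0]
    if coarse_step is None:
        coarse_step = 0.1 if regime == "cc_delayed" else 0.02
    limit = 0.0 if regime == "cc_delayfree" else 1.0

    def statistic(m_pl: float) -> float:
        plant = build_plant(PlantParams(m=m_pl, gamma=gamma_pl), noise_scale=noise_scale)
        return _regime_statistic(regime, plant, internal, K, L, h, tau, delta)

    return stability_threshold(
        statistic, limit, bracket=bracket, coarse_step=coarse_step, resolution=resolution
    )


def threshold_table(
    rows: list[tuple[float, float]] | None = None,
    h: float = 0.2,
    taus: tuple[float, float] = (0.1, 0.15),
    delta: float = 1e-3,
) -> "list[dict]":
    """Minimum stable mass table: IC and CC at two delays per internal model.

    ``rows`` are ``(m_im, gamma_im)`` pairs; defaults to the six combinations
    of m_im in {2,4,6} kg and gamma_im in {8,6} N s/m.
    """
    if rows is None:
        rows = [(2, 8), (4, 8), (6, 8), (2, 6), (4, 6), (6, 6)]
    out = []
    for m_im, g_im in rows:
        rec = {"m_im": m_im, "gamma_im": g_im}
        for tau in taus:
            rec[f"ic_tau{tau:g}"] = str(
                mass_threshold("ic_delayed", m_im, g_im, h=h, tau=tau)
            )
        for tau in taus:
            rec[f"cc_tau{tau:g}"] = str(
                mass_threshold("cc_delayed", m_im, g_im, tau=tau, delta=delta)
            )
        out.append(rec)
    return out


def eigenvalue_growth(lam: float, t: float, delta: float) -> float:
    """Growth factor ``lam**(t/delta)`` of a discrete eigenvalue after time t."""
    return float(lam ** (t / delta))
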