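"""Muscle-actuated hand model and its (possibly mismatched) internal model.

A single-joint reach is approximated as a translational damped point mass
(mass ``m``, viscous damping ``gamma``) driven by an over-damped second-order
muscle with time constant ``mu``::

    m p''(t) + gamma p'(t) = f(t)
    mu f'(t) + f(t) = g(t)
    mu g'(t) + g(t) = u(t) + w_g(t)

With state ``x = [p, p', f, g]`` this is the linear system ``x' = A x + B u + w``
where ``A`` is upper triangular with a zero first column (the plant is
marginally stable: position is a pure integral of velocity).  Only position and
velocity are sensed, through measurement noise of covariance ``V``.

The *internal model* used by observer, predictor, and hold is the same system
with its own mass/damping values, which may differ from the true plant's.
Coordinates place the reach target at the origin, so a reach of amplitude
``d`` starts at ``p = -d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import solve_continuous_are

__all__ = [
    "PlantParams",
    "LinearModel",
    "CostSpec",
    "DelaySamplingConfig",
    "build_plant",
    "build_cost",
    "MU",
    "SIGMA_G",
    "SIGMA_P",
    "SIGMA_V",
    "MOTOR_STEP",
    "Q_INF_NOMINAL",
    "Q_INF_MODIFIED",
    "R_INF",
    "NOMINAL_MASS_IM",
    "NOMINAL_DAMPING_IM",
    "TARGET_DISTANCE",
    "REACH_TIME",
]

#: Muscle time constant [s] (both muscle stages share it).
MU = 0.04
#: Motor (process) noise std [N] of the per-update command disturbance.
SIGMA_G = 0.46
#: Visual position measurement noise std [m].
SIGMA_P = 0.005
#: Visual velocity measurement noise std [m/s].
SIGMA_V = 0.04
#: Update interval [s] at which the motor noise draw is defined.  The noise
#: magnitudes above are per-sample values of a sensorimotor model discretized
#: at 10 ms; converting the motor draw to a continuous white-noise intensity
#: multiplies its variance by 1/MOTOR_STEP.  See docs/methods.md.
MOTOR_STEP = 0.01

#: Nominal state cost diag(1, 0.2^2, 0.02^2, 0): position error dominates,
#: with smaller penalties on residual velocity and muscle force.
Q_INF_NOMINAL = np.diag([1.0, 0.2**2, 0.02**2, 0.0])
#: Variant with a reduced velocity penalty, diag(1, 0.1^2, 0.02^2, 0).
Q_INF_MODIFIED = np.diag([1.0, 0.1**2, 0.02**2, 0.0])
#: Control effort weight.
R_INF = 1e-5

NOMINAL_MASS_IM = 2.0       # kg (forearm + hand + expected load)
NOMINAL_DAMPING_IM = 8.0    # N s/m
TARGET_DISTANCE = 0.2       # m
REACH_TIME = 0.6            # s


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain (e.g. non-positive mass)."""


class SynthesisError(RuntimeError):
    """A Riccati / gain-synthesis step failed."""


@dataclass(frozen=True)
class PlantParams:
    """Physical parameters of the plant or of its internal model."""

    m: float                 # mass [kg]
    gamma: float             # viscous damping [N s/m]
    mu: float = MU           # muscle time constant [s]

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise InvalidParameterError(f"mass must be positive, got {self.m}")
        if self.gamma < 0:
            raise InvalidParameterError(f"damping must be >= 0, got {self.gamma}")
        if not self.mu > 0:
            raise InvalidParameterError(f"muscle time constant must be positive, got {self.mu}")


@dataclass(frozen=True)
class LinearModel:
    """State-space model with noise covariances.

    ``A`` (4x4), ``B`` (4x1), ``C`` (2x4), process-noise intensity ``W``
    (4x4) and measurement-noise intensity ``V`` (2x2).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    W: np.ndarray
    V: np.ndarray
    params: PlantParams | None = None

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def q(self) -> int:
        return self.C.shape[0]


def build_plant(
    params: PlantParams,
    sigma_g: float = SIGMA_G,
    sigma_p: float = SIGMA_P,
    sigma_v: float = SIGMA_V,
    noise_scale: float = 1.0,
    motor_step: float = MOTOR_STEP,
) -> LinearModel:
    """Assemble the state-space hand model for the given physical parameters.

    ``noise_scale`` scales the measurement covariance (``V = noise_scale * V0``),
    which is how the nominal-vs-tenfold-less-noisy comparison is expressed.
    The motor noise enters the last state equation as ``w_g / mu``; since
    ``sigma_g`` is the std of a per-``motor_step`` discrete draw, its
    continuous intensity is ``sigma_g**2 / motor_step``.
    """
    if noise_scale <= 0:
        raise InvalidParameterError("noise_scale must be positive")
    m, g, mu = params.m, params.gamma, params.mu
    A = np.array(
        [
            [0.0, 1.0, 0.0, 0.0],
            [0.0, -g / m, 1.0 / m, 0.0],
            [0.0, 0.0, -1.0 / mu, 1.0 / mu],
            [0.0, 0.0, 0.0, -1.0 / mu],
        ]
    )
    B = np.array([[0.0], [0.0], [0.0], [1.0 / mu]])
    C = np.hstack([np.eye(2), np.zeros((2, 2))])
    W = np.diag([0.0, 0.0, 0.0, (sigma_g / mu) ** 2 / motor_step])
    V = noise_scale * np.diag([sigma_p**2, sigma_v**2])
    return LinearModel(A=A, B=B, C=C, W=W, V=V, params=params)


@dataclass(frozen=True)
class CostSpec:
    """Quadratic reaching cost with a finite horizon ``T``.

    The running state cost is zero before the desired reaching time and
    ``Q_inf`` from ``T`` on (right-closed at the boundary), which shapes a
    discrete reach while keeping the stationary gains active afterwards.  The
    terminal weight ``S_T`` equals the infinite-horizon Riccati solution so the
    feedback gain is continuous at ``T``.
    """

    T: float
    Q_inf: np.ndarray
    R_inf: float
    S_T: np.ndarray
    Q: Callable[[float], np.ndarray] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.Q is None:
            object.__setattr__(self, "Q", self._q_of_t)

    def _q_of_t(self, t: float) -> np.ndarray:
        return self.Q_inf if t >= self.T else np.zeros_like(self.Q_inf)


def build_cost(
    T: float,
    Q_inf: np.ndarray,
    R_inf: float,
    A: np.ndarray,
    B: np.ndarray,
) -> CostSpec:
    """Build the reaching cost, solving the control ARE for the terminal weight."""
    if R_inf <= 0:
        raise InvalidParameterError("R_inf must be positive")
    try:
        S_T = solve_continuous_are(A, B, Q_inf, np.atleast_2d(R_inf))
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise SynthesisError(f"terminal Riccati solve failed: {exc}") from exc
    return CostSpec(T=T, Q_inf=np.asarray(Q_inf, dtype=float), R_inf=float(R_inf), S_T=S_T)


@dataclass(frozen=True)
class DelaySamplingConfig:
    """Timing of measurement delay, intermittent sampling, and discretization."""

    tau: float = 0.0         # measurement delay [s]
    h: float = 0.2           # intermittent-control sampling period [s]
    delta: float = 1e-3      # discretization step [s]

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise InvalidParameterError("delay must be >= 0")
        if self.h <= 0 or self.delta <= 0:
            raise InvalidParameterError("sampling period and step must be positive")

    @property
    def k_tau(self) -> int:
        k = self.tau / self.delta
        if abs(k - round(k)) > 1e-9:
            raise InvalidParameterError(
                f"tau/delta = {k} must be an integer (tau={self.tau}, delta={self.delta})"
            )
        return int(round(k))
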