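"""Dysmetria and early-velocity analysis of simulated reaches.

Following the conventions of reaching studies in cerebellar patients:

* *movement onset* — the first time hand speed exceeds 0.05 m/s;
* *early velocity* — the velocity 0.15 s after onset (a proxy for the
  preplanned, feedback-free phase of the movement);
* *first correction* — after the velocity peak, the earlier of the velocity
  dropping below 0.01 m/s or reaching a local minimum;
* *dysmetria* — signed position error at first correction, positive for
  overshoot (hypermetria) and negative for undershoot (hypometria).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import lqg, plant as plant_mod, simulate
from .plant import PlantParams, Q_INF_NOMINAL, R_INF, REACH_TIME, build_cost, build_plant
from .simulate import Trajectory

__all__ = [
    "ReachMetrics",
    "SweepResult",
    "detect_onset",
    "early_velocity",
    "first_correction",
    "dysmetria",
    "mismatch_sweep",
]

ONSET_SPEED = 0.05        # m/s
CORRECTION_SPEED = 0.01   # m/s
EARLY_OFFSET = 0.15       # s after onset
SMOOTH_WINDOW = 5         # samples, moving average before local-minimum search


class NoMovementError(RuntimeError):
    """The velocity never exceeds the onset threshold."""


@dataclass(frozen=True)
class ReachMetrics:
    onset_t: float
    early_v: float
    correction_t: float
    correction_p: float
    dysmetria: float            # m, positive = overshoot
    criterion: str              # "velocity-threshold" | "local-minimum" | "end-of-record"


def detect_onset(traj: Trajectory) -> float:
    """First grid time at which the velocity exceeds the onset threshold."""
    idx = np.flatnonzero(traj.velocity > ONSET_SPEED)
    if idx.size == 0:
        raise NoMovementError("velocity never exceeded the onset threshold")
    return float(traj.t[idx[0]])


def early_velocity(traj: Trajectory) -> float:
    """Velocity sampled ``EARLY_OFFSET`` after movement onset."""
    t_eval = detect_onset(traj) + EARLY_OFFSET
    if t_eval > traj.t[-1]:
        raise ValueError("trajectory too short to evaluate early velocity")
    return float(np.interp(t_eval, traj.t, traj.velocity))


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v
    # edge-padded moving average: zero padding would depress the record ends
    # and create spurious peaks/minima there
    half = window // 2
    padded = np.pad(v, (half, window - 1 - half), mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def first_correction(traj: Trajectory, window: int = SMOOTH_WINDOW) -> tuple[float, float, str]:
    """Time, position, and criterion of the first correction.

    After the (smoothed) velocity peak, take the earlier of (i) the velocity
    descending below the correction threshold, and (ii) a strict local minimum
    of the smoothed velocity.  Falls back to the end of the record, flagged,
    if neither occurs.
    """
    onset_t = detect_onset(traj)
    v = _smooth(traj.velocity, window)
    start = int(np.searchsorted(traj.t, onset_t))
    peak = start + int(np.argmax(v[start:]))

    below = np.flatnonzero(v[peak + 1 :] < CORRECTION_SPEED)
    i_below = peak + 1 + below[0] if below.size else None

    seg = v[peak + 1 :]
    interior = np.flatnonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] < seg[2:]))
    i_min = peak + 2 + interior[0] if interior.size else None

    candidates = [(i, c) for i, c in ((i_below, "velocity-threshold"), (i_min, "local-minimum")) if i is not None]
    if not candidates:
        i, crit = len(v) - 1, "end-of-record"
    else:
        i, crit = min(candidates, key=lambda ic: ic[0])
    return float(traj.t[i]), float(traj.position[i]), crit


def dysmetria(traj: Trajectory, target: float | None = None) -> float:
    """Signed reach error at first correction; positive = overshoot."""
    if target is None:
        target = traj.target
    _, p, _ = first_correction(traj)
    return float(p - target)


@dataclass
class SweepResult:
    varied: str                     # "mass" | "damping"
    values: np.ndarray
    records: pd.DataFrame           # per (value, mode) metrics
    regressions: dict               # mode -> {slope, intercept, r, n}


def _metrics_record(traj: Trajectory) -> ReachMetrics:
    onset_t = detect_onset(traj)
    ev = early_velocity(traj)
    ct, cp, crit = first_correction(traj)
    return ReachMetrics(
        onset_t=onset_t,
        early_v=ev,
        correction_t=ct,
        correction_p=cp,
        dysmetria=cp - traj.target,
        criterion=crit,
    )


def mismatch_sweep(
    vary: str = "mass",
    m_im: float = 2.0,
    gamma_im: float = 8.0,
    n_values: int = 9,
    span: float | None = None,
    modes: tuple[str, ...] = ("cc", "ic"),
    Q_inf: np.ndarray | None = None,
    tau: float = 0.15,
    h: float = 0.2,
    T: float = REACH_TIME,
    duration: float = 2.0,
    noise: bool = False,
    seed: int | None = None,
    dt: float = 1e-3,
) -> SweepResult:
    """Reach with a range of true plants under gains designed for one model.

    ``vary="mass"`` sweeps ``m_PL`` over ``m_im +- span`` (default span 0.5 kg
    at m_im = 2, scaled proportionally for other internal models);
    ``vary="damping"`` sweeps ``gamma_PL`` over ``gamma_im +- 2`` N s/m.
    Values are evenly spaced, endpoints included, so the accurate model sits
    at the center.  Runs use time-varying feedback gains (reaching time ``T``)
    and the stationary observer gain; dysmetria is regressed on early
    velocity per control mode.
    """
    if vary == "mass":
        if span is None:
            span = 0.25 * m_im
        values = np.linspace(m_im - span, m_im + span, n_values)
    elif vary == "damping":
        if span is None:
            span = 2.0
        values = np.linspace(gamma_im - span, gamma_im + span, n_values)
    else:
        raise ValueError("vary must be 'mass' or 'damping'")

    Q_inf = Q_INF_NOMINAL if Q_inf is None else Q_inf
    internal = build_plant(PlantParams(m=m_im, gamma=gamma_im))
    cost = build_cost(T, Q_inf, R_INF, internal.A, internal.B)
    grid = np.arange(0.0, duration + dt / 2, dt)
    K_arr, S_arr = lqg.feedback_schedule(internal, cost, grid)
    L_inf, P_inf = lqg.kalman_gain_infinite(internal)
    gains = lqg.GainSchedule(
        t=grid, K=K_arr, L=L_inf[None, :, :], S=S_arr[-1], P=P_inf
    )

    rows = []
    for i, val in enumerate(values):
        pp = PlantParams(m=val if vary == "mass" else m_im,
                         gamma=val if vary == "damping" else gamma_im)
        true_plant = build_plant(pp)
        cfg = simulate.SimConfig(
            duration=duration, dt=dt, tau=tau, h=h, noise=noise,
            seed=None if seed is None else seed + i,
        )
        for mode in modes:
            run = simulate.simulate_cc if mode == "cc" else simulate.simulate_ic
            traj = run(true_plant, internal, gains, cfg)
            if traj.unstable:
                rows.append({"value": val, "mode": mode, "excluded": True})
                continue
            rec = _metrics_record(traj)
            rows.append(
                {
                    "value": val,
                    "mode": mode,
                    "excluded": False,
                    "onset_t": rec.onset_t,
                    "early_v": rec.early_v,
                    "correction_t": rec.correction_t,
                    "dysmetria": rec.dysmetria,
                    "criterion": rec.criterion,
                }
            )
    frame = pd.DataFrame(rows)
    regressions = {}
    for mode in modes:
        sub = frame[(frame["mode"] == mode) & (~frame["excluded"])]
        if len(sub) >= 3:
            fit = linregress(sub["early_v"], sub["dysmetria"])
            regressions[mode] = {
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r": float(fit.rvalue),
                "n": int(len(sub)),
            }
    return SweepResult(varied=vary, values=values, records=frame, regressions=regressions)
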