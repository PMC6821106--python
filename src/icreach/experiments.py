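"""Registered experiment runners: parameter scans, trajectory demos, sweeps.

Each runner recomputes one of the package's headline analyses from its
parameters and writes deterministic CSV/JSON outputs plus a manifest.  No
result values are computed here; everything delegates to the library modules.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, lqg, metrics, simulate, stability
from .plant import (
    NOMINAL_DAMPING_IM,
    NOMINAL_MASS_IM,
    PlantParams,
    Q_INF_MODIFIED,
    Q_INF_NOMINAL,
    R_INF,
    build_plant,
)

__all__ = ["run_experiment", "EXPERIMENTS"]


def _manifest(outdir: Path, name: str, params: dict, outputs: list[str], t0: float) -> None:
    import scipy

    manifest = {
        "experiment": name,
        "params": params,
        "outputs": outputs,
        "seed": params.get("seed"),
        "versions": {
            "icreach": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "git_hash": None,
        "wall_time_s": round(time.time() - t0, 3),
    }
    (outdir / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=2))


def _scan_frame(regime: str, m_values, statistic) -> pd.DataFrame:
    limit = 0.0 if regime == "cc_delayfree" else 1.0
    rows = [{"m_pl": m, "statistic": statistic(m), "stable": statistic(m) < limit} for m in m_values]
    return pd.DataFrame(rows)


def stability_scan(
    regime: str,
    m_im: float = NOMINAL_MASS_IM,
    gamma_im: float = NOMINAL_DAMPING_IM,
    noise_scale: float = 1.0,
    h: float = 0.2,
    tau: float = 0.0,
    delta: float = 1e-3,
    m_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decision statistic over a plant-mass grid for one regime."""
    internal = build_plant(PlantParams(m=m_im, gamma=gamma_im), noise_scale=noise_scale)
    gains = lqg.design_lti_gains(internal, Q_INF_NOMINAL, R_INF)
    K, L = gains.K[0], gains.L[0]
    if m_grid is None:
        step = 0.1 if regime == "cc_delayed" else 0.02
        m_grid = np.arange(0.2, 4.0 + step / 2, step)
    rows = []
    for m in m_grid:
        plant = build_plant(PlantParams(m=m, gamma=gamma_im), noise_scale=noise_scale)
        rep = stability.stability_report(regime, plant, internal, K, L, h=h, tau=tau, delta=delta)
        rows.append({"m_pl": m, "statistic": rep.statistic, "stable": rep.stable})
    return pd.DataFrame(rows)


def _run_eig_scan_figure(outdir, name, regimes, seed=None, **kw):
    t0 = time.time()
    outputs = []
    for label, regime, extra in regimes:
        frame = stability_scan(regime, **{**kw, **extra})
        fn = f"{name}_{label}.csv"
        frame.to_csv(outdir / fn, index=False)
        outputs.append(fn)
    _manifest(outdir, name, {**kw, "seed": seed}, outputs, t0)
    return outputs


def run_fig2(outdir: Path, seed=None, noise_scale: float = 1.0) -> list[str]:
    """Delay-free eigenvalue analysis: IC at h in {0.05, 0.1, 0.2} vs CC."""
    regimes = [(f"ic_h{h:g}", "ic_delayfree", {"h": h}) for h in (0.05, 0.1, 0.2)]
    regimes.append(("cc", "cc_delayfree", {}))
    return _run_eig_scan_figure(outdir, "fig2", regimes, seed=seed, noise_scale=noise_scale)


def run_fig4(outdir: Path, seed=None) -> list[str]:
    """Delayed eigenvalue analysis: IC (h=0.2) and discretized CC over delays."""
    regimes = [(f"ic_tau{t:g}", "ic_delayed", {"h": 0.2, "tau": t}) for t in (0.1, 0.15)]
    regimes += [(f"cc_tau{t:g}", "cc_delayed", {"tau": t}) for t in (0.001, 0.1, 0.15)]
    return _run_eig_scan_figure(outdir, "fig4", regimes, seed=seed)


def _demo_trajectories(outdir, name, configs, seed, noise, noise_scale=1.0):
    t0 = time.time()
    outputs = []
    internal = build_plant(PlantParams(m=2.0, gamma=8.0), noise_scale=noise_scale)
    gains = lqg.design_lti_gains(internal, Q_INF_NOMINAL, R_INF)
    for label, mode, m_pl, h, tau in configs:
        plant = build_plant(PlantParams(m=m_pl, gamma=8.0), noise_scale=noise_scale)
        cfg = simulate.SimConfig(duration=3.0, tau=tau, h=h, noise=noise, seed=seed)
        run = simulate.simulate_ic if mode == "ic" else simulate.simulate_cc
        traj = run(plant, internal, gains, cfg)
        fn = f"{name}_{label}.csv"
        traj.to_frame().to_csv(outdir / fn, index=False)
        outputs.append(fn)
    _manifest(outdir, name, {"seed": seed, "noise": noise, "noise_scale": noise_scale}, outputs, t0)
    return outputs


def run_fig3(outdir: Path, seed=0, noise_scale: float = 1.0) -> list[str]:
    """Delay-free reaches at m_PL=0.4: IC stable at h=0.2, unstable at h=0.1."""
    configs = [
        ("ic_h0.1", "ic", 0.4, 0.1, 0.0),
        ("ic_h0.2", "ic", 0.4, 0.2, 0.0),
        ("cc", "cc", 0.4, 0.2, 0.0),
    ]
    return _demo_trajectories(outdir, "fig3", configs, seed, noise=True, noise_scale=noise_scale)


def run_fig5(outdir: Path, seed=0) -> list[str]:
    """Delayed reaches at m_PL=0.4: IC stable at tau=0.15, unstable at 0.1; CC unstable."""
    configs = [
        ("ic_tau0.1", "ic", 0.4, 0.2, 0.1),
        ("ic_tau0.15", "ic", 0.4, 0.2, 0.15),
        ("cc_tau0.1", "cc", 0.4, 0.2, 0.1),
        ("cc_tau0.15", "cc", 0.4, 0.2, 0.15),
    ]
    return _demo_trajectories(outdir, "fig5", configs, seed, noise=True)


def run_table1(outdir: Path, seed=None) -> list[str]:
    """Six-row minimum-stable-mass table (IC and CC at tau = 0.1 and 0.15 s)."""
    t0 = time.time()
    rows = stability.threshold_table()
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "table1.csv", index=False)
    _manifest(outdir, "table1", {"seed": seed}, ["table1.csv"], t0)
    return ["table1.csv"]


def _mismatch_figure(outdir, name, mode_params, seed):
    t0 = time.time()
    outputs = []
    internal = build_plant(PlantParams(m=2.0, gamma=8.0))
    import numpy as _np

    from .plant import REACH_TIME, build_cost

    cost = build_cost(REACH_TIME, Q_INF_NOMINAL, R_INF, internal.A, internal.B)
    grid = _np.arange(0.0, 2.0 + 5e-4, 1e-3)
    K_arr, _ = lqg.feedback_schedule(internal, cost, grid)
    L_inf, _ = lqg.kalman_gain_infinite(internal)
    gains = lqg.GainSchedule(t=grid, K=K_arr, L=L_inf[None, :, :])
    for label, mode, m_pl, g_pl in mode_params:
        plant = build_plant(PlantParams(m=m_pl, gamma=g_pl))
        cfg = simulate.SimConfig(duration=2.0, tau=0.15, h=0.2, noise=False, seed=seed)
        run = simulate.simulate_ic if mode == "ic" else simulate.simulate_cc
        traj = run(plant, internal, gains, cfg)
        fn = f"{name}_{label}.csv"
        traj.to_frame().to_csv(outdir / fn, index=False)
        outputs.append(fn)
    _manifest(outdir, name, {"seed": seed}, outputs, t0)
    return outputs


def run_fig6(outdir: Path, seed=None) -> list[str]:
    """Mass mismatch: accurate, lighter, heavier plants under CC and IC."""
    params = [
        (f"{mode}_m{m:g}", mode, m, 8.0)
        for mode in ("cc", "ic")
        for m in (1.5, 2.0, 2.5)
    ]
    return _mismatch_figure(outdir, "fig6", params, seed)


def run_fig7(outdir: Path, seed=None) -> list[str]:
    """Damping mismatch: smaller, equal, larger damping under CC and IC."""
    params = [
        (f"{mode}_g{g:g}", mode, 2.0, g)
        for mode in ("cc", "ic")
        for g in (6.0, 8.0, 10.0)
    ]
    return _mismatch_figure(outdir, "fig7", params, seed)


def _sweep_runner(outdir, name, sweeps, seed):
    t0 = time.time()
    outputs = []
    for label, kw in sweeps:
        res = metrics.mismatch_sweep(seed=seed, **kw)
        fn = f"{name}_{label}.csv"
        res.records.to_csv(outdir / fn, index=False)
        (outdir / f"{name}_{label}_regression.json").write_text(
            json.dumps(res.regressions, indent=2)
        )
        outputs += [fn, f"{name}_{label}_regression.json"]
    _manifest(outdir, name, {"seed": seed}, outputs, t0)
    return outputs


def run_fig8(outdir: Path, seed=None) -> list[str]:
    """Dysmetria vs early velocity for mass and damping sweeps (nominal cost)."""
    sweeps = [
        ("mass", {"vary": "mass", "m_im": 2.0, "gamma_im": 8.0}),
        ("damping", {"vary": "damping", "m_im": 2.0, "gamma_im": 8.0}),
    ]
    return _sweep_runner(outdir, "fig8", sweeps, seed)


def run_fig9(outdir: Path, seed=None) -> list[str]:
    """Mass sweeps under the reduced-velocity-penalty cost, m_IM = 2 and 4 kg."""
    sweeps = [
        ("mim2", {"vary": "mass", "m_im": 2.0, "gamma_im": 8.0, "Q_inf": Q_INF_MODIFIED}),
        ("mim4", {"vary": "mass", "m_im": 4.0, "gamma_im": 8.0, "Q_inf": Q_INF_MODIFIED}),
    ]
    return _sweep_runner(outdir, "fig9", sweeps, seed)


EXPERIMENTS = {
    "fig2": run_fig2,
    "fig3": run_fig3,
    "fig4": run_fig4,
    "fig5": run_fig5,
    "fig6": run_fig6,
    "fig7": run_fig7,
    "fig8": run_fig8,
    "fig9": run_fig9,
    "table1": run_table1,
}


def run_experiment(name: str, outdir: str | Path, seed: int | None = None, **overrides):
    """Run a registered experiment, writing CSV/JSON outputs and a manifest."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; known: {sorted(EXPERIMENTS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return EXPERIMENTS[name](outdir, seed=seed, **overrides)
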