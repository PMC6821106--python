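"""Simulated reach with an accurate vs. a mismatched internal model.

Reaches 0.2 m in T = 0.6 s with measurement delay tau = 0.15 s, comparing
continuous control with periodic intermittent control (h = 0.2 s).  With an
accurate model the system-matched hold replicates the continuous predictor
exactly, so the two trajectories coincide; with a heavier-than-expected plant
both overshoot.
"""

import numpy as np

from icreach import (
    GainSchedule,
    PlantParams,
    SimConfig,
    build_cost,
    build_plant,
    dysmetria,
    feedback_schedule,
    kalman_gain_infinite,
    simulate_cc,
    simulate_ic,
)
from icreach.plant import Q_INF_NOMINAL, R_INF, REACH_TIME

internal = build_plant(PlantParams(m=2.0, gamma=8.0))
cost = build_cost(REACH_TIME, Q_INF_NOMINAL, R_INF, internal.A, internal.B)
grid = np.arange(0.0, 2.0 + 5e-4, 1e-3)
K_arr, _ = feedback_schedule(internal, cost, grid)
L_inf, _ = kalman_gain_infinite(internal)
gains = GainSchedule(t=grid, K=K_arr, L=L_inf[None, :, :])
cfg = SimConfig(duration=2.0, tau=0.15, h=0.2)

for m_pl in (2.0, 2.5):
    plant = build_plant(PlantParams(m=m_pl, gamma=8.0))
    tcc = simulate_cc(plant, internal, gains, cfg)
    tic = simulate_ic(plant, internal, gains, cfg)
    print(f"m_PL = {m_pl} kg (internal model expects 2.0 kg):")
    print(f"  CC: final position {tcc.position[-1]:.4f} m, dysmetria {dysmetria(tcc)*1000:+.1f} mm")
    print(f"  IC: final position {tic.position[-1]:.4f} m, dysmetria {dysmetria(tic)*1000:+.1f} mm")
    print(f"  max |CC - IC| position gap: {np.abs(tcc.position - tic.position).max()*1000:.3f} mm")

print()
print("Positive dysmetria = overshoot at the first movement correction.")
print("The accurate-model gap is at numerical precision: the hold is exact.")
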