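# icreach

Continuous vs. periodic intermittent LQG control of inaccurately modeled
reaching movements: closed-form stability criteria, observer–predictor–
controller simulation with measurement delay, and dysmetria analysis.

## The problem

Human motor control is commonly modeled as stochastic optimal feedback
control: an observer (Kalman filter) estimates the state from noisy, delayed
measurements, a predictor bridges the delay, and a feedback controller acts
on the prediction.  Whether these processes communicate *continuously*
(continuous control, CC) or only at discrete trigger times (intermittent
control, IC) is an open question.  Under periodic IC with a *system-matched
hold* (SMH), the predictor runs only every `h` seconds; between triggers a
hold state `x_h` propagates the last prediction through the internal-model
closed loop, `ẋ_h = (A − B K) x_h`, and the control is `u = −K x_h`.

A viable controller must tolerate *inaccurately modeled plants* — lifting a
lighter load than expected, for instance.  This package quantifies that
tolerance for a muscle-actuated hand model

```
m_PL p̈ + γ_PL ṗ = f,    μ f˙ + f = g,    μ ġ + g = u + w_g,
```

with state `x = [p, ṗ, f, g]`, whose internal model differs only in mass and
damping (`m_IM`, `γ_IM`).  Gains are the LQG solution *for the internal
model*: `K = R⁻¹B′S` and `L = P C′V⁻¹` from the control and filter algebraic
Riccati equations (stationary case), or from the corresponding Riccati ODEs
(time-varying reaching gains).

## Stability criteria

With time-invariant gains, four regimes are decided spectrally:

- **CC, delay-free** — eigenvalues of the 8-dim closed loop
  `A_ov = [[Ā, −B̄K], [LC, A−BK−LC]]`; stable iff max Re λ < 0.
- **IC, delay-free** — the trigger-to-trigger monodromy
  `A_p = e^{A_o h}(I − S[0 I])`, where `S` solves one Sylvester equation
  `A_o S − S A_F + (e^{−A_o h} B_o K e^{A_F h} − B_o K) = 0`; stable iff the
  spectral radius is < 1.
- **IC with measurement delay `τ < h`** — a 12-dim monodromy on
  `[x_ov; x_p[m−1]]` assembled from three Sylvester solutions (validated
  against an independent method-of-steps integration oracle).
- **CC with delay** — the zero-order-hold discrete equivalent `A_ex` of
  dimension `8 + 4·τ/Δ` with a shift register of past predictions.

`mass_threshold` locates the minimum stable plant mass over
`m_PL ∈ [0.2, 4]` kg by a coarse scan plus bisection.

## Worked example

```
$ python examples/01_stability_thresholds.py
Delay-free periodic IC (nominal measurement noise):
  h = 0.05 s -> minimum stable m_PL = 0.329 kg
  h =  0.1 s -> minimum stable m_PL = 0.493 kg
  h =  0.2 s -> minimum stable m_PL = < 0.2 kg
Delay-free periodic IC (tenfold less measurement noise, V = V0/10):
  h = 0.05 s -> minimum stable m_PL = 0.522 kg
  h =  0.1 s -> minimum stable m_PL = 0.763 kg
Delay-free CC:
  V = V0     -> minimum stable m_PL = < 0.2 kg
  V = V0/10  -> minimum stable m_PL = 0.489 kg
```

Reading: with gains designed for a 2 kg load, periodic IC at `h = 0.05 s`
loses stability only when the true mass drops below ≈0.33 kg; at `h = 0.2 s`
(and for CC with nominal noise) it is stable over the entire scanned range.
Less noisy measurements make the observer *more* aggressive and narrow the
stable range — over-reaction to measurements the inaccurate internal model
cannot explain.

`examples/02_reaching_simulation.py` simulates delayed reaches (accurate
model: IC and CC coincide to numerical precision — the hold is exact;
heavier plant: both overshoot by ≈13 mm), and
`examples/03_dysmetria_sweep.py` reproduces the dysmetria/early-velocity
regressions (mass sweep: slopes −0.26/−0.19 m per m/s for CC/IC; damping
sweep: +0.27/+0.71), the sign pattern observed in cerebellar reaching
studies.

A thin CLI exposes the same machinery:
`icreach stability --regime ic --h 0.05 --out results.csv`,
`icreach simulate --mode ic --m-pl 2.5 --tau 0.15 --out traj.csv`,
`icreach dysmetria-sweep --vary mass --out sweep.csv`,
`icreach experiment fig2|...|fig9|table1 --outdir results`.

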