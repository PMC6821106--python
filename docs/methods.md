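# Methods

## Model

The hand and forearm (plus any held load) are a translational damped point
mass driven by a second-order over-damped muscle:

```
m_PL p̈ + γ_PL ṗ = f,   μ f˙ + f = g,   μ ġ + g = u + w_g,
```

state `x = [p, ṗ, f, g]` (SI units throughout), muscle time constant
`μ = 0.04 s`.  The system matrix is upper triangular with a zero first
column, so the open-loop plant is marginally stable (position is a pure
integrator of velocity) and singular — every zero-order-hold (ZOH)
discretization here therefore uses the augmented-matrix-exponential form,
never `A⁻¹(e^{AΔ}−I)B`.

Position and velocity are sensed (`C = [I₂ 0]`) through white measurement
noise.  Coordinates place the target at the origin; a reach of amplitude
`d = 0.2 m` starts at `x(0) = (−d, 0, 0, 0)`, which is an equilibrium under
zero control — a property the delay buffers exploit (pre-movement history is
exactly representable).  Reported positions are re-shifted so the target sits
at `+0.2 m`.

### Noise intensities

Defaults: `σ_g = 0.46 N` (motor), `σ_p = 0.005 m`, `σ_v = 0.04 m/s`
(visual).  These magnitudes originate in discretely sampled sensorimotor
models with a 10 ms update; `σ_g` is the standard deviation of the
per-update motor disturbance, so its continuous-time white-noise intensity
is `σ_g²/0.01`, giving `W = diag(0, 0, 0, (σ_g/μ)²/0.01)`.  The measurement
covariance is used as printed, `V = noise_scale · diag(σ_p², σ_v²)`, with
`noise_scale = 1` (nominal, `V₀`) or `0.1` (the less-noisy comparison).
Only the ratio `W/V` enters the Kalman design — rescaling both by a common
factor leaves every gain, spectrum, and threshold unchanged — so the choice
above is equivalent to reading the measurement variances as per-sample
values at a 100 Hz sensory frame rate.  It is the unique one-parameter
reading of the printed noise magnitudes under which the full threshold table
of the stability analysis is reproduced; see the limitations note below.

### Cost

`J = E[x′(T) S(T) x(T) + ∫₀ᵀ x′Qx + u′Ru dt]` with `T = 0.6 s`,
`R = 10⁻⁵`, and running cost `Q(t) = 0` for `t < T`, `Q_∞ =
diag(1, 0.2², 0.02², 0)` for `t ≥ T` (right-closed at the boundary, which
makes `K(t)` continuous at `T`).  Setting `S(T) = S_∞(Q_∞, R_∞)` makes the
finite-horizon problem equivalent to an infinite-horizon one whose running
cost switches on at `T`, so the gains neither vanish nor jump after the
nominal reaching time.  A variant `Q_∞ = diag(1, 0.1², 0.02², 0)` reduces
the terminal velocity penalty.

## Gain synthesis (`lqg`)

Gains are always designed from the *internal model* — as if the plant were
modeled accurately.  Stationary gains solve the two algebraic Riccati
equations (`scipy.linalg.solve_continuous_are`).  Time-varying feedback
gains integrate the control Riccati ODE backward from `S(T) = S_∞` with
LSODA at rtol 1e−8, sampled onto the simulation grid with zero-order hold;
time-varying observer gains integrate the filter Riccati ODE forward from a
configurable `P₀` (default `P_∞`, i.e. a stationary filter — the transient
filter start is available but not the default, since nothing in the analyzed
task pins `P(0)`).

## Stability criteria (`stability`)

All four regime constructions and their independent oracles are described in
the module docstring and README.  Numerical choices:

- **Sylvester solves** use the Schur-based `scipy` solver plus one pass of
  iterative refinement; the feedback-gain magnitudes (`‖B_o K‖ ~ 10⁴`)
  otherwise leave residuals near 1e−8, and refinement brings
  construction-vs-oracle agreement to ~1e−11.  A residual guard raises on
  (near-)singular instances, i.e. when `A_o` and `A_F` share spectrum.
- **Delayed-CC observer discretization**: the innovation is treated as a
  held input over each step, `L_d = (∫₀^Δ e^{As} ds) L`.  The alternatives
  (`L_d = ΔL`, exact `e^{(A−LC)Δ}` factorization) shift thresholds by
  < 0.002 kg at `Δ = 10⁻³ s` — immaterial.
- **Decision statistic**: max eigenvalue modulus (discrete maps) or max real
  part (continuous).  Dense eigensolves up to dimension 100, ARPACK
  (`k = 8`, largest modulus) above; agreement checked to 1e−13.
- **Threshold search**: coarse downward scan (step 0.02 kg; 0.1 kg for the
  large delayed-CC matrices) then bisection to 1e−3 kg.  The statistic is
  monotone near every crossing encountered here.  Stable-everywhere /
  unstable-everywhere brackets return sentinels rather than errors.

The method-of-steps oracle for the delayed IC map integrates the hybrid
dynamics over one period with fixed-step RK4 (default step 1e−5 s), matrix
column-wise: backward over the delay tail of the previous interval, forward
through the predictor ODE, forward over the new interval.  Agreement with
the Sylvester construction is ≤ 1e−6 on the analyzed parameter sets.

## Simulation (`simulate`)

A fixed-step loop (default `dt = 10⁻³ s`) advances plant, observer (on the
delayed time base, driven by `u(t−τ)` from a ring buffer), predictor, and —
for IC — the hold state.  Per-step ordering at a trigger: measurement,
prediction from the estimate available at the trigger, hold reset, control
output.  The first trigger is at `t = 0`.

Two backends:

- `zoh` (default): exact ZOH propagation of every linear block.  Noise-free
  delayed-CC runs then realize the `A_ex` map exactly, and noise-free
  accurate-model IC equals CC to machine precision (the hold is exact by
  construction), which is what the 1e−6 agreement tests exercise.
- `euler`: explicit Euler / Euler–Maruyama.  Used to confirm backend
  insensitivity; noisy runs scale the process draw by `√dt` and the
  measurement draw by `1/√dt` (per-sample variance of a white-noise
  intensity).

A divergence guard truncates runs whose state norm exceeds 10³ and flags
them unstable; `is_divergent` additionally classifies marginally unstable
runs by comparing late- vs. mid-run peak state norms (slowly contracting
loops, e.g. spectral radius 0.93 per 0.2 s period, need several seconds to
shrink below their reach transient).

## Metrics (`metrics`)

Onset = first grid time with velocity > 0.05 m/s; early velocity = velocity
0.15 s after onset; first correction = after the velocity peak, the earlier
of velocity < 0.01 m/s or a strict local minimum of the 5-sample
edge-padded moving average (zero padding would fabricate extrema at the
record ends); dysmetria = position at first correction minus target,
positive = overshoot.  Mismatch sweeps run nine plants evenly spaced around
the internal model (endpoints included, accurate model at the center):
masses within ±25 % of `m_IM`, damping within ±2 N s/m, all noise-free with
`τ = 0.15 s`, `h = 0.2 s`, time-varying feedback gains and stationary
observer gain, 2 s of simulated time.  Dysmetria is regressed on early
velocity with ordinary least squares (`scipy.stats.linregress`); the regression
result of interest is the slope sign: negative for mass sweeps, positive for
damping sweeps, under both controllers and both cost variants.

Noise-free sweeps are the default (the analyzed single-trial curves are
smooth and no averaging is specified); noisy sweeps with per-value seeds are
available via `noise=True, seed=...` and are bitwise reproducible.

## What the tests do and do not show

The simulations share the linear plant family with the stability theory, so
verdict agreement between simulation and spectra is a consistency check of
two independent code paths, not evidence about real limbs.  Real reaching
involves signal-dependent noise, nonlinear/rotational dynamics, and
event-driven triggering, all outside scope here.  Because IC ≡ CC exactly
for accurate models in the noise-free pipeline, any accurate-model
difference between the two controllers (e.g. which first-correction
criterion fires) can only appear with noise on; deterministic sweeps
evaluate both controllers at identical trajectories for the accurate plant.

## Known limitations

- The noise-intensity convention above is inferred: the source text never
  states `W` numerically, and the printed per-sample noise magnitudes
  underdetermine the continuous intensities.  The chosen reading reproduces
  23 of 24 entries of the reference threshold table within ±0.05 kg; the
  remaining entry (`m_IM = 6 kg, γ_IM = 6 N s/m`, delayed CC at
  `τ = 0.15 s`) computes to 1.745 kg against a printed 1.8, a 0.055 kg gap
  that is robust to every discretization convention tried and presumably
  reflects the reference's unstated scan grid.
- Stability theory covers time-invariant gains only; time-varying-gain
  behavior is assessed by simulation.
- Sylvester-based constructions fail (by design, with an explicit error) on
  parameter sets where `A_o` and `A_F` share an eigenvalue; the oracles
  remain available there.
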