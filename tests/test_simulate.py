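import numpy as np
import pytest

from icreach import lqg, simulate as sim
from icreach.plant import PlantParams, Q_INF_NOMINAL, R_INF, build_plant
from icreach.simulate import SimConfig, is_divergent, predict_state, simulate_cc, simulate_ic
from icreach.stability import zoh_discretize


class TestPredictState:
    def test_zero_delay_is_identity(self, internal_model):
        x = np.array([0.1, -0.2, 0.3, 0.4])
        out = predict_state(x, np.array([]), internal_model.A, internal_model.B, 0.0, 1e-3)
        assert np.allclose(out, x)

    def test_zero_control_is_homogeneous_flow(self, internal_model):
        from scipy.linalg import expm

        x = np.array([0.1, -0.2, 0.3, 0.4])
        tau, dt = 0.05, 1e-3
        out = predict_state(x, np.zeros(50), internal_model.A, internal_model.B, tau, dt)
        assert np.allclose(out, expm(internal_model.A * tau) @ x, atol=1e-9)

    def test_constant_control_matches_closed_form(self, internal_model):
        """Constant held control over the delay equals one big ZOH step."""
        x = np.array([0.0, 0.1, 0.0, -0.1])
        tau, dt, u = 0.1, 1e-3, 0.7
        out = predict_state(
            x, np.full(100, u), internal_model.A, internal_model.B, tau, dt
        )
        A_tau, B_tau = zoh_discretize(internal_model.A, internal_model.B, tau)
        assert np.allclose(out, A_tau @ x + B_tau[:, 0] * u, atol=1e-9)


class TestClosedLoopSimulation:
    def test_target_is_equilibrium(self, internal_model, nominal_gains):
        cfg = SimConfig(duration=0.5, tau=0.0, h=0.1, x0=np.zeros(4))
        traj = simulate_cc(internal_model, internal_model, nominal_gains, cfg)
        assert np.abs(traj.x).max() < 1e-12

    def test_accurate_model_reaches_target(self, internal_model, nominal_gains):
        cfg = SimConfig(duration=1.2, tau=0.15, h=0.2)
        traj = simulate_cc(internal_model, internal_model, nominal_gains, cfg)
        assert not traj.unstable
        assert traj.position[-1] == pytest.approx(traj.target, rel=0.05)

    def test_smh_exactness_accurate_model(self, internal_model, nominal_gains):
        """Noise-free, accurate model: the hold replicates the predictor, so
        IC and CC trajectories coincide to numerical precision."""
        cfg = SimConfig(duration=1.5, tau=0.15, h=0.2)
        tcc = simulate_cc(internal_model, internal_model, nominal_gains, cfg)
        tic = simulate_ic(internal_model, internal_model, nominal_gains, cfg)
        assert np.abs(tcc.position - tic.position).max() < 1e-6

    def test_hold_state_continuous_between_triggers(self, internal_model, nominal_gains):
        """x_h jumps only at triggers and follows the internal-model closed
        loop in between (one-step propagation residual is zero)."""
        plant = build_plant(PlantParams(m=2.5, gamma=8.0))
        cfg = SimConfig(duration=0.8, tau=0.0, h=0.2)
        traj = simulate_ic(plant, internal_model, nominal_gains, cfg)
        A_d, B_d = zoh_discretize(internal_model.A, internal_model.B, cfg.dt)
        K = nominal_gains.K[0][0]
        trig = set(traj.trigger_idx.tolist())
        for k in range(len(traj.t) - 1):
            if (k + 1) in trig:
                continue
            xh_next = A_d @ traj.x_h[k] + B_d[:, 0] * (-float(K @ traj.x_h[k]))
            assert np.allclose(traj.x_h[k + 1], xh_next, atol=1e-12)

    def test_backend_consistency(self, internal_model, nominal_gains):
        """Euler and exact-ZOH stepping agree to O(dt) on a stable reach."""
        plant = build_plant(PlantParams(m=2.5, gamma=8.0))
        out = {}
        for backend in ("zoh", "euler"):
            cfg = SimConfig(duration=1.0, tau=0.0, h=0.2, backend=backend)
            out[backend] = simulate_ic(plant, internal_model, nominal_gains, cfg)
        assert np.abs(out["zoh"].position - out["euler"].position).max() < 5e-3

    def test_dt_refinement_converges(self, internal_model, nominal_gains):
        plant = build_plant(PlantParams(m=2.5, gamma=8.0))
        pos = {}
        for dt in (1e-3, 5e-4):
            cfg = SimConfig(duration=1.0, dt=dt, tau=0.15, h=0.2)
            traj = simulate_ic(plant, internal_model, nominal_gains, cfg)
            pos[dt] = traj.position[:: int(round(1e-3 / dt))]
        assert np.abs(pos[1e-3] - pos[5e-4]).max() < 1e-3

    def test_noise_reproducible_by_seed(self, internal_model, nominal_gains):
        cfg = SimConfig(duration=0.5, tau=0.0, h=0.1, noise=True, seed=42)
        a = simulate_ic(internal_model, internal_model, nominal_gains, cfg)
        b = simulate_ic(internal_model, internal_model, nominal_gains, cfg)
        assert np.array_equal(a.x, b.x)
        c = simulate_ic(
            internal_model, internal_model, nominal_gains,
            SimConfig(duration=0.5, tau=0.0, h=0.1, noise=True, seed=43),
        )
        assert not np.array_equal(a.x, c.x)

    def test_divergence_guard_truncates(self, quiet_internal_model, quiet_gains):
        plant = build_plant(PlantParams(m=0.25, gamma=8.0), noise_scale=0.1)
        cfg = SimConfig(duration=8.0, tau=0.0, h=0.1)
        traj = simulate_ic(plant, quiet_internal_model, quiet_gains, cfg)
        assert traj.unstable
        assert len(traj.t) < cfg.steps()

    def test_ic_requires_delay_shorter_than_period(self, internal_model, nominal_gains):
        with pytest.raises(ValueError):
            simulate_ic(
                internal_model, internal_model, nominal_gains,
                SimConfig(duration=0.5, tau=0.2, h=0.1),
            )


class TestVerdictAgreement:
    """Noise-free simulated stability verdicts must match the spectral ones."""

    CASES = [
        # (mode, m_pl, h, tau, noise_scale, divergent)
        ("ic", 0.4, 0.1, 0.0, 1.0, True),
        ("ic", 0.4, 0.2, 0.0, 1.0, False),
        ("ic", 0.4, 0.1, 0.0, 0.1, True),
        ("ic", 0.4, 0.2, 0.0, 0.1, False),
        ("cc", 0.4, 0.2, 0.0, 1.0, False),
        ("cc", 0.4, 0.2, 0.0, 0.1, True),
        ("ic", 0.4, 0.2, 0.1, 1.0, True),
        ("ic", 0.4, 0.2, 0.15, 1.0, False),
        ("cc", 0.4, 0.2, 0.1, 1.0, True),
        ("cc", 0.4, 0.2, 0.15, 1.0, True),
    ]

    @pytest.mark.parametrize("mode,m_pl,h,tau,noise_scale,expected", CASES)
    def test_simulation_matches_spectrum(self, mode, m_pl, h, tau, noise_scale, expected):
        internal = build_plant(PlantParams(m=2.0, gamma=8.0), noise_scale=noise_scale)
        gains = lqg.design_lti_gains(internal, Q_INF_NOMINAL, R_INF)
        plant = build_plant(PlantParams(m=m_pl, gamma=8.0), noise_scale=noise_scale)
        cfg = SimConfig(duration=6.0, tau=tau, h=h)
        run = simulate_ic if mode == "ic" else simulate_cc
        traj = run(plant, internal, gains, cfg)
        assert is_divergent(traj) == expected
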