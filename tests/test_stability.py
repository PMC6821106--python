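import numpy as np
import pytest
from scipy.linalg import expm

from icreach import stability as st
from icreach.plant import PlantParams, build_plant
from icreach.stability import (
    SingularSylvesterError,
    cc_closedloop_delayfree,
    cc_discrete_delayed,
    eigenvalue_growth,
    ic_monodromy_delayed,
    ic_monodromy_delayed_oracle,
    ic_monodromy_delayfree,
    ic_monodromy_delayfree_oracle,
    spectral_radius,
    stability_threshold,
    sylvester_solve,
    zoh_discretize,
)

from conftest import random_stable_system


def _model_from(A, B, C):
    from icreach.plant import LinearModel

    n, q = A.shape[0], C.shape[0]
    return LinearModel(A=A, B=B, C=C, W=np.eye(n), V=np.eye(q))


class TestSylvester:
    def test_homogeneous_gives_zero(self):
        g = np.diag([1.0, 2.0])
        b = np.diag([3.0, 4.0])
        assert np.allclose(sylvester_solve(g, b, np.zeros((2, 2))), 0)

    def test_scalar_instance(self):
        # 2S + 3S - 10 = 0 -> S = 2
        S = sylvester_solve(np.array([[2.0]]), np.array([[3.0]]), np.array([[-10.0]]))
        assert S[0, 0] == pytest.approx(2.0)

    def test_matches_kronecker_vectorization(self):
        rng = np.random.default_rng(7)
        g = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        a = rng.normal(size=(3, 3))
        S = sylvester_solve(g, b, a)
        Kmat = np.kron(np.eye(3), g) + np.kron(b.T, np.eye(3))
        S_vec = np.linalg.solve(Kmat, -a.T.ravel()).reshape(3, 3, order="F")
        assert np.allclose(S, S_vec, atol=1e-10)

    def test_overlapping_spectra_raise(self):
        g = np.eye(2)
        b = -np.eye(2)  # gamma and -beta share eigenvalue 1
        with pytest.raises((SingularSylvesterError, np.linalg.LinAlgError, ValueError)):
            sylvester_solve(g, b, np.ones((2, 2)))


class TestDelayFreeMonodromy:
    def test_zero_gain_reduces_to_open_loop_flow(self, internal_model):
        plant = build_plant(PlantParams(m=1.0, gamma=8.0))
        K = np.zeros((1, 4))
        L = np.ones((4, 2)) * 0.1
        A_o, _ = st.stacked_open_loop(plant, internal_model, L)
        A_p = ic_monodromy_delayfree(plant, internal_model, K, L, 0.1)
        assert np.allclose(A_p, expm(A_o * 0.1), atol=1e-10)

    def test_matches_oracle_on_hand_model_parameters(self, internal_model, nominal_gains):
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        for m_pl in (0.3, 0.4, 2.0, 4.0):
            for h in (0.05, 0.1, 0.2):
                plant = build_plant(PlantParams(m=m_pl, gamma=8.0))
                A_p = ic_monodromy_delayfree(plant, internal_model, K, L, h)
                A_p_o = ic_monodromy_delayfree_oracle(plant, internal_model, K, L, h)
                assert np.abs(A_p - A_p_o).max() < 1e-8

    def test_matches_oracle_on_random_systems(self):
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 20:
            A_bar, A, B, C, K, L = random_stable_system(rng)
            plant = _model_from(A_bar, B, C)
            internal = _model_from(A, B, C)
            h = float(rng.uniform(0.05, 0.5))
            try:
                A_p = ic_monodromy_delayfree(plant, internal, K, L, h)
            except SingularSylvesterError:
                continue
            A_p_o = ic_monodromy_delayfree_oracle(plant, internal, K, L, h)
            scale = max(1.0, np.abs(A_p_o).max())
            assert np.abs(A_p - A_p_o).max() < 1e-8 * scale
            checked += 1

    def test_short_period_limit_is_identity(self, internal_model, nominal_gains):
        """As h -> 0 the trigger map approaches the identity; the leading
        deviation is O(h * ||B_o K||), which the gain magnitudes put near
        8e-3 at h = 1e-6."""
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        A_p6 = ic_monodromy_delayfree_oracle(internal_model, internal_model, K, L, 1e-6)
        A_p7 = ic_monodromy_delayfree_oracle(internal_model, internal_model, K, L, 1e-7)
        assert np.abs(A_p6 - np.eye(8)).max() < 0.05
        # linear vanishing of the deviation
        assert np.abs(A_p7 - np.eye(8)).max() < 0.2 * np.abs(A_p6 - np.eye(8)).max()

    def test_heavier_than_expected_mass_is_stable(self, internal_model, nominal_gains):
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        plant = build_plant(PlantParams(m=4.0, gamma=8.0))
        A_p = ic_monodromy_delayfree(plant, internal_model, K, L, 0.1)
        assert spectral_radius(A_p) < 1


class TestDelayedMonodromy:
    def test_matches_method_of_steps_oracle(self, internal_model, nominal_gains):
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        for m_pl in (0.4, 2.0):
            plant = build_plant(PlantParams(m=m_pl, gamma=8.0))
            A_tot = ic_monodromy_delayed(plant, internal_model, K, L, 0.2, 0.1)
            A_tot_o = ic_monodromy_delayed_oracle(
                plant, internal_model, K, L, 0.2, 0.1, step=1e-5
            )
            assert np.abs(A_tot - A_tot_o).max() < 1e-6

    def test_vanishing_delay_recovers_delayfree_map(self, internal_model, nominal_gains):
        """The x_ov block of the delayed map converges linearly to the
        delay-free map as tau -> 0 (Lipschitz constant ~1e3 from the gain
        magnitudes, so the deviation at tau = 1e-6 is ~1e-3)."""
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        plant = build_plant(PlantParams(m=1.0, gamma=8.0))
        A_p = ic_monodromy_delayfree(plant, internal_model, K, L, 0.1)

        def dev(tau):
            A_tot = ic_monodromy_delayed(plant, internal_model, K, L, 0.1, tau)
            return np.abs(A_tot[:8, :8] - A_p).max()

        d6, d5 = dev(1e-6), dev(1e-5)
        assert d6 < 5e-3
        assert d6 < 0.2 * d5  # linear in tau

    def test_delay_bounds_enforced(self, internal_model, nominal_gains):
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        with pytest.raises(ValueError):
            ic_monodromy_delayed(internal_model, internal_model, K, L, 0.1, 0.15)

    def test_long_delay_stabilizes_whole_bracket(self, internal_model, nominal_gains):
        """At h=0.2 a longer delay (0.15 s) keeps IC stable for all scanned masses."""
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        for m_pl in np.linspace(0.2, 4.0, 20):
            plant = build_plant(PlantParams(m=m_pl, gamma=8.0))
            A_tot = ic_monodromy_delayed(plant, internal_model, K, L, 0.2, 0.15)
            assert spectral_radius(A_tot) < 1


class TestContinuousControl:
    def test_nominal_noise_stable_over_bracket(self, internal_model, nominal_gains):
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        for m_pl in np.arange(0.2, 4.01, 0.1):
            plant = build_plant(PlantParams(m=m_pl, gamma=8.0))
            A_ov = cc_closedloop_delayfree(plant, internal_model, K, L)
            assert np.max(np.linalg.eigvals(A_ov).real) < 0

    def test_quiet_noise_light_mass_unstable(self, quiet_internal_model, quiet_gains):
        K, L = quiet_gains.K[0], quiet_gains.L[0]
        plant = build_plant(PlantParams(m=0.4, gamma=8.0), noise_scale=0.1)
        A_ov = cc_closedloop_delayfree(plant, quiet_internal_model, K, L)
        assert np.max(np.linalg.eigvals(A_ov).real) > 0


class TestDiscreteDelayedCC:
    def test_zero_gain_block_spectrum(self, internal_model):
        """With K = L = 0 and one delay block the spectrum decouples."""
        plant = build_plant(PlantParams(m=1.0, gamma=8.0))
        K = np.zeros((1, 4))
        L = np.zeros((4, 2))
        M = cc_discrete_delayed(plant, internal_model, K, L, tau=1e-3, delta=1e-3)
        assert M.shape == (12, 12)
        Abar_d, _ = zoh_discretize(plant.A, plant.B, 1e-3)
        A_d, _ = zoh_discretize(internal_model.A, internal_model.B, 1e-3)
        expected = np.concatenate(
            [np.linalg.eigvals(Abar_d), np.linalg.eigvals(A_d), np.zeros(4)]
        )
        got = np.linalg.eigvals(M)
        assert np.allclose(np.sort(np.abs(got)), np.sort(np.abs(expected)), atol=1e-10)

    def test_dimension_grows_with_delay(self, internal_model, nominal_gains):
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        M = cc_discrete_delayed(internal_model, internal_model, K, L, 0.01, 1e-3)
        assert M.shape == (8 + 4 * 10, 8 + 4 * 10)

    def test_non_integer_ratio_rejected(self, internal_model, nominal_gains):
        K, L = nominal_gains.K[0], nominal_gains.L[0]
        with pytest.raises(ValueError):
            cc_discrete_delayed(internal_model, internal_model, K, L, 0.0015, 1e-3)

    def test_crossing_bracket_at_short_delay(self, internal_model, nominal_gains):
        """At tau=0.15 the spectral radius crosses 1 between 0.46 and 0.50 kg."""
        K, L = nominal_gains.K[0], nominal_gains.L[0]

        def rho(m):
            plant = build_plant(PlantParams(m=m, gamma=8.0))
            return spectral_radius(
                cc_discrete_delayed(plant, internal_model, K, L, 0.15, 1e-3)
            )

        assert rho(0.46) > 1 > rho(0.50)

    def test_eigenvalue_growth_helper(self):
        assert eigenvalue_growth(1.001, 0.2, 1e-3) == pytest.approx(1.22, abs=0.005)


class TestThresholdSearch:
    def test_monotone_statistic_bisection(self):
        res = stability_threshold(lambda m: 1.0 / m, limit=1.0, bracket=(0.2, 4.0))
        assert res.status == "crossing"
        assert res.value == pytest.approx(1.0, abs=2e-3)

    def test_stable_everywhere_sentinel(self):
        res = stability_threshold(lambda m: 0.5, limit=1.0)
        assert res.status == "stable"
        assert str(res) == "< 0.2"

    def test_unstable_everywhere_sentinel(self):
        res = stability_threshold(lambda m: 2.0, limit=1.0)
        assert res.status == "unstable"
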