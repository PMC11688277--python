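import numpy as np
import pytest

from eldersim.allocation import LogisticAllocationParams, logistic_allocation
from eldersim.dynamics import (
    ClosedLoopSpec,
    DriverSignals,
    EnvResourceParams,
    HealthState,
    LinearDriverParams,
    LinearModel,
    calibrate_linear,
    find_equilibrium,
    health_derivative_env,
    health_derivative_linear,
    simulate_trajectory,
)
from eldersim.economics import SocialCostParams
from eldersim.exceptions import (
    ConfigurationError,
    DomainError,
    IdentifiabilityError,
    SimulationError,
)


class TestLinearDerivative:
    def test_exact_cancellation(self):
        d = DriverSignals(S=1.0, P=1.0, E_env=1.0, C_exo=3.0)
        p = LinearDriverParams(1.0, 1.0, 1.0, 1.0)
        assert health_derivative_linear(0.0, 0.0, d, p) == 0.0

    def test_zero_drivers(self):
        d = DriverSignals(S=0.0, P=0.0, E_env=0.0, C_exo=0.0)
        p = LinearDriverParams(1.0, 2.0, 3.0, 4.0)
        assert health_derivative_linear(5.0, 1.0, d, p) == 0.0

    def test_hand_oracle(self):
        # 0.5*2 + 0.3*1 + 0.2*1 - 0.1*5 = 1.0
        d = DriverSignals(S=2.0, P=1.0, E_env=1.0, C_exo=5.0)
        p = LinearDriverParams(0.5, 0.3, 0.2, 0.1)
        assert health_derivative_linear(0.0, 0.0, d, p) == pytest.approx(1.0, abs=1e-15)

    def test_independent_of_H(self):
        d = DriverSignals(S=1.0, P=0.5, E_env=0.2, C_exo=1.0)
        p = LinearDriverParams(0.5, 0.3, 0.2, 0.1)
        vals = {health_derivative_linear(H, 0.0, d, p) for H in (-10.0, 0.0, 3.0, 1e6)}
        assert len(vals) == 1

    def test_missing_cost_signal_named(self):
        d = DriverSignals(S=1.0, P=1.0, E_env=1.0)
        p = LinearDriverParams(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ConfigurationError, match="C_exo"):
            health_derivative_linear(0.0, 0.0, d, p)

    def test_linearity_in_gains(self):
        d = DriverSignals(S=1.3, P=-0.4, E_env=0.7, C_exo=2.1)
        p1 = LinearDriverParams(0.5, 0.3, 0.2, 0.1)
        p2 = LinearDriverParams(1.0, 0.6, 0.4, 0.2)
        for t in (0.0, 1.5, 7.0):
            v1 = health_derivative_linear(0.0, t, d, p1)
            v2 = health_derivative_linear(0.0, t, d, p2)
            assert v2 == pytest.approx(2.0 * v1, rel=1e-14)


class TestEnvDerivative:
    def test_hand_oracle(self):
        # 1*2/(1+1*1) - 0.5*2 = 0
        d = DriverSignals(E_env=1.0)
        p = EnvResourceParams(alpha_r=1.0, kappa=1.0, beta=0.5)
        assert health_derivative_env(0.0, 0.0, 2.0, d, p, C=2.0) == pytest.approx(0.0, abs=1e-15)

    def test_kappa_zero_reduction(self):
        p = EnvResourceParams(alpha_r=1.3, kappa=0.0, beta=0.4)
        for E in (-5.0, 0.0, 100.0):
            d = DriverSignals(E_env=E)
            got = health_derivative_env(0.0, 0.0, 2.0, d, p, C=3.0)
            assert got == pytest.approx(1.3 * 2.0 - 0.4 * 3.0, rel=1e-14)

    def test_large_E_asymptote(self):
        p = EnvResourceParams(alpha_r=1.0, kappa=1.0, beta=0.5)
        prev = np.inf
        for E in (1e2, 1e4, 1e6):
            got = health_derivative_env(0.0, 0.0, 2.0, DriverSignals(E_env=E), p, C=2.0)
            assert got > -0.5 * 2.0
            assert got < prev
            prev = got
        assert prev == pytest.approx(-1.0, abs=1e-4)

    def test_nonpositive_denominator_reports_t_and_E(self):
        p = EnvResourceParams(alpha_r=1.0, kappa=2.0, beta=0.5)
        with pytest.raises(DomainError, match="t=3.0"):
            health_derivative_env(0.0, 3.0, 1.0, DriverSignals(E_env=-1.0), p, C=0.0)

    def test_monotone_in_E(self):
        # derivative non-increasing in E when alpha_r*R_h > 0
        p = EnvResourceParams(alpha_r=1.0, kappa=0.8, beta=0.1)
        Es = np.linspace(0.0, 10.0, 50)
        vals = [
            health_derivative_env(0.0, 0.0, 2.0, DriverSignals(E_env=E), p, C=1.0) for E in Es
        ]
        assert np.all(np.diff(vals) <= 1e-15)


class TestSimulateTrajectory:
    def test_constant_drivers_closed_form(self):
        # net drive g = 1: alpha1*S - beta*C = 2 - 1
        d = DriverSignals(S=2.0, P=0.0, E_env=0.0, C_exo=1.0)
        model = LinearModel(LinearDriverParams(1.0, 0.0, 0.0, 1.0), d)
        t = np.arange(0.0, 5.0 + 1e-9, 0.1)
        traj = simulate_trajectory(0.0, model, t)
        assert traj.H[0] == 0.0
        assert abs(traj.H[-1] - 5.0) < 1e-6

    def test_zero_drivers_constant_trajectory(self):
        d = DriverSignals(S=0.0, P=0.0, E_env=0.0, C_exo=0.0)
        model = LinearModel(LinearDriverParams(1.0, 1.0, 1.0, 1.0), d)
        traj = simulate_trajectory(2.5, model, np.linspace(0, 10, 101))
        assert np.all(traj.H == 2.5)

    def test_closed_loop_matches_adaptive_reference(self):
        spec = ClosedLoopSpec(
            env_resource=EnvResourceParams(alpha_r=1.0, kappa=0.5, beta=0.3),
            allocation=LogisticAllocationParams(lam_total=5.0, gamma_sens=-1.0),
            cost=SocialCostParams(C0=2.0, delta_sc=0.3, eta=0.5),
            drivers=DriverSignals(
                S=lambda t: 1.0 + 0.5 * np.sin(t),
                E_env=lambda t: 0.5 + 0.3 * np.cos(0.7 * t),
                Rm=lambda t: 1.0,
            ),
        )
        t = np.linspace(0.0, 5.0, 501)
        rk4 = simulate_trajectory(0.2, spec, t, method="rk4")
        ref = simulate_trajectory(0.2, spec, t, method="rk45")
        assert np.max(np.abs(rk4.H - ref.H)) < 1e-5

    def test_divergence_reports_first_bad_time(self):
        d = DriverSignals(S=lambda t: np.inf if t > 0.5 else 1.0, P=0.0, E_env=0.0, C_exo=0.0)
        model = LinearModel(LinearDriverParams(1.0, 0.0, 0.0, 0.0), d)
        with pytest.raises(SimulationError, match="t="):
            simulate_trajectory(0.0, model, np.linspace(0, 2, 21))

    def test_grid_must_increase(self):
        d = DriverSignals(S=1.0, C_exo=1.0)
        model = LinearModel(LinearDriverParams(1.0, 0.0, 0.0, 0.0), d)
        with pytest.raises(ConfigurationError):
            simulate_trajectory(0.0, model, np.array([0.0, 1.0, 1.0]))


def _closed_loop(alpha_r=1.0, kappa=0.0, beta=1.0, lam=2.0, gamma=1.0, C0=1.0, E=0.0):
    # delta_sc=0 makes the behavior cost exactly C0
    return ClosedLoopSpec(
        env_resource=EnvResourceParams(alpha_r=alpha_r, kappa=kappa, beta=beta),
        allocation=LogisticAllocationParams(lam_total=lam, gamma_sens=gamma),
        cost=SocialCostParams(C0=C0, delta_sc=0.0, eta=0.0),
        drivers=DriverSignals(S=0.0, E_env=E, Sc=0.0, Rm=0.0),
    )


class TestEquilibrium:
    def test_logit_half_is_zero(self):
        # beta*C*(1+kappa*E)/(alpha_r*lam) = 1*1/(1*2) = 0.5 -> logit(0.5) = 0
        spec = _closed_loop(alpha_r=1.0, kappa=0.0, beta=1.0, lam=2.0, gamma=1.0, C0=1.0)
        assert find_equilibrium(spec) == pytest.approx(0.0, abs=1e-14)

    def test_none_when_cost_unreachable(self):
        # beta*C*(1+kappa*E) >= alpha_r*lam: sigmoid cannot reach 1
        spec = _closed_loop(beta=3.0, C0=1.0, lam=2.0)
        assert find_equilibrium(spec) is None

    def test_equilibrium_zeroes_derivative(self):
        spec = _closed_loop(alpha_r=1.2, kappa=0.7, beta=0.4, lam=3.0, gamma=-0.8, C0=1.5, E=0.6)
        H_star = find_equilibrium(spec)
        assert H_star is not None
        assert abs(spec.rhs(0.0, H_star)) < 1e-10

    def test_gamma_zero_rejected(self):
        spec = _closed_loop(gamma=0.0)
        with pytest.raises(DomainError, match="gamma"):
            find_equilibrium(spec)

    def test_negative_gamma_equilibrium_is_stable(self):
        spec = _closed_loop(alpha_r=1.0, kappa=0.2, beta=0.5, lam=4.0, gamma=-1.5, C0=1.2, E=0.5)
        H_star = find_equilibrium(spec)
        assert H_star is not None
        t = np.linspace(0.0, 60.0, 1201)
        for dH0 in (-0.5, 0.5):
            traj = simulate_trajectory(H_star + dH0, spec, t)
            assert abs(traj.H[-1] - H_star) < 1e-3

    def test_allocation_at_equilibrium_balances_cost(self):
        spec = _closed_loop(alpha_r=1.0, kappa=0.0, beta=0.5, lam=4.0, gamma=-1.0, C0=1.2)
        H_star = find_equilibrium(spec)
        R_h = logistic_allocation(H_star, spec.allocation)
        d = health_derivative_env(H_star, 0.0, R_h, spec.drivers, spec.env_resource, C=1.2)
        assert abs(d) < 1e-10


class TestCalibration:
    TRUE = LinearDriverParams(0.5, 0.3, 0.2, 0.1)

    def test_noiseless_recovery(self, sinusoidal_drivers):
        t = np.linspace(0.0, 10.0, 200)
        traj = simulate_trajectory(0.0, LinearModel(self.TRUE, sinusoidal_drivers), t)
        est, diag = calibrate_linear(traj, sinusoidal_drivers)
        for name in ("alpha1", "alpha2", "alpha3", "beta"):
            true, got = getattr(self.TRUE, name), getattr(est, name)
            assert abs(got - true) / abs(true) < 1e-2, name
        assert diag.rank == 4

    def test_constant_drivers_unidentifiable(self):
        d = DriverSignals(S=1.0, P=1.0, E_env=1.0, C_exo=1.0)
        t = np.linspace(0.0, 10.0, 100)
        traj = simulate_trajectory(0.0, LinearModel(self.TRUE, d), t)
        with pytest.raises(IdentifiabilityError):
            calibrate_linear(traj, d)

    def test_noisy_recovery_within_10pct(self, sinusoidal_drivers):
        t = np.linspace(0.0, 10.0, 500)
        traj = simulate_trajectory(0.0, LinearModel(self.TRUE, sinusoidal_drivers), t)
        rng = np.random.default_rng(42)
        noisy = HealthState(t=t, H=traj.H + rng.normal(0.0, 0.01, size=t.size))
        est, _ = calibrate_linear(noisy, sinusoidal_drivers)
        for name in ("alpha1", "alpha2", "alpha3", "beta"):
            true, got = getattr(self.TRUE, name), getattr(est, name)
            assert abs(got - true) / abs(true) < 0.10, name

    def test_diagnostics_report_condition_number(self, sinusoidal_drivers):
        t = np.linspace(0.0, 10.0, 200)
        traj = simulate_trajectory(0.0, LinearModel(self.TRUE, sinusoidal_drivers), t)
        _, diag = calibrate_linear(traj, sinusoidal_drivers)
        assert np.isfinite(diag.condition_number) and diag.condition_number >= 1.0
        assert diag.residual_rms < 1e-2
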