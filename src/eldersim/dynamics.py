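"""Health-state dynamics: two ODE variants, equilibrium analysis and calibration.

Two right-hand sides are exposed as selectable model variants:

* ``linear-driver`` — dH/dt = a1*S(t) + a2*P(t) + a3*E(t) - b*C(t).  The
  derivative is deliberately independent of H (no mean reversion); trajectories
  can drift without bound and this is preserved, not clamped.
* ``env-resource`` — dH/dt = a*R_h(t)/(1 + k*E(t)) - b*C(t), optionally run
  closed-loop, where R_h is the health-sensitive logistic allocation and C the
  social-capital behavior cost, both recomputed at every integrator evaluation.

H is a dimensionless standardized health index; a working range of roughly
[-3, 3] is recommended but not enforced.  The time unit is arbitrary
("days" by convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    ConfigurationError,
    DomainError,
    IdentifiabilityError,
    SimulationError,
)

__all__ = [
    "HealthState",
    "LinearDriverParams",
    "EnvResourceParams",
    "DriverSignals",
    "ClosedLoopSpec",
    "LinearModel",
    "EnvResourceModel",
    "health_derivative_linear",
    "health_derivative_env",
    "simulate_trajectory",
    "find_equilibrium",
    "calibrate_linear",
]

# A driver signal may be a constant, a callable of t, or a (t, values) table
# that is linearly interpolated between grid points (no extrapolation).
SignalLike = Union[float, int, Callable[[float], float], tuple]


def as_callable(signal: SignalLike, name: str = "signal") -> Callable[[float], float]:
    """Normalize a signal specification to a callable of time.

    Dense tables ``(t, values)`` are linearly interpolated; evaluation outside
    the tabulated range raises :class:`ConfigurationError`.
    """
    if signal is None:
        raise ConfigurationError(f"driver signal '{name}' is not configured")
    if callable(signal):
        return signal
    if isinstance(signal, (int, float, np.floating, np.integer)):
        value = float(signal)
        return lambda t: value
    t_tab = np.asarray(signal[0], dtype=float)
    v_tab = np.asarray(signal[1], dtype=float)
    if t_tab.ndim != 1 or t_tab.shape != v_tab.shape:
        raise ConfigurationError(f"signal '{name}' table must be two equal-length 1-D arrays")
    if np.any(np.diff(t_tab) <= 0):
        raise ConfigurationError(f"signal '{name}' time column must be strictly increasing")

    def interp(t: float) -> float:
        if t < t_tab[0] - 1e-12 or t > t_tab[-1] + 1e-12:
            raise ConfigurationError(
                f"signal '{name}' not evaluable at t={t}: tabulated on "
                f"[{t_tab[0]}, {t_tab[-1]}]"
            )
        return float(np.interp(t, t_tab, v_tab))

    return interp


@dataclass
class HealthState:
    """A simulated health trajectory: health index H on a strictly increasing grid."""

    t: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.H.shape:
            raise ConfigurationError("t and H must be equal-length 1-D arrays")
        if self.t.size < 2:
            raise ConfigurationError("a trajectory needs at least two grid points")
        if np.any(np.diff(self.t) <= 0):
            raise ConfigurationError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.H)):
            bad = self.t[~np.isfinite(self.H)][0]
            raise SimulationError(f"non-finite health index at t={bad}")


@dataclass(frozen=True)
class LinearDriverParams:
    """Gains of the linear-driver model: dH/dt = a1*S + a2*P + a3*E - beta*C."""

    alpha1: float
    alpha2: float
    alpha3: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "beta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"LinearDriverParams.{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class EnvResourceParams:
    """Gains of the environment-suppressed model: dH/dt = a*R_h/(1+k*E) - beta*C."""

    alpha_r: float
    kappa: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha_r", "kappa", "beta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"EnvResourceParams.{name} must be finite, got {v!r}")
        if self.kappa < 0:
            raise ConfigurationError(f"kappa must be >= 0, got {self.kappa}")


@dataclass
class DriverSignals:
    """Exogenous inputs of the health dynamics.

    S, P and E_env are social support, psychological state and environmental
    exposure.  C_exo / R_exo are exogenous behavior-cost and resource signals
    for the open-loop variants.  Sc / Rm are social-capital support and
    resource input for the closed-loop cost rule; they default to S and R_exo
    respectively when not given.
    """

    S: SignalLike = 0.0
    P: SignalLike = 0.0
    E_env: SignalLike = 0.0
    C_exo: Optional[SignalLike] = None
    R_exo: Optional[SignalLike] = None
    Sc: Optional[SignalLike] = None
    Rm: Optional[SignalLike] = None

    def get(self, name: str, required: bool = True) -> Callable[[float], float]:
        sig = getattr(self, name)
        if sig is None:
            if required:
                raise ConfigurationError(f"driver signal '{name}' is required but absent")
            return lambda t: 0.0
        return as_callable(sig, name)


def health_derivative_linear(
    H: float, t: float, drivers: DriverSignals, params: LinearDriverParams
) -> float:
    """Linear-driver derivative a1*S(t) + a2*P(t) + a3*E(t) - beta*C(t).

    Independent of ``H`` by construction; ``H`` is accepted only for ODE
    interface uniformity.  Requires an exogenous cost signal ``C_exo``.
    """
    if drivers.C_exo is None:
        raise ConfigurationError(
            "linear-driver model requires the exogenous cost signal 'C_exo'"
        )
    S = drivers.get("S")(t)
    P = drivers.get("P")(t)
    E = drivers.get("E_env")(t)
    C = drivers.get("C_exo")(t)
    return (
        params.alpha1 * S + params.alpha2 * P + params.alpha3 * E - params.beta * C
    )


def health_derivative_env(
    H: float,
    t: float,
    R_h: float,
    drivers: DriverSignals,
    params: EnvResourceParams,
    C: Optional[float] = None,
) -> float:
    """Environment-suppressed derivative a*R_h/(1+k*E(t)) - beta*C(t).

    ``C`` may be passed explicitly (closed-loop callers); otherwise the
    exogenous cost signal is used.
    """
    E = drivers.get("E_env")(t)
    denom = 1.0 + params.kappa * E
    if denom <= 0.0:
        raise DomainError(
            f"1 + kappa*E(t) must be positive; got {denom} at t={t} (E={E})"
        )
    if C is None:
        C = drivers.get("C_exo")(t)
    return params.alpha_r * R_h / denom - params.beta * C


@dataclass
class LinearModel:
    """Open-loop linear-driver variant."""

    params: LinearDriverParams
    drivers: DriverSignals

    variant = "linear-driver"

    def rhs(self, t: float, H: float) -> float:
        return health_derivative_linear(H, t, self.drivers, self.params)


@dataclass
class EnvResourceModel:
    """Open-loop environment-suppressed variant with exogenous R and C signals."""

    params: EnvResourceParams
    drivers: DriverSignals

    variant = "env-resource"

    def rhs(self, t: float, H: float) -> float:
        if self.drivers.R_exo is None:
            raise ConfigurationError(
                "open-loop env-resource model requires the resource signal 'R_exo'"
            )
        R_h = self.drivers.get("R_exo")(t)
        return health_derivative_env(H, t, R_h, self.drivers, self.params)


@dataclass
class ClosedLoopSpec:
    """Closed-loop env-resource variant.

    R_h is recomputed from the logistic allocation rule and C from the
    social-capital cost model at every integrator evaluation.  Sc defaults to
    the social-support signal S; Rm defaults to R_exo (0 if absent).
    """

    env_resource: EnvResourceParams
    allocation: "LogisticAllocationParams"  # noqa: F821 - allocation module
    cost: "SocialCostParams"  # noqa: F821 - economics module
    drivers: DriverSignals = field(default_factory=DriverSignals)

    variant = "closed-loop"

    def _sc(self, t: float) -> float:
        sig = self.drivers.Sc if self.drivers.Sc is not None else self.drivers.S
        return as_callable(sig, "Sc")(t)

    def _rm(self, t: float) -> float:
        if self.drivers.Rm is not None:
            return as_callable(self.drivers.Rm, "Rm")(t)
        if self.drivers.R_exo is not None:
            return as_callable(self.drivers.R_exo, "R_exo")(t)
        return 0.0

    def cost_at(self, t: float) -> float:
        from .economics import behavior_cost

        return behavior_cost(self._sc(t), self._rm(t), self.cost)

    def rhs(self, t: float, H: float) -> float:
        from .allocation import logistic_allocation

        R_h = logistic_allocation(H, self.allocation)
        return health_derivative_env(
            H, t, R_h, self.drivers, self.env_resource, C=self.cost_at(t)
        )


ModelSpec = Union[LinearModel, EnvResourceModel, ClosedLoopSpec]


def _rk4(rhs: Callable[[float, float], float], H0: float, t_grid: np.ndarray) -> np.ndarray:
    H = np.empty_like(t_grid)
    H[0] = H0
    for i in range(t_grid.size - 1):
        t, h = t_grid[i], t_grid[i + 1] - t_grid[i]
        y = H[i]
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2.0, y + h * k1 / 2.0)
        k3 = rhs(t + h / 2.0, y + h * k2 / 2.0)
        k4 = rhs(t + h, y + h * k3)
        H[i + 1] = y + h * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        if not np.isfinite(H[i + 1]):
            raise SimulationError(
                f"integration diverged: non-finite health index at t={t_grid[i + 1]}"
            )
    return H


def simulate_trajectory(
    H0: float,
    spec: ModelSpec,
    t_grid: np.ndarray,
    method: str = "rk4",
) -> HealthState:
    """Integrate a model variant on ``t_grid`` starting from ``H0``.

    ``method`` is ``"rk4"`` (fixed-step, one step per grid interval; the
    reproducible default) or ``"rk45"`` (adaptive SciPy reference integrator
    with tight tolerances, used as an accuracy oracle).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ConfigurationError("t_grid must be a strictly increasing 1-D array")
    if method == "rk4":
        H = _rk4(spec.rhs, float(H0), t_grid)
    elif method == "rk45":
        sol = solve_ivp(
            lambda t, y: spec.rhs(t, y[0]),
            (t_grid[0], t_grid[-1]),
            [float(H0)],
            t_eval=t_grid,
            method="RK45",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise SimulationError(f"adaptive integration failed: {sol.message}")
        H = sol.y[0]
        if not np.all(np.isfinite(H)):
            bad = t_grid[~np.isfinite(H)][0]
            raise SimulationError(f"integration diverged: non-finite health index at t={bad}")
    else:
        raise ConfigurationError(f"unknown integrator '{method}' (use 'rk4' or 'rk45')")
    return HealthState(t=t_grid, H=H)


def find_equilibrium(spec: ClosedLoopSpec, t_ref: float = 0.0) -> Optional[float]:
    """Equilibrium health index of the closed-loop model with constant drivers.

    Setting dH/dt = 0 with the logistic allocation rule gives
    ``H* = logit(beta*C*(1+kappa*E) / (alpha_r*lam_total)) / gamma``.
    Returns ``None`` when the logit argument falls outside (0, 1), i.e. the
    sigmoid cannot balance the cost term.  Drivers are evaluated at ``t_ref``
    and assumed constant (the caller's responsibility).
    """
    gamma = spec.allocation.gamma_sens
    if gamma == 0.0:
        raise DomainError("gamma_sens = 0: allocation is insensitive to H, no unique equilibrium")
    E = spec.drivers.get("E_env")(t_ref)
    C = spec.cost_at(t_ref)
    denom = spec.env_resource.alpha_r * spec.allocation.lam_total
    if denom == 0.0:
        raise DomainError("alpha_r * lam_total = 0: no resource pathway, no equilibrium")
    p = spec.env_resource.beta * C * (1.0 + spec.env_resource.kappa * E) / denom
    if not 0.0 < p < 1.0:
        return None
    return math.log(p / (1.0 - p)) / gamma


@dataclass
class CalibrationDiagnostics:
    residual_rms: float
    condition_number: float
    rank: int
    n_points: int


def calibrate_linear(
    trajectory: HealthState,
    drivers: DriverSignals,
    rank_tol: Optional[float] = None,
) -> tuple[LinearDriverParams, CalibrationDiagnostics]:
    """Recover linear-driver gains from an observed trajectory by least squares.

    dH/dt is estimated by finite differences (central on interior points,
    one-sided at the ends) and regressed on [S, P, E, -C] evaluated on the
    grid.  Rank-deficient regressors raise :class:`IdentifiabilityError`
    rather than returning arbitrary parameters.  No smoothing is applied;
    noisy trajectories should be pre-smoothed by the caller if needed.
    """
    t, H = trajectory.t, trajectory.H
    if drivers.C_exo is None:
        raise ConfigurationError("calibration requires the exogenous cost signal 'C_exo'")
    dHdt = np.gradient(H, t)
    cols = []
    for name, sign in (("S", 1.0), ("P", 1.0), ("E_env", 1.0), ("C_exo", -1.0)):
        f = drivers.get(name)
        cols.append(sign * np.array([f(ti) for ti in t]))
    X = np.column_stack(cols)
    rank = int(np.linalg.matrix_rank(X, tol=rank_tol))
    if rank < 4:
        raise IdentifiabilityError(
            f"regressor matrix [S, P, E, -C] has rank {rank} < 4; "
            "parameters are not identifiable from these drivers"
        )
    coef, _, _, sv = np.linalg.lstsq(X, dHdt, rcond=None)
    resid = dHdt - X @ coef
    diag = CalibrationDiagnostics(
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        condition_number=float(sv[0] / sv[-1]),
        rank=rank,
        n_points=int(t.size),
    )
    params = LinearDriverParams(
        alpha1=float(coef[0]), alpha2=float(coef[1]), alpha3=float(coef[2]), beta=float(coef[3])
    )
    return params, diag
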