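"""Resource allocation: saturating utility, logistic feedback rule, budget optimizer.

The utility of allocating ``R`` resources to individual ``i`` is
``U(R) = a * R**theta / (1 + b * R**delta_u)``, which exhibits diminishing
marginal returns for suitable exponents (verified numerically, not assumed).

Budget-constrained maximization of the summed utility is solved, in the
concave case, by bisection on the shared Lagrange multiplier with
per-individual inversion of the marginal utility; non-concave problems fall
back to a flagged multi-start local search with no global-optimality claim.

The logistic feedback rule ``R_h = lam * sigmoid(gamma * H)`` allocates more
resources at *higher* H when gamma > 0, exactly as the formula reads.  The
narrative behavior — more resources when health is poor — corresponds to
gamma < 0, which is the recommended configuration default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "UtilityParams",
    "LogisticAllocationParams",
    "BudgetProblem",
    "AllocationResult",
    "utility",
    "marginal_utility",
    "check_diminishing_returns",
    "logistic_allocation",
    "allocate_budget",
]


@dataclass(frozen=True)
class UtilityParams:
    """Parameters of the saturating utility a*R^theta / (1 + b*R^delta_u)."""

    a: float
    b: float
    theta: float
    delta_u: float

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("theta", self.theta), ("delta_u", self.delta_u)):
            if not math.isfinite(v):
                raise ConfigurationError(f"UtilityParams.{name} must be finite, got {v!r}")
        if self.a <= 0:
            raise ConfigurationError(f"a must be > 0, got {self.a}")
        if self.b < 0:
            raise ConfigurationError(f"b must be >= 0, got {self.b}")
        if self.theta <= 0:
            raise ConfigurationError(f"theta must be > 0, got {self.theta}")
        if self.delta_u <= 0:
            raise ConfigurationError(f"delta_u must be > 0, got {self.delta_u}")


@dataclass(frozen=True)
class LogisticAllocationParams:
    """Parameters of the health-sensitive logistic allocation rule."""

    lam_total: float
    gamma_sens: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lam_total) and self.lam_total > 0):
            raise ConfigurationError(f"lam_total must be > 0, got {self.lam_total}")
        if not math.isfinite(self.gamma_sens):
            raise ConfigurationError(f"gamma_sens must be finite, got {self.gamma_sens}")


@dataclass
class BudgetProblem:
    individuals: Sequence[UtilityParams]
    budget: float
    bounds: Optional[Sequence[float]] = None  # per-individual caps, None = budget

    def __post_init__(self) -> None:
        if len(self.individuals) == 0:
            raise ConfigurationError("BudgetProblem needs at least one individual")
        if not math.isfinite(self.budget) or self.budget < 0:
            raise ConfigurationError(f"budget must be >= 0, got {self.budget}")
        if self.bounds is not None and len(self.bounds) != len(self.individuals):
            raise ConfigurationError("bounds must match the number of individuals")

    def caps(self) -> np.ndarray:
        if self.bounds is None:
            return np.full(len(self.individuals), self.budget)
        return np.minimum(np.asarray(self.bounds, dtype=float), self.budget)


def utility(R, params: UtilityParams):
    """Utility a*R^theta / (1 + b*R^delta_u); U(0) = 0.  Accepts scalars or arrays."""
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr < 0):
        raise DomainError(f"resources must be >= 0, got {np.min(R_arr)}")
    val = params.a * R_arr**params.theta / (1.0 + params.b * R_arr**params.delta_u)
    return float(val) if np.isscalar(R) or R_arr.ndim == 0 else val


def marginal_utility(R: float, params: UtilityParams) -> float:
    """Analytic dU/dR = a*R^(theta-1) * [theta + b*R^delta*(theta-delta)] / (1+b*R^delta)^2."""
    if R < 0:
        raise DomainError(f"resources must be >= 0, got {R}")
    a, b, th, de = params.a, params.b, params.theta, params.delta_u
    if R == 0.0:
        if th > 1.0:
            return 0.0
        if th == 1.0:
            return a
        return math.inf
    brd = b * R**de
    return a * R ** (th - 1.0) * (th + brd * (th - de)) / (1.0 + brd) ** 2


def check_diminishing_returns(
    params: UtilityParams, R_max: float, n_grid: int = 201, tol: float = 1e-9
) -> tuple[bool, Optional[float]]:
    """Numerically check that marginal utility is non-increasing on (0, R_max].

    Uses central differences of U on a uniform grid.  Returns ``(ok, R_viol)``
    where ``R_viol`` is the first grid point at which the marginal utility
    increases (None when concavity holds).
    """
    if R_max <= 0:
        raise DomainError(f"R_max must be > 0, got {R_max}")
    if n_grid < 3:
        raise ConfigurationError(f"n_grid must be >= 3, got {n_grid}")
    R = np.linspace(0.0, R_max, n_grid)
    U = utility(R, params)
    mid = 0.5 * (R[:-1] + R[1:])
    marginal = np.diff(U) / np.diff(R)  # central difference of U at midpoints
    increases = np.diff(marginal) > tol * max(1.0, float(np.max(np.abs(marginal))))
    if np.any(increases):
        first = int(np.argmax(increases))
        return False, float(mid[first + 1])
    return True, None


def logistic_allocation(H, params: LogisticAllocationParams):
    """Health-sensitive allocation lam * sigmoid(gamma * H).

    Overflow-safe for arbitrarily large |gamma*H| (branches on the sign of the
    exponent).  Output lies strictly within (0, lam) for finite inputs.
    """
    x = params.gamma_sens * np.asarray(H, dtype=float)
    # stable sigmoid: exp of a non-positive argument on both branches
    pos = x >= 0
    sig = np.empty_like(x, dtype=float)
    sig[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    sig[~pos] = ex / (1.0 + ex)
    out = params.lam_total * sig
    return float(out) if np.isscalar(H) or out.ndim == 0 else out


@dataclass
class AllocationResult:
    R: np.ndarray
    utilities: np.ndarray
    total_utility: float
    multiplier: float
    kkt_residual: float
    concave: bool
    flags: list[str] = field(default_factory=list)


def _invert_marginal(params: UtilityParams, mu: float, cap: float) -> float:
    """Solve marginal_utility(R) = mu on [0, cap] for a concave utility.

    The marginal is non-increasing, so the solution is the cap when the
    marginal at the cap still exceeds mu, zero when even the marginal near
    zero is below mu, and a bracketed root otherwise.
    """
    if cap <= 0.0:
        return 0.0
    if marginal_utility(cap, params) >= mu:
        return cap
    lo = 1e-12 * max(cap, 1.0)
    if marginal_utility(lo, params) <= mu:
        return 0.0
    return float(optimize.brentq(lambda r: marginal_utility(r, params) - mu, lo, cap, xtol=1e-13))


def _concave_allocate(problem: BudgetProblem, tol: float) -> AllocationResult:
    inds = list(problem.individuals)
    caps = problem.caps()
    budget = problem.budget

    def spend(mu: float) -> np.ndarray:
        return np.array([_invert_marginal(p, mu, c) for p, c in zip(inds, caps)])

    R0 = spend(0.0)
    if R0.sum() <= budget * (1.0 + tol) + 1e-300:
        R, mu = R0, 0.0
    else:
        # bisection on the shared multiplier; total spend is non-increasing in mu
        mu_lo, mu_hi = 0.0, 1.0
        while spend(mu_hi).sum() > budget and mu_hi < 1e15:
            mu_hi *= 10.0
        for _ in range(200):
            mu = 0.5 * (mu_lo + mu_hi)
            total = spend(mu).sum()
            if total > budget:
                mu_lo = mu
            else:
                mu_hi = mu
            if mu_hi - mu_lo <= 1e-15 * max(1.0, mu_hi):
                break
        mu = mu_hi
        R = spend(mu)
        # linear/degenerate utilities make spend(mu) discontinuous at mu;
        # distribute any residual lexicographically among individuals whose
        # marginal at the current allocation is within tolerance of mu
        residual = budget - R.sum()
        if residual > tol * max(budget, 1.0):
            for i, (p, c) in enumerate(zip(inds, caps)):
                if residual <= 0:
                    break
                if abs(marginal_utility(min(R[i] + 1e-12, c), p) - mu) <= 1e-6 * max(mu, 1.0):
                    add = min(residual, c - R[i])
                    R[i] += add
                    residual -= add

    utilities = np.array([utility(r, p) for r, p in zip(R, inds)])
    interior = (R > 1e-9) & (R < caps - 1e-9)
    marg = np.array([marginal_utility(r, p) for r, p in zip(R, inds)])
    kkt = float(np.max(np.abs(marg[interior] - mu))) if interior.any() else 0.0
    return AllocationResult(
        R=R,
        utilities=utilities,
        total_utility=float(utilities.sum()),
        multiplier=float(mu),
        kkt_residual=kkt,
        concave=True,
    )


def _multistart_allocate(problem: BudgetProblem, n_starts: int = 20, seed: int = 0) -> AllocationResult:
    inds = list(problem.individuals)
    caps = problem.caps()
    n = len(inds)
    budget = problem.budget
    rng = np.random.default_rng(seed)

    def neg_total(R: np.ndarray) -> float:
        return -sum(utility(max(r, 0.0), p) for r, p in zip(R, inds))

    best_R, best_val = np.zeros(n), 0.0
    cons = [{"type": "ineq", "fun": lambda R: budget - R.sum()}]
    bounds = [(0.0, c) for c in caps]
    for k in range(n_starts):
        x0 = rng.dirichlet(np.ones(n)) * budget if k else np.full(n, budget / n)
        x0 = np.minimum(x0, caps)
        res = optimize.minimize(neg_total, x0, method="SLSQP", bounds=bounds, constraints=cons)
        if res.success and -res.fun > best_val:
            best_val, best_R = -res.fun, np.clip(res.x, 0.0, caps)
    utilities = np.array([utility(r, p) for r, p in zip(best_R, inds)])
    return AllocationResult(
        R=best_R,
        utilities=utilities,
        total_utility=float(utilities.sum()),
        multiplier=math.nan,
        kkt_residual=math.nan,
        concave=False,
        flags=["non-concave"],
    )


def allocate_budget(problem: BudgetProblem, tol: float = 1e-9, seed: int = 0) -> AllocationResult:
    """Maximize summed utility subject to sum(R) <= budget, R >= 0.

    Concave problems (every individual passes :func:`check_diminishing_returns`
    on [0, budget]) are solved by bisection on the shared Lagrange multiplier.
    Otherwise a 20-start projected local search is used and the result is
    flagged ``"non-concave"``.  Ties in degenerate symmetric problems are
    broken lexicographically by individual index.
    """
    if problem.budget == 0.0:
        n = len(problem.individuals)
        return AllocationResult(
            R=np.zeros(n),
            utilities=np.zeros(n),
            total_utility=0.0,
            multiplier=math.inf,
            kkt_residual=0.0,
            concave=True,
        )
    all_concave = all(
        check_diminishing_returns(p, R_max=problem.budget)[0] for p in problem.individuals
    )
    if all_concave:
        return _concave_allocate(problem, tol)
    return _multistart_allocate(problem, seed=seed)
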