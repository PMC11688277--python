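"""Synthetic cohorts, driver signals, sensor streams and bundled market fixtures.

Every generator is a pure function of an explicit seed: one global seed is
split into independent per-stream generators through a fixed registry of
stream ids (``np.random.default_rng([seed, stream_id, ...])``), so adding a
new generator never perturbs existing streams.

Six scenario contrasts are shipped (urban/rural, income, lifestyle, diet,
social activity, pollution exposure).  The source model states only the
*direction* of each contrast and the per-arm sample sizes; directions are
encoded as shifts of the arm's parameter priors (default effect size 0.5
prior standard deviations) and every magnitude is configurable.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .allocation import LogisticAllocationParams
from .dynamics import DriverSignals, LinearDriverParams
from .economics import SocialCostParams
from .exceptions import ConfigurationError, DomainError
from .monitoring import SensorSeries

__all__ = [
    "ParamPrior",
    "ArmSpec",
    "ScenarioSpec",
    "Individual",
    "SyntheticCohort",
    "MarketTable",
    "SCENARIO_NAMES",
    "generate_drivers",
    "default_scenario",
    "generate_population",
    "simulate_cohort",
    "inject_missingness",
    "generate_vitals",
    "inject_joint_events",
    "load_market_table",
    "feature_gap_report",
]

# Fixed registry: stream name -> id used to split the global seed.
STREAM_IDS = {
    "S": 0,
    "P": 1,
    "E_env": 2,
    "C_exo": 3,
    "R_exo": 4,
    "Sc": 5,
    "Rm": 6,
    "population": 7,
    "missingness": 8,
    "activity": 9,
    "heart_rate": 10,
}

SCENARIO_NAMES = ("urban_rural", "income", "lifestyle", "diet", "social", "pollution")


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    if stream not in STREAM_IDS:
        raise ConfigurationError(f"unknown random stream '{stream}'")
    return np.random.default_rng([int(seed), STREAM_IDS[stream], *map(int, extra)])


# ---------------------------------------------------------------------------
# driver signal processes
# ---------------------------------------------------------------------------

def _gen_process(t_grid: np.ndarray, cfg: dict, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.get("process")
    if kind == "constant":
        return np.full(t_grid.size, float(cfg["value"]))
    if kind == "sinusoid":
        mean = float(cfg.get("mean", 0.0))
        amp = float(cfg.get("amplitude", 1.0))
        period = float(cfg.get("period", 1.0))
        phase = float(cfg.get("phase", 0.0))
        noise = float(cfg.get("noise_sd", 0.0))
        x = mean + amp * np.sin(2.0 * np.pi * t_grid / period + phase)
        if noise > 0:
            x = x + rng.normal(0.0, noise, size=t_grid.size)
        return x
    if kind == "mean_reverting":
        # Euler-discretized Ornstein-Uhlenbeck: x_{k+1} = x_k + rate*(mean-x_k)*dt + sd*sqrt(dt)*eps
        rate = float(cfg.get("rate", 1.0))
        mean = float(cfg.get("mean", 0.0))
        sd = float(cfg.get("sd", 1.0))
        x0 = float(cfg.get("x0", mean))
        x = np.empty(t_grid.size)
        x[0] = x0
        dt = np.diff(t_grid)
        eps = rng.normal(size=t_grid.size - 1)
        for i, h in enumerate(dt):
            x[i + 1] = x[i] + rate * (mean - x[i]) * h + sd * math.sqrt(h) * eps[i]
        return x
    raise ConfigurationError(f"unknown driver process '{kind}'")


def generate_drivers(t_grid: np.ndarray, spec: dict, seed: int) -> DriverSignals:
    """Build DriverSignals from per-signal process configs.

    ``spec`` maps signal names (S, P, E_env, C_exo, R_exo, Sc, Rm) to process
    configs with ``process`` one of constant / sinusoid / mean_reverting.
    Deterministic for a fixed seed; each signal consumes its own stream.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ConfigurationError("t_grid must be a strictly increasing 1-D array")
    out: dict = {}
    for name, cfg in spec.items():
        if name not in STREAM_IDS or name in ("population", "missingness", "activity", "heart_rate"):
            raise ConfigurationError(f"unknown driver signal '{name}'")
        values = _gen_process(t_grid, cfg, _rng(seed, name))
        out[name] = (t_grid.copy(), values)
    return DriverSignals(**out)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamPrior:
    """Truncated-normal prior: N(mean, sd) clipped to [lo, hi]."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0 or not math.isfinite(self.mean):
            raise ConfigurationError(f"invalid prior {self}")
        if self.lo > self.hi:
            raise ConfigurationError(f"prior bounds inverted: lo={self.lo} > hi={self.hi}")

    def shifted(self, n_sd: float) -> "ParamPrior":
        m = min(max(self.mean + n_sd * self.sd, self.lo), self.hi)
        return replace(self, mean=m)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, size=n), self.lo, self.hi)


# Baseline priors for one individual.  Drivers are constant per-individual
# levels; dynamics follow the linear-driver model.
_BASE_PRIORS: dict[str, ParamPrior] = {
    "alpha1": ParamPrior(0.50, 0.10, lo=0.0, hi=2.0),
    "alpha2": ParamPrior(0.30, 0.08, lo=0.0, hi=2.0),
    "alpha3": ParamPrior(0.20, 0.08, lo=0.0, hi=2.0),
    "beta": ParamPrior(0.10, 0.03, lo=0.0, hi=1.0),
    "H0": ParamPrior(0.0, 0.5, lo=-3.0, hi=3.0),
    "S": ParamPrior(1.0, 0.3, lo=0.0, hi=2.5),
    "P": ParamPrior(0.5, 0.2, lo=-1.0, hi=2.0),
    "E": ParamPrior(0.5, 0.3, lo=-2.0, hi=2.0),
    "C": ParamPrior(2.0, 0.5, lo=0.0, hi=5.0),
    "C0": ParamPrior(2.0, 0.5, lo=0.0, hi=5.0),
}

# Directional contrasts, as prior-mean shifts in units of the prior sd.
# Mapping of narrative outcomes onto model quantities (documented convention):
# cardiovascular / chronic-disease burden -> larger cost gain beta and lower
# baseline H0; better environment -> higher E level; more social contact ->
# higher S level; lifestyle/diet quality -> driver gains and beta.
_DEFAULT_EFFECT = 0.5

_CONTRASTS: dict[str, list[tuple[str, int, dict[str, float]]]] = {
    # urban elders: higher cardiovascular burden, worse air -> beta up, E down
    "urban_rural": [
        ("urban", 500, {"beta": +1.0, "E": -1.0}),
        ("rural", 500, {"beta": -0.0, "E": +0.0, "S": +0.5}),
    ],
    # low income: higher chronic-disease burden and behavior cost, worse baseline
    "income": [
        ("high_income", 500, {"C": -1.0, "H0": +1.0}),
        ("low_income", 500, {"beta": +1.0, "C": +1.0, "H0": -1.0}),
    ],
    # active elders: larger driver gains (better cardio/cognitive response)
    "lifestyle": [
        ("active", 500, {"alpha1": +1.0, "alpha2": +1.0, "alpha3": +1.0, "beta": -0.5}),
        ("sedentary", 500, {"alpha1": -1.0, "alpha2": -1.0, "beta": +1.0}),
    ],
    # metabolic burden rises with a high-fat/high-sugar diet
    "diet": [
        ("balanced", 300, {"beta": -0.5, "H0": +0.5}),
        ("high_fat_sugar", 300, {"beta": +1.5, "H0": -0.5}),
        ("vegetarian", 300, {"beta": +0.0}),
    ],
    # social contact level drives S and the mental-health gain alpha2
    "social": [
        ("high_social", 400, {"S": +1.0, "alpha2": +0.5}),
        ("medium_social", 400, {}),
        ("low_social", 400, {"S": -1.0, "alpha2": -0.5, "H0": -0.5}),
    ],
    # pollution exposure lowers the environment level (respiratory burden)
    "pollution": [
        ("high_pollution", 500, {"E": -1.5, "beta": +0.5}),
        ("low_pollution", 500, {"E": +0.5}),
    ],
}


@dataclass
class ArmSpec:
    name: str
    n: int
    priors: dict[str, ParamPrior]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError(f"arm '{self.name}': n must be > 0, got {self.n}")
        missing = set(_BASE_PRIORS) - set(self.priors)
        if missing:
            raise ConfigurationError(f"arm '{self.name}': missing priors for {sorted(missing)}")


@dataclass
class ScenarioSpec:
    name: str
    arms: list[ArmSpec]
    seed: int = 0
    lam_total: float = 10.0
    gamma_sens: float = -1.0  # narrative default: more resources when health is poor
    delta_sc: float = 0.3
    eta: float = 0.5

    def __post_init__(self) -> None:
        if not self.arms:
            raise ConfigurationError("scenario needs at least one arm")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate arm names in scenario '{self.name}'")


def default_scenario(name: str, seed: int = 0, effect: float = _DEFAULT_EFFECT) -> ScenarioSpec:
    """The shipped scenario configuration for one of the six cohort contrasts.

    Per-arm sample sizes follow the published experimental design (500 per arm
    for urban/rural, income, lifestyle and pollution; 3 x 300 for diet;
    3 x 400 for social activity).  ``effect`` rescales all directional shifts.
    """
    if name not in _CONTRASTS:
        raise ConfigurationError(f"unknown scenario '{name}'; choose from {SCENARIO_NAMES}")
    arms = []
    for arm_name, n, shifts in _CONTRASTS[name]:
        priors = {
            key: prior.shifted(effect * shifts[key]) if key in shifts else prior
            for key, prior in _BASE_PRIORS.items()
        }
        arms.append(ArmSpec(name=arm_name, n=n, priors=priors))
    return ScenarioSpec(name=name, arms=arms, seed=seed)


@dataclass
class Individual:
    id: str
    arm: str
    dynamics: LinearDriverParams
    allocation: LogisticAllocationParams
    cost: SocialCostParams
    H0: float
    driver_levels: dict[str, float]
    trajectory: Optional[object] = None  # filled by simulate_cohort

    def drivers(self) -> DriverSignals:
        lv = self.driver_levels
        return DriverSignals(S=lv["S"], P=lv["P"], E_env=lv["E"], C_exo=lv["C"])


@dataclass
class SyntheticCohort:
    scenario: str
    seed: int
    individuals: list[Individual]

    def arm_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ind in self.individuals:
            counts[ind.arm] = counts.get(ind.arm, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            row = {
                "id": ind.id,
                "arm": ind.arm,
                "alpha1": ind.dynamics.alpha1,
                "alpha2": ind.dynamics.alpha2,
                "alpha3": ind.dynamics.alpha3,
                "beta": ind.dynamics.beta,
                "H0": ind.H0,
                "C0": ind.cost.C0,
                **{f"level_{k}": v for k, v in ind.driver_levels.items()},
            }
            rows.append(row)
        return pd.DataFrame(rows)


def _validate_priors(spec: ScenarioSpec) -> None:
    """Reject inadmissible prior ranges before any random draw."""
    for arm in spec.arms:
        pr = arm.priors
        for key in ("alpha1", "alpha2", "alpha3", "beta", "C", "C0", "S"):
            if pr[key].lo < 0:
                raise ConfigurationError(
                    f"arm '{arm.name}': prior for '{key}' admits negative values "
                    f"(lo={pr[key].lo}); downstream validators require >= 0"
                )
        # behavior cost stays non-negative: delta_sc * Sc_max must not exceed 1
        if spec.delta_sc * pr["S"].hi > 1.0:
            raise ConfigurationError(
                f"arm '{arm.name}': delta_sc={spec.delta_sc} with S up to {pr['S'].hi} "
                "can drive the behavior cost negative"
            )


def generate_population(spec: ScenarioSpec) -> SyntheticCohort:
    """Draw a cohort from a scenario spec; per-arm counts match exactly.

    Reproducible: a fixed (spec, seed) pair always produces the same cohort.
    """
    _validate_priors(spec)
    individuals: list[Individual] = []
    for arm_idx, arm in enumerate(spec.arms):
        rng = _rng(spec.seed, "population", arm_idx)
        draws = {key: prior.draw(rng, arm.n) for key, prior in arm.priors.items()}
        for i in range(arm.n):
            individuals.append(
                Individual(
                    id=f"{spec.name}-{arm.name}-{i:04d}",
                    arm=arm.name,
                    dynamics=LinearDriverParams(
                        alpha1=float(draws["alpha1"][i]),
                        alpha2=float(draws["alpha2"][i]),
                        alpha3=float(draws["alpha3"][i]),
                        beta=float(draws["beta"][i]),
                    ),
                    allocation=LogisticAllocationParams(
                        lam_total=spec.lam_total, gamma_sens=spec.gamma_sens
                    ),
                    cost=SocialCostParams(
                        C0=float(draws["C0"][i]), delta_sc=spec.delta_sc, eta=spec.eta
                    ),
                    H0=float(draws["H0"][i]),
                    driver_levels={
                        "S": float(draws["S"][i]),
                        "P": float(draws["P"][i]),
                        "E": float(draws["E"][i]),
                        "C": float(draws["C"][i]),
                    },
                )
            )
    return SyntheticCohort(scenario=spec.name, seed=spec.seed, individuals=individuals)


def simulate_cohort(
    cohort: SyntheticCohort, t_grid: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """Simulate each individual's linear-driver trajectory; return end-of-horizon summary.

    Attaches the trajectory to each individual and returns a DataFrame with
    columns (id, arm, H0, H_end, H_mean).
    """
    from .dynamics import LinearModel, simulate_trajectory

    if t_grid is None:
        t_grid = np.linspace(0.0, 10.0, 26)
    rows = []
    for ind in cohort.individuals:
        traj = simulate_trajectory(
            ind.H0, LinearModel(ind.dynamics, ind.drivers()), t_grid
        )
        ind.trajectory = traj
        rows.append(
            {
                "id": ind.id,
                "arm": ind.arm,
                "H0": ind.H0,
                "H_end": float(traj.H[-1]),
                "H_mean": float(np.mean(traj.H)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensor streams, missingness and injected events
# ---------------------------------------------------------------------------

def inject_missingness(
    series: SensorSeries,
    mechanism: str,
    rate: float,
    max_burst: int = 5,
    seed: int = 0,
) -> SensorSeries:
    """Mask a fraction of points as missing; original values stay under the mask.

    ``random`` drops exactly round(rate*n) isolated points; ``burst`` drops
    contiguous runs, each of length <= max_burst (runs never coalesce, so the
    cap holds for maximal gaps too).
    """
    if not 0.0 <= rate < 1.0:
        raise DomainError(f"rate must be in [0, 1), got {rate}")
    out = series.copy()
    n = out.t.size
    k = int(round(rate * n))
    if k == 0:
        return out
    rng = _rng(seed, "missingness")
    if mechanism == "random":
        idx = rng.choice(n, size=k, replace=False)
        out.mask[idx] = False
    elif mechanism == "burst":
        if max_burst < 1:
            raise ConfigurationError(f"max_burst must be >= 1, got {max_burst}")
        missing = np.zeros(n, dtype=bool)
        dropped, attempts = 0, 0
        while dropped < k and attempts < 200 * k:
            attempts += 1
            L = min(int(rng.integers(1, max_burst + 1)), k - dropped)
            start = int(rng.integers(0, n - L + 1))
            lo = max(start - 1, 0)
            hi = min(start + L + 1, n)
            if missing[lo:hi].any():  # keep runs separated so they never merge
                continue
            missing[start : start + L] = True
            dropped += L
        out.mask[missing] = False
    else:
        raise ConfigurationError(f"unknown missingness mechanism '{mechanism}'")
    return out


def generate_vitals(
    t_grid: np.ndarray,
    seed: int = 0,
    activity_mean: float = 100.0,
    activity_sd: float = 10.0,
    hr_mean: float = 70.0,
    hr_sd: float = 5.0,
) -> tuple[SensorSeries, SensorSeries]:
    """Stationary Gaussian activity and heart-rate streams on a shared grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    act = activity_mean + activity_sd * _rng(seed, "activity").normal(size=t_grid.size)
    hr = hr_mean + hr_sd * _rng(seed, "heart_rate").normal(size=t_grid.size)
    return (
        SensorSeries(t_grid, act, channel="activity"),
        SensorSeries(t_grid, hr, channel="heart_rate"),
    )


def inject_joint_events(
    activity: SensorSeries,
    heart_rate: SensorSeries,
    starts: Sequence[int],
    duration: int,
    effect_sd: float = 3.0,
    activity_sd: float = 10.0,
    hr_sd: float = 5.0,
) -> tuple[SensorSeries, SensorSeries]:
    """Superimpose simultaneous activity drops and heart-rate rises.

    Each event shifts activity down and heart rate up by ``effect_sd`` noise
    standard deviations for ``duration`` consecutive points starting at the
    given indices.
    """
    act, hr = activity.copy(), heart_rate.copy()
    n = act.t.size
    for s in starts:
        sl = slice(int(s), min(int(s) + duration, n))
        act.values[sl] -= effect_sd * activity_sd
        hr.values[sl] += effect_sd * hr_sd
    return act, hr


# ---------------------------------------------------------------------------
# bundled market-research fixtures
# ---------------------------------------------------------------------------

_FIXTURES = {
    "features": (
        "features.csv",
        "71e53e1ab14668e04261e3e6ddb55694760aa7d32f63815f2bfa777b9e76d097",
    ),
    "conditions": (
        "conditions.csv",
        "28056cf6bc71ededdb6772738cbf3a840e455d79e17f64cfbe71c50198b4cf19",
    ),
}

_PCT_BOUNDS = (0.0, 100.0)


@dataclass
class MarketTable:
    kind: str
    df: pd.DataFrame

    @property
    def label_column(self) -> str:
        return "feature" if self.kind == "features" else "condition"

    def row(self, label: str) -> pd.Series:
        match = self.df[self.df[self.label_column] == label]
        if match.empty:
            raise KeyError(f"no row labeled '{label}' in the {self.kind} table")
        return match.iloc[0]


def load_market_table(which: str) -> MarketTable:
    """Load a bundled market-research fixture ('features' or 'conditions').

    The file checksum is verified before parsing; percentage columns must lie
    in [0, 100] and the difficulty score in [1, 5].
    """
    if which not in _FIXTURES:
        raise ConfigurationError(f"unknown table '{which}'; choose 'features' or 'conditions'")
    fname, expected = _FIXTURES[which]
    try:
        raw = resources.files("eldersim.data").joinpath(fname).read_bytes()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ConfigurationError(f"fixture {fname} missing: {exc}") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise ConfigurationError(
            f"fixture {fname} corrupt: sha256 {digest} != expected {expected}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    for col in df.columns:
        if col.endswith("_pct"):
            vals = df[col]
            if (vals < _PCT_BOUNDS[0]).any() or (vals > _PCT_BOUNDS[1]).any():
                raise ConfigurationError(f"fixture {fname}: column {col} outside [0, 100]")
    if "technical_difficulty" in df.columns:
        td = df["technical_difficulty"]
        if (td < 1).any() or (td > 5).any():
            raise ConfigurationError(f"fixture {fname}: technical_difficulty outside [1, 5]")
    return MarketTable(kind=which, df=df)


def feature_gap_report(table: MarketTable) -> pd.DataFrame:
    """Gap = importance - current availability per feature, sorted descending.

    Stable sort: descending gap, ties broken by feature label.
    """
    if table.kind != "features":
        raise ConfigurationError("feature_gap_report expects the 'features' table")
    df = table.df.copy()
    df["gap"] = df["importance_pct"] - df["current_availability_pct"]
    df = df.sort_values(["gap", "feature"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)
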