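"""Social-capital cost model and cost-benefit accounting.

The behavior cost ``C = C0 * (1 - delta_sc*Sc / (1 + eta*Rm))`` decreases with
social-capital support Sc and its resource input Rm.  Inadmissible parameter
combinations (which would make the cost negative) raise rather than clamp, so
misconfiguration is surfaced instead of hidden.

Benefits and costs are weighted sums of caller-supplied components; weights are
NOT required to sum to one (use :func:`normalize_weights` if that convention is
wanted).  The cost-benefit ratio is their quotient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AdmissibilityError, ConfigurationError, DomainError

__all__ = [
    "SocialCostParams",
    "BenefitComponents",
    "CostComponents",
    "behavior_cost",
    "total_benefit",
    "total_cost",
    "cbr",
    "scenario_compare",
    "health_benefit_from_trajectory",
    "normalize_weights",
]


@dataclass(frozen=True)
class SocialCostParams:
    """Baseline cost C0, social-capital impact delta_sc and resource sensitivity eta."""

    C0: float
    delta_sc: float
    eta: float

    def __post_init__(self) -> None:
        for name, v in (("C0", self.C0), ("delta_sc", self.delta_sc), ("eta", self.eta)):
            if not math.isfinite(v):
                raise ConfigurationError(f"SocialCostParams.{name} must be finite, got {v!r}")
            if v < 0:
                raise ConfigurationError(f"SocialCostParams.{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class BenefitComponents:
    E_h: float
    E_s: float
    E_e: float
    w_h: float = 1.0
    w_s: float = 1.0
    w_e: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.E_h, self.E_s, self.E_e, self.w_h, self.w_s, self.w_e)
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError("benefit components and weights must be finite")
        if min(self.w_h, self.w_s, self.w_e) < 0:
            raise ConfigurationError("benefit weights must be >= 0")


@dataclass(frozen=True)
class CostComponents:
    C_d: float
    C_o: float
    C_m: float
    w_d: float = 1.0
    w_o: float = 1.0
    w_m: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.C_d, self.C_o, self.C_m, self.w_d, self.w_o, self.w_m)
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError("cost components and weights must be finite")
        if min(self.C_d, self.C_o, self.C_m) < 0:
            raise ConfigurationError("cost components must be >= 0")
        if min(self.w_d, self.w_o, self.w_m) < 0:
            raise ConfigurationError("cost weights must be >= 0")


def behavior_cost(Sc: float, Rm: float, params: SocialCostParams) -> float:
    """Behavior cost C0 * (1 - delta_sc*Sc / (1 + eta*Rm)).

    Raises :class:`AdmissibilityError` when the offset term exceeds 1 (the
    cost would be negative), naming the offending values.
    """
    if Sc < 0 or Rm < 0:
        raise DomainError(f"Sc and Rm must be >= 0, got Sc={Sc}, Rm={Rm}")
    ratio = params.delta_sc * Sc / (1.0 + params.eta * Rm)
    if ratio > 1.0 + 1e-12:
        raise AdmissibilityError(
            f"delta_sc*Sc/(1+eta*Rm) = {ratio:.6g} > 1 would give a negative cost "
            f"(Sc={Sc}, Rm={Rm}, delta_sc={params.delta_sc}, eta={params.eta})"
        )
    return params.C0 * (1.0 - min(ratio, 1.0))


def total_benefit(bc: BenefitComponents) -> float:
    """Weighted total benefit w_h*E_h + w_s*E_s + w_e*E_e."""
    return bc.w_h * bc.E_h + bc.w_s * bc.E_s + bc.w_e * bc.E_e


def total_cost(cc: CostComponents) -> float:
    """Weighted total cost w_d*C_d + w_o*C_o + w_m*C_m."""
    return cc.w_d * cc.C_d + cc.w_o * cc.C_o + cc.w_m * cc.C_m


def cbr(benefit: float, cost: float) -> float:
    """Cost-benefit ratio benefit / cost; a non-positive cost is an error, not inf."""
    if cost <= 0.0:
        raise DomainError(f"cost-benefit ratio undefined for weighted cost {cost} <= 0")
    return benefit / cost


def scenario_compare(
    scenarios: Sequence[tuple[str, BenefitComponents, CostComponents]]
) -> pd.DataFrame:
    """Rank scenarios by cost-benefit ratio (descending; ties broken by name).

    Returns a DataFrame with all benefit/cost components for audit plus the
    computed E, B, CBR and rank columns.
    """
    if len(scenarios) == 0:
        raise ConfigurationError("scenario_compare needs at least one scenario")
    names = [s[0] for s in scenarios]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate scenario names: {dupes}")
    rows = []
    for name, bc, cc in scenarios:
        E, B = total_benefit(bc), total_cost(cc)
        rows.append(
            {
                "scenario": name,
                "E_h": bc.E_h, "E_s": bc.E_s, "E_e": bc.E_e,
                "w_h": bc.w_h, "w_s": bc.w_s, "w_e": bc.w_e,
                "C_d": cc.C_d, "C_o": cc.C_o, "C_m": cc.C_m,
                "w_d": cc.w_d, "w_o": cc.w_o, "w_m": cc.w_m,
                "E": E, "B": B, "CBR": cbr(E, B),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["CBR", "scenario"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def health_benefit_from_trajectory(trajectory) -> float:
    """Repo convention for the health-benefit component: mean(H) - H0.

    The source model never operationalizes how the health benefit is measured
    from a trajectory; this helper is a documented convention of this package,
    not part of the model itself.
    """
    H = np.asarray(trajectory.H, dtype=float)
    return float(np.mean(H) - H[0])


def normalize_weights(w: Sequence[float]) -> list[float]:
    """Scale weights to sum to one (convenience only; never applied implicitly)."""
    arr = np.asarray(w, dtype=float)
    s = arr.sum()
    if s <= 0:
        raise DomainError("cannot normalize weights with non-positive sum")
    return list(arr / s)
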