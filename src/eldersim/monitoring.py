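"""Operational monitoring: GP imputation of short sensor gaps and rule-based alerts.

Short runs of missing samples (length <= ``max_gap``) are filled with the
posterior mean of a Gaussian process with a squared-exponential kernel whose
hyperparameters are fixed by policy (no marginal-likelihood optimization, for
reproducibility).  Longer gaps are left masked and reported — the long-gap
pathway is out of scope here.

The emergency rule is a conjunction: a window is flagged when the window-mean
activity level drops below the trailing baseline by at least ``|z_drop|``
baseline standard deviations AND the window-mean heart rate rises by at least
``z_rise`` baseline standard deviations, simultaneously.  Drop-only or
rise-only anomalies never trigger.  Thresholds, window sizes and escalation
levels are clinician-configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "SensorSeries",
    "GapPolicy",
    "AlertRule",
    "AlertEvent",
    "ImputationResult",
    "find_gaps",
    "impute_short_gaps",
    "rolling_zscores",
    "detect_emergency",
]


@dataclass
class SensorSeries:
    """One channel of a sensor stream on a strictly increasing time grid.

    ``mask`` marks observed points (True = observed).  Values under a False
    mask are ignored by consumers but retained, which lets synthetic studies
    score imputation against the hidden truth.
    """

    t: np.ndarray
    values: np.ndarray
    mask: Optional[np.ndarray] = None
    channel: str = "signal"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.t.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.t.ndim != 1 or self.t.shape != self.values.shape or self.t.shape != self.mask.shape:
            raise ConfigurationError("t, values and mask must be equal-length 1-D arrays")
        if np.any(np.diff(self.t) <= 0):
            raise ConfigurationError("sensor time grid must be strictly increasing")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ConfigurationError(f"observed values of channel '{self.channel}' must be finite")

    def copy(self) -> "SensorSeries":
        return SensorSeries(self.t.copy(), self.values.copy(), self.mask.copy(), self.channel)


@dataclass(frozen=True)
class GapPolicy:
    """Imputation policy: short-gap cutoff and fixed GP hyperparameters."""

    max_gap: int = 5
    kernel_scale: float = 5.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ConfigurationError(f"max_gap must be >= 1, got {self.max_gap}")
        if self.kernel_scale <= 0:
            raise ConfigurationError(f"kernel_scale must be > 0, got {self.kernel_scale}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class AlertRule:
    """Conjunction rule for emergency detection on (activity, heart-rate) streams."""

    window: int = 12
    baseline_window: int = 48
    z_drop: float = -2.0
    z_rise: float = 2.0
    escalation_levels: tuple[float, ...] = (2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ConfigurationError(f"window must be >= 2, got {self.window}")
        if self.baseline_window < 3:
            raise ConfigurationError(f"baseline_window must be >= 3, got {self.baseline_window}")
        if not (self.z_drop <= 0.0 <= self.z_rise):
            raise ConfigurationError(
                f"need z_drop <= 0 <= z_rise, got ({self.z_drop}, {self.z_rise})"
            )
        if np.any(np.diff(self.escalation_levels) <= 0):
            raise ConfigurationError("escalation_levels must be strictly increasing")


@dataclass
class AlertEvent:
    t_start: float
    t_end: float
    severity: int
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ConfigurationError(f"need t_start < t_end, got [{self.t_start}, {self.t_end}]")


@dataclass
class ImputationResult:
    series: SensorSeries
    predictive_sd: np.ndarray
    long_gaps: list[tuple[int, int]]  # (start_idx, end_idx) inclusive, still masked


def find_gaps(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of missing points as (start, end) inclusive index pairs."""
    gaps = []
    missing = ~np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(np.diff(np.concatenate(([False], missing, [False])).astype(int)))
    for start, stop in zip(idx[::2], idx[1::2]):
        gaps.append((int(start), int(stop - 1)))
    return gaps


def impute_short_gaps(series: SensorSeries, policy: GapPolicy) -> ImputationResult:
    """Fill gaps of length <= max_gap with the GP posterior mean.

    The GP (squared-exponential kernel, prior mean = observed mean, signal
    variance = observed variance) is conditioned on all observed points.
    Observed points pass through bitwise-unchanged; gaps longer than
    ``max_gap`` remain masked and are returned in ``long_gaps``.
    """
    obs = series.mask
    if obs.sum() < 2:
        raise DomainError("imputation requires at least two observed points")
    t_obs = series.t[obs].reshape(-1, 1)
    y_obs = series.values[obs]
    y_mean = float(np.mean(y_obs))
    y_var = float(np.var(y_obs))
    amplitude = max(y_var, 1e-12)
    kernel = ConstantKernel(amplitude, constant_value_bounds="fixed") * RBF(
        policy.kernel_scale, length_scale_bounds="fixed"
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, alpha=policy.noise_sd**2 + 1e-10, optimizer=None
    )
    gp.fit(t_obs, y_obs - y_mean)
    pred_mean, pred_sd = gp.predict(series.t.reshape(-1, 1), return_std=True)
    pred_mean = pred_mean + y_mean

    out = series.copy()
    long_gaps = []
    for start, end in find_gaps(series.mask):
        length = end - start + 1
        if length <= policy.max_gap:
            out.values[start : end + 1] = pred_mean[start : end + 1]
            out.mask[start : end + 1] = True
        else:
            long_gaps.append((start, end))
    return ImputationResult(series=out, predictive_sd=pred_sd, long_gaps=long_gaps)


def rolling_zscores(series: SensorSeries, baseline_window: int) -> np.ndarray:
    """Per-point z-scores against a trailing baseline ending just before each point.

    ``z[i] = (x[i] - mean(x[i-w:i])) / sd(x[i-w:i])``.  Points without a full
    baseline, and points whose baseline has zero variance, are NaN (the latter
    with a warning).
    """
    if baseline_window < 3:
        raise ConfigurationError(f"baseline_window must be >= 3, got {baseline_window}")
    x = series.values.astype(float)
    n = x.size
    z = np.full(n, np.nan)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    w = baseline_window
    idx = np.arange(w, n)
    mean = (csum[idx] - csum[idx - w]) / w
    var = (csum2[idx] - csum2[idx - w]) / w - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    zero_var = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(zero_var):
        warnings.warn(
            f"channel '{series.channel}': zero baseline variance at "
            f"{int(zero_var.sum())} point(s); z-scores masked there",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        zi = (x[idx] - mean) / sd
    zi[zero_var] = np.nan
    z[idx] = zi
    return z


def _window_zscores(x: np.ndarray, window: int, baseline_window: int) -> np.ndarray:
    """z-score of each window mean versus the trailing baseline, indexed by window start.

    For window start w: baseline = x[w-bw:w], statistic =
    (mean(x[w:w+window]) - mean(baseline)) / sd(baseline).  Entries without a
    full baseline or a full window are NaN.
    """
    n = x.size
    bw = baseline_window
    out = np.full(n, np.nan)
    if n < bw + window:
        return out
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    starts = np.arange(bw, n - window + 1)
    b_mean = (csum[starts] - csum[starts - bw]) / bw
    b_var = (csum2[starts] - csum2[starts - bw]) / bw - b_mean**2
    b_sd = np.sqrt(np.maximum(b_var, 0.0))
    w_mean = (csum[starts + window] - csum[starts]) / window
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w_mean - b_mean) / b_sd
    z[b_sd <= 1e-12 * np.maximum(1.0, np.abs(b_mean))] = np.nan
    out[starts] = z
    return out


def detect_emergency(
    activity: SensorSeries, heart_rate: SensorSeries, rule: AlertRule
) -> list[AlertEvent]:
    """Flag windows with a simultaneous significant activity drop and heart-rate rise.

    Both series must share the same time grid (resampling is the caller's
    job).  Qualifying windows closer than ``window/2`` apart are merged into a
    single event; severity is the highest escalation level not exceeding the
    event's maximum absolute window z-score (minimum severity 1).
    """
    if activity.t.shape != heart_rate.t.shape or not np.allclose(
        activity.t, heart_rate.t, rtol=0.0, atol=1e-12
    ):
        raise ConfigurationError("activity and heart-rate series must share the same time grid")
    t = activity.t
    z_act = _window_zscores(activity.values, rule.window, rule.baseline_window)
    z_hr = _window_zscores(heart_rate.values, rule.window, rule.baseline_window)
    with np.errstate(invalid="ignore"):
        qualifying = (z_act <= rule.z_drop) & (z_hr >= rule.z_rise)
    starts = np.flatnonzero(qualifying)
    if starts.size == 0:
        return []

    merge_gap = rule.window / 2.0
    groups: list[list[int]] = [[int(starts[0])]]
    for s in starts[1:]:
        if s - groups[-1][-1] < rule.window + merge_gap:  # overlapping or near windows merge
            groups[-1].append(int(s))
        else:
            groups.append([int(s)])

    n = t.size
    events = []
    for grp in groups:
        i0 = grp[0]
        i1 = min(grp[-1] + rule.window - 1, n - 1)
        max_z = max(float(np.max(np.abs(z_act[grp]))), float(np.max(z_hr[grp])))
        severity = 1
        for lvl, thr in enumerate(rule.escalation_levels, start=1):
            if max_z >= thr:
                severity = lvl
        events.append(
            AlertEvent(
                t_start=float(t[i0]),
                t_end=float(t[i1]),
                severity=severity,
                evidence={
                    "activity_z": float(np.min(z_act[grp])),
                    "heart_rate_z": float(np.max(z_hr[grp])),
                    "max_abs_z": max_z,
                },
            )
        )
    return events
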