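"""Discrete-day self-excitation (Hawkes-type) contagion model.

Each incident transiently raises the expected number of incidents on the
following days.  With contagion decaying exponentially with mean duration
``T_excite`` days, the probability that an event on day ``t_i`` incites an
event during the 24 hours of a later day ``t_j`` is the exponential mass
falling in that day,

    P(t_j | t_i, T) = exp(-(d - 1) / T) - exp(-d / T),   d = t_j - t_i >= 1,

which sums to one over d = 1..inf.  The expected number of events on day
``t_n`` given the observed history is then

    N_exp(t_n) = N0(t_n) + N_secondary * sum_{t_i < t_n} P(t_n | t_i, T),

where ``N_secondary`` is the branching ratio (mean number of secondary
events directly incited by one event) and ``N0(t)`` a slowly varying
baseline rate: constant, linear, or a Gaussian-weighted running mean of
the data itself, optionally modulated by mean-one day-of-week and
month-of-year weights.  Daily counts are modelled as Poisson with mean
``N_exp(t)`` conditioned on the observed history, which supports multiple
same-day events; same-day pairs do not excite each other (d >= 1 only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.special import gammaln

from .event_io import DailySeries

__all__ = [
    "T_EXCITE_BOUNDS",
    "N_SECONDARY_BOUNDS",
    "BaselineModel",
    "ContagionParams",
    "excitation_probability",
    "excitation_series",
    "expected_events",
    "expected_series",
    "log_likelihood",
    "poisson_log_likelihood",
    "estimate_calendar_weights",
    "baseline_running_mean",
]

#: Fitting box for the mean contagion duration (days).
T_EXCITE_BOUNDS = (0.5, 365.0)
#: Fitting box for the branching ratio.
N_SECONDARY_BOUNDS = (0.0, 5.0)

_BASELINE_FORMS = ("constant", "linear", "running_mean")


def excitation_probability(delta_days, t_excite: float):
    """Probability that an event excites a successor ``delta_days`` later.

    Vectorized over ``delta_days`` (integers >= 1).  Strictly decreasing in
    the lag and sums to 1 - exp(-K/T) over lags 1..K (telescoping).
    """
    if t_excite <= 0:
        raise ValueError("t_excite must be positive")
    delta = np.asarray(delta_days)
    if np.any(delta < 1):
        raise ValueError("delta_days must be >= 1 (same-day excitation undefined)")
    out = np.exp(-(delta - 1.0) / t_excite) - np.exp(-delta / t_excite)
    return float(out) if np.isscalar(delta_days) else out


def excitation_series(counts: np.ndarray, t_excite: float) -> np.ndarray:
    """Per-day excitation pressure ``S(t) = sum_{t_i < t} P(t | t_i, T)``.

    Computed in O(n) with the recursion B(t+1) = (B(t) + c_t) * exp(-1/T),
    S(t) = (exp(1/T) - 1) * B(t), via an IIR filter.  One unit of S times
    the branching ratio is the contagion part of the day-t mean.
    """
    if t_excite <= 0:
        raise ValueError("t_excite must be positive")
    counts = np.asarray(counts, dtype=float)
    r = np.exp(-1.0 / t_excite)
    # y[t] = r * (y[t-1] + counts[t]) = sum_{s<=t} c_s r^{t-s+1}
    y = signal.lfilter([r], [1.0, -r], counts)
    s = np.empty_like(y)
    s[0] = 0.0
    s[1:] = (np.exp(1.0 / t_excite) - 1.0) * y[:-1]
    return s


@dataclass(frozen=True)
class BaselineModel:
    """Non-contagion baseline rate ``N0(t)`` in events/day.

    form
        ``constant``: ``params = (rate,)``.
        ``linear``: ``params = (rate_start, rate_end)``, linearly
        interpolated across the span (both endpoints >= 0, so the line is
        non-negative everywhere inside).
        ``running_mean``: Gaussian-kernel weighted running mean of the
        daily counts themselves (sd = ``bandwidth_days``, renormalized at
        the series edges, self-day included) times ``params[0]`` as a
        global scale.
    weekday_weights / month_weights
        Optional mean-one multipliers applied on top of the shape; they
        redistribute rate across the calendar without changing its mean.
    """

    form: str = "constant"
    params: tuple[float, ...] = (0.1,)
    weekday_weights: np.ndarray | None = None
    month_weights: np.ndarray | None = None
    bandwidth_days: float = 365.0

    def __post_init__(self) -> None:
        if self.form not in _BASELINE_FORMS:
            raise ValueError(f"unknown baseline form {self.form!r}")
        if self.bandwidth_days <= 0:
            raise ValueError("bandwidth_days must be positive")
        if any(p < 0 for p in self.params):
            raise ValueError("baseline parameters must be non-negative")
        for name in ("weekday_weights", "month_weights"):
            w = getattr(self, name)
            if w is not None:
                w = np.asarray(w, dtype=float)
                size = 7 if name == "weekday_weights" else 12
                if w.shape != (size,):
                    raise ValueError(f"{name} must have length {size}")
                if np.any(w < 0) or not np.isclose(w.mean(), 1.0):
                    raise ValueError(f"{name} must be non-negative with mean 1")
                object.__setattr__(self, name, w)

    def calendar_weights(self, series: DailySeries) -> np.ndarray:
        """Per-day multiplier from the weekday/month weight vectors."""
        w = np.ones(series.n_days)
        if self.weekday_weights is not None:
            w = w * self.weekday_weights[series.weekday]
        if self.month_weights is not None:
            w = w * self.month_weights[series.month - 1]
        return w

    def shape(self, series: DailySeries) -> np.ndarray:
        """Unit-scale baseline shape before calendar weighting."""
        t = np.arange(series.n_days, dtype=float)
        if self.form == "constant":
            return np.full(series.n_days, self.params[0])
        if self.form == "linear":
            a, b = self.params
            frac = t / max(series.n_days - 1, 1)
            return a * (1.0 - frac) + b * frac
        scale = self.params[0] if self.params else 1.0
        return scale * baseline_running_mean(series, self.bandwidth_days)

    def evaluate(self, series: DailySeries) -> np.ndarray:
        """Baseline rate N0(t) over the series span (>= 0 everywhere)."""
        return self.shape(series) * self.calendar_weights(series)


@dataclass(frozen=True)
class ContagionParams:
    """Full model state: branching ratio, contagion duration, baseline."""

    n_secondary: float
    t_excite: float
    baseline: BaselineModel

    def __post_init__(self) -> None:
        if self.n_secondary < 0:
            raise ValueError("n_secondary must be >= 0")
        if self.t_excite <= 0:
            raise ValueError("t_excite must be > 0")


def baseline_running_mean(
    series: DailySeries,
    bandwidth_days: float = 365.0,
    weekday_weights: np.ndarray | None = None,
    month_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-kernel weighted running mean of the daily counts.

    ``N0_rm(t) = sum_s K(t-s) c_s / sum_s K(t-s)`` with a Gaussian kernel
    of standard deviation ``bandwidth_days`` truncated at 4 sd; dividing by
    the in-span kernel mass renormalizes the edges, so a constant series
    maps to itself exactly and the running mean stays unbiased near the
    boundaries.  Optional mean-one calendar weights multiply the result.
    A bandwidth much wider than the excitation scale (>= 10x) keeps the
    baseline from absorbing the contagion signal; narrower bandwidths
    trigger a warning.
    """
    if bandwidth_days <= 0:
        raise ValueError("bandwidth_days must be positive")
    if bandwidth_days < 10 * 13.0:
        warnings.warn(
            "running-mean bandwidth is < 10x the typical excitation scale; "
            "the baseline may absorb part of the contagion signal",
            stacklevel=2,
        )
    counts = series.counts.astype(float)
    half = int(np.ceil(4 * bandwidth_days))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / bandwidth_days) ** 2)
    num = signal.fftconvolve(counts, kernel, mode="same")
    den = signal.fftconvolve(np.ones_like(counts), kernel, mode="same")
    out = np.clip(num / den, 0.0, None)
    if weekday_weights is not None:
        out = out * np.asarray(weekday_weights)[series.weekday]
    if month_weights is not None:
        out = out * np.asarray(month_weights)[series.month - 1]
    return out


def estimate_calendar_weights(
    series: DailySeries, weekday: bool = True, month: bool = True
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Exposure-adjusted empirical calendar weights, normalized to mean 1.

    The weekday weight for Monday is (events on Mondays / Mondays in span)
    divided by the overall daily rate; likewise for months.  These are
    estimated once from the data and held fixed during likelihood
    maximization.  Returns ``(weekday_weights, month_weights)`` with None
    for a component not requested.
    """
    rate = series.n_events / series.n_days
    wd = mo = None
    if weekday:
        obs = np.bincount(np.repeat(series.weekday, series.counts), minlength=7)
        exposure = np.bincount(series.weekday, minlength=7)
        wd = (obs / np.maximum(exposure, 1)) / rate
        wd = wd / wd.mean()
    if month:
        obs = np.bincount(np.repeat(series.month, series.counts), minlength=13)[1:]
        exposure = np.bincount(series.month, minlength=13)[1:]
        mo = np.where(exposure > 0, obs / np.maximum(exposure, 1) / rate, 1.0)
        mo = mo / mo.mean()
    return wd, mo


def expected_events(
    day: int,
    prior_event_days,
    params: ContagionParams,
    baseline_value: float | None = None,
) -> float:
    """Expected event count on one day given an explicit event history.

    ``baseline_value`` overrides the baseline evaluation for non-constant
    forms (which need the whole series for their shape).
    """
    prior = np.asarray(prior_event_days, dtype=float)
    if prior.size and prior.max() >= day:
        raise ValueError("all prior event days must precede the target day")
    if baseline_value is None:
        if params.baseline.form != "constant":
            raise ValueError(
                "baseline_value is required for non-constant baselines"
            )
        baseline_value = params.baseline.params[0]
    excite = 0.0
    if prior.size:
        excite = float(
            excitation_probability((day - prior).astype(int), params.t_excite).sum()
        )
    return float(baseline_value) + params.n_secondary * excite


def expected_series(series: DailySeries, params: ContagionParams) -> np.ndarray:
    """Expected daily counts over the whole span, conditioned on the
    observed history (events strictly before each day)."""
    n0 = params.baseline.evaluate(series)
    s = excitation_series(series.counts, params.t_excite)
    return n0 + params.n_secondary * s


def poisson_log_likelihood(counts: np.ndarray, mu: np.ndarray) -> float:
    """Sum of Poisson log-pmfs; -inf when an event sits on a zero mean."""
    counts = np.asarray(counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        return -np.inf
    zero_mean = mu == 0
    if np.any(counts[zero_mean] > 0):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            zero_mean, 0.0, counts * np.log(np.where(zero_mean, 1.0, mu))
        )
    return float(terms.sum() - mu.sum() - gammaln(counts + 1.0).sum())


def log_likelihood(series: DailySeries, params: ContagionParams) -> float:
    """Log-likelihood of a daily series under the contagion model."""
    return poisson_log_likelihood(series.counts, expected_series(series, params))
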