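"""Promoter-cycle period and rate estimation from switch profiles.

The three-state gene cycle (on -> off -> primed -> on) implies that on-episode
durations are exponential with mean T0 while the low episode between a down
switch and the next up switch is the sum of two exponentials (refractory T1
plus off T2), i.e. hypoexponential.  Step-function transcription profiles give
realisations of these durations; episodes cut off by the end of recording are
right-censored and contribute survival terms to the likelihood.

Estimators
----------
- exponential MLE with right-censoring (closed form),
- hypoexponential (two-phase) MLE with right-censoring under the
  identifiability constraint T1 < T2,
- low/high transcription rates as probability-weighted medians of post-switch
  levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import InsufficientDataError, NonIdentifiableError
from .profiles import StepProfile, SwitchProfileSet

__all__ = [
    "DurationData",
    "PeriodEstimates",
    "merge_consecutive_switches",
    "extract_durations",
    "durations_from_profiles",
    "mle_exponential_censored",
    "mle_hypoexponential_censored",
    "hypoexp_logpdf",
    "hypoexp_logsf",
    "estimate_transcription_rates",
]


@dataclass
class DurationData:
    """Complete and right-censored state durations (hours).

    ``kind`` is "on" (post-up-switch) or "down" (post-down-switch, i.e.
    refractory + off).  Optional weights carry candidate-profile occurrence
    probabilities into the likelihood.
    """

    complete: np.ndarray
    censored: np.ndarray
    kind: str = "down"
    weights_complete: np.ndarray | None = None
    weights_censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.complete = np.asarray(self.complete, dtype=float)
        self.censored = np.asarray(self.censored, dtype=float)
        if np.any(self.complete <= 0) or np.any(self.censored <= 0):
            raise ValueError("durations must be positive")
        if self.weights_complete is None:
            self.weights_complete = np.ones_like(self.complete)
        if self.weights_censored is None:
            self.weights_censored = np.ones_like(self.censored)

    @property
    def n_complete(self) -> int:
        return self.complete.size

    @property
    def n_censored(self) -> int:
        return self.censored.size


@dataclass
class PeriodEstimates:
    """Fitted cycle parameters: mean durations (h) and transcription rates (1/h)."""

    T0: float | None = None
    T1: float | None = None
    T2: float | None = None
    beta_L: float | None = None
    beta_H: float | None = None
    loglik: float | None = None
    boundary: bool = False
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# switch-train preprocessing
# ---------------------------------------------------------------------------

def merge_consecutive_switches(profile: StepProfile) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a step profile to an alternating up/down switch train.

    Continuous switch inference often emits several same-direction switches in
    a row; under the discrete on/off/primed model these belong to one episode,
    so a run of same-direction switches collapses to its first switch.
    Zero-level-change switches carry no direction and are dropped first.

    Returns ``(times, signs)`` with signs alternating in {+1, -1}.
    """
    dirs = profile.switch_directions()
    keep = dirs != 0
    times = profile.switch_times[keep]
    signs = dirs[keep]
    if times.size == 0:
        return times, signs
    first = np.ones(times.size, dtype=bool)
    first[1:] = signs[1:] != signs[:-1]
    return times[first], signs[first]


def extract_durations(
    trains: list[tuple[np.ndarray, np.ndarray]],
    horizon: float,
    weights: np.ndarray | None = None,
) -> tuple[DurationData, DurationData]:
    """Split alternating switch trains into on- and down-duration samples.

    An up -> down gap is a complete on-duration; a down -> up gap a complete
    down-duration.  The final open-ended gap of each train is right-censored
    at the horizon.  The segment before the first switch is discarded (its
    starting state is unobserved).

    Returns ``(on_durations, down_durations)``.
    """
    if weights is None:
        weights = np.ones(len(trains))
    on_c, on_x, down_c, down_x = [], [], [], []
    on_wc, on_wx, down_wc, down_wx = [], [], [], []
    for (times, signs), w in zip(trains, weights):
        if times.size == 0:
            warnings.warn("switch train with no switches yields no durations")
            continue
        gaps = np.diff(times)
        for g, s in zip(gaps, signs[:-1]):
            (on_c if s > 0 else down_c).append(g)
            (on_wc if s > 0 else down_wc).append(w)
        tail = horizon - times[-1]
        if tail > 0:
            (on_x if signs[-1] > 0 else down_x).append(tail)
            (on_wx if signs[-1] > 0 else down_wx).append(w)
    return (
        DurationData(np.array(on_c), np.array(on_x), "on",
                     np.array(on_wc), np.array(on_wx)),
        DurationData(np.array(down_c), np.array(down_x), "down",
                     np.array(down_wc), np.array(down_wx)),
    )


def durations_from_profiles(
    profiles: dict[str, SwitchProfileSet], horizon: float
) -> tuple[DurationData, DurationData]:
    """Pool durations across cells and candidates, weighting by occurrence
    probability."""
    trains, weights = [], []
    for pset in profiles.values():
        for cand in pset:
            trains.append(merge_consecutive_switches(cand))
            weights.append(cand.weight)
    return extract_durations(trains, horizon, np.asarray(weights))


# ---------------------------------------------------------------------------
# censored exponential MLE
# ---------------------------------------------------------------------------

def mle_exponential_censored(data: DurationData) -> float:
    """MLE of the exponential mean with right-censoring.

    Maximises sum(log f(t_comp)) + sum(log S(t_cens)); the maximiser is the
    total (weighted) time at risk divided by the (weighted) number of complete
    events.
    """
    if data.n_complete == 0:
        raise NonIdentifiableError("need at least one complete duration")
    wc, wx = data.weights_complete, data.weights_censored
    total = float(wc @ data.complete + (wx @ data.censored if data.n_censored else 0.0))
    return total / float(wc.sum())


# ---------------------------------------------------------------------------
# censored hypoexponential MLE
# ---------------------------------------------------------------------------

_ERLANG_RTOL = 1e-6


def hypoexp_logpdf(t: np.ndarray, lam1: float, lam2: float) -> np.ndarray:
    """log density of the sum of Exp(rate lam1) and Exp(rate lam2).

    f(t) = lam1 lam2 / (lam2 - lam1) * (exp(-lam1 t) - exp(-lam2 t)) for
    lam1 != lam2, continued as the Erlang-2 limit lam^2 t exp(-lam t) when the
    rates coincide.  Evaluated in log space for numerical stability.
    """
    t = np.asarray(t, dtype=float)
    lo, hi = min(lam1, lam2), max(lam1, lam2)
    if hi - lo <= _ERLANG_RTOL * hi:
        lam = 0.5 * (lo + hi)
        return 2.0 * np.log(lam) + np.log(t) - lam * t
    # symmetric in (lam1, lam2); use the ordered pair
    return (
        np.log(lo) + np.log(hi) - np.log(hi - lo)
        - lo * t
        + np.log1p(-np.exp(-(hi - lo) * t))
    )


def hypoexp_logsf(t: np.ndarray, lam1: float, lam2: float) -> np.ndarray:
    """log survival function of the hypoexponential sum.

    S(t) = (lam2 exp(-lam1 t) - lam1 exp(-lam2 t)) / (lam2 - lam1), Erlang-2
    limit (1 + lam t) exp(-lam t).
    """
    t = np.asarray(t, dtype=float)
    lo, hi = min(lam1, lam2), max(lam1, lam2)
    if hi - lo <= _ERLANG_RTOL * hi:
        lam = 0.5 * (lo + hi)
        return np.log1p(lam * t) - lam * t
    return -lo * t + np.log(hi - lo * np.exp(-(hi - lo) * t)) - np.log(hi - lo)


def _hypoexp_negloglik(log_T: np.ndarray, data: DurationData) -> float:
    T1, T2 = np.exp(log_T)
    lam1, lam2 = 1.0 / T1, 1.0 / T2
    ll = float(data.weights_complete @ hypoexp_logpdf(data.complete, lam1, lam2))
    if data.n_censored:
        ll += float(data.weights_censored @ hypoexp_logsf(data.censored, lam1, lam2))
    return -ll


def _moment_starts(data: DurationData) -> list[np.ndarray]:
    """Multi-start points: method-of-moments (when real) plus a coarse grid."""
    m = float(np.average(data.complete, weights=data.weights_complete))
    v = float(
        np.average(
            (data.complete - m) ** 2, weights=data.weights_complete
        )
    )
    starts: list[np.ndarray] = []
    # T1 + T2 = m, T1^2 + T2^2 = v for a hypoexponential sum
    disc = 2.0 * v - m**2
    if disc > 0:
        r = np.sqrt(disc)
        a, b = (m - r) / 2.0, (m + r) / 2.0
        if a > 0:
            starts.append(np.log([a, b]))
    for frac in (0.5, 0.2, 0.1, 0.35):
        starts.append(np.log([max(frac * m, 1e-3), max((1 - frac) * m, 1e-3)]))
    return starts[:5]


def mle_hypoexponential_censored(data: DurationData) -> PeriodEstimates:
    """Joint MLE of the two phase means of censored hypoexponential durations.

    The likelihood is exchange-symmetric in the two rates; the constraint
    T1 < T2 selects one of the two equal maxima after an unconstrained fit in
    log-parameters (5 multi-starts, Nelder-Mead, tol 1e-8).  A fit landing on
    the T1 = T2 diagonal is flagged ``boundary`` and evaluated through the
    Erlang-2 limit.
    """
    if data.n_complete < 10:
        raise InsufficientDataError(
            f"need >= 10 complete durations, got {data.n_complete}"
        )
    best = None
    for x0 in _moment_starts(data):
        res = optimize.minimize(
            _hypoexp_negloglik,
            x0,
            args=(data,),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    T = np.sort(np.exp(best.x))
    boundary = (T[1] - T[0]) <= 1e-3 * T[1]
    return PeriodEstimates(
        T1=float(T[0]),
        T2=float(T[1]),
        loglik=-float(best.fun),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# transcription rates
# ---------------------------------------------------------------------------

def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1], side="left")])


def estimate_transcription_rates(
    profiles: dict[str, SwitchProfileSet]
) -> tuple[float | None, float | None]:
    """Low/high transcription rates from post-switch levels.

    beta_L is the probability-weighted median of levels entered at down
    switches, beta_H of levels entered at up switches.  A side with no
    switches returns None for that rate.
    """
    lo_v, lo_w, hi_v, hi_w = [], [], [], []
    for pset in profiles.values():
        for cand in pset:
            times, signs = merge_consecutive_switches(cand)
            if times.size == 0:
                continue
            # level entered at each kept switch
            idx = np.searchsorted(cand.switch_times, times) + 1
            for lev, s in zip(cand.levels[idx], signs):
                if s > 0:
                    hi_v.append(lev)
                    hi_w.append(cand.weight)
                else:
                    lo_v.append(lev)
                    lo_w.append(cand.weight)
    beta_L = _weighted_median(np.array(lo_v), np.array(lo_w)) if lo_v else None
    beta_H = _weighted_median(np.array(hi_v), np.array(hi_w)) if hi_v else None
    if beta_L is None or beta_H is None:
        warnings.warn("one-sided switch data: returning partial rate estimates")
    return beta_L, beta_H
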