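"""Synthetic inputs with the statistical structure the analysis assumes.

Real lactotroph tissue recordings (centroid tracks with two fluorescence
channels, switch-profile sets, size summaries) are not redistributable, so
every input the pipeline consumes can be generated here: dense 2-D tissue
geometries with Gamma-distributed cell diameters, two-channel reporter tracks
in which the high-sensitivity channel saturates, alternating step-function
transcription profiles with exponential on- and hypoexponential off-durations,
and right-censored duration samples for the likelihood fits.

Defaults emulate the study conditions: ~100 cells in a 90 um square field,
12.0 +/- 2.2 um diameters, 48 h of recording sampled every 15 min.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .estimation import DurationData
from .profiles import StepProfile, SwitchProfileSet

__all__ = [
    "SynthConfig",
    "generate_tissue",
    "bell_profile",
    "generate_two_channel_tracks",
    "generate_switch_profiles",
    "generate_durations",
]


@dataclass(frozen=True)
class SynthConfig:
    """Settings for the synthetic tissue and imaging model.

    Parameters
    ----------
    n_cells:
        Number of cells placed uniformly in the square field.  With
        ``poisson_count=True`` the count is instead drawn as
        Poisson(``n_cells`` / ``field_side``**2 * area), i.e. ``n_cells``
        doubles as the expected count.
    field_side:
        Side of the square field in um.  The default 90 um together with 100
        cells of ~12 um diameter gives the dense packing under which contact
        networks are connected.
    diameter_mean, diameter_sd:
        Mean and standard deviation (um) of the Gamma cell-diameter
        distribution.
    duration_hours, dt_minutes:
        Length and cadence of the recording; dt must divide the duration.
    saturation_level:
        Intensity (a.u.) at which the high-sensitivity channel clips.
    channel_gain, channel_offset:
        Linear response of the low-sensitivity channel:
        ``ch2 = offset + gain * signal (+ noise)``.
    noise_sd:
        Standard deviation of additive Gaussian intensity noise on both
        channels.
    """

    seed: int = 0
    n_cells: int = 100
    field_side: float = 90.0
    diameter_mean: float = 12.0
    diameter_sd: float = 2.2
    duration_hours: float = 48.0
    dt_minutes: float = 15.0
    saturation_level: float = 800.0
    channel_gain: float = 0.2
    channel_offset: float = 50.0
    noise_sd: float = 4.0
    poisson_count: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidConfigError("n_cells must be >= 1")
        if self.field_side <= 0 or self.diameter_mean <= 0 or self.diameter_sd <= 0:
            raise InvalidConfigError("field and diameter settings must be positive")
        if self.duration_hours <= 0 or self.dt_minutes <= 0:
            raise InvalidConfigError("duration and dt must be positive")
        n_steps = self.duration_hours * 60.0 / self.dt_minutes
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise InvalidConfigError("dt_minutes must divide duration_hours evenly")
        if self.saturation_level <= 0:
            raise InvalidConfigError("saturation_level must be positive")
        if self.channel_gain < 0:
            raise InvalidConfigError("channel_gain must be non-negative")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_hours * 60.0 / self.dt_minutes)) + 1

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_minutes / 60.0


def _gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of the Gamma distribution with the given mean and sd."""
    return (mean / sd) ** 2, sd**2 / mean


def generate_tissue(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Place cells uniformly in the square field and draw their diameters.

    Returns
    -------
    centroids : (N, 2) array in um
    diameters : (N,) array in um, i.i.d. Gamma(mean, sd) draws
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_cells
    if config.poisson_count:
        n = max(1, int(rng.poisson(config.n_cells)))
    centroids = rng.uniform(0.0, config.field_side, size=(n, 2))
    shape, scale = _gamma_from_moments(config.diameter_mean, config.diameter_sd)
    diameters = rng.gamma(shape, scale, size=n)
    return centroids, diameters


def bell_profile(
    times_h: np.ndarray,
    amplitude: float = 1.0,
    rise_tau: float = 1.0 / 0.14095,
    decay_tau: float = 12.0,
) -> np.ndarray:
    """Bell-shaped mean signal: near zero at t=0, rises, then decays.

    Difference of exponentials normalised to peak at ``amplitude`` -- the mean
    response of a linear birth-death process whose production rate decays with
    time constant ``decay_tau`` while the product turns over with time constant
    ``rise_tau``.
    """
    t = np.asarray(times_h, dtype=float)
    a, b = 1.0 / decay_tau, 1.0 / rise_tau
    if np.isclose(a, b):
        raw = t * np.exp(-a * t)
    else:
        raw = np.exp(-a * t) - np.exp(-b * t)
    peak = raw.max()
    return amplitude * raw / peak if peak > 0 else np.zeros_like(t)


def generate_two_channel_tracks(
    true_signal: np.ndarray,
    config: SynthConfig,
    centroids: np.ndarray | None = None,
    position_jitter_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Turn per-cell true signals into a two-channel track table.

    Channel 1 (high sensitivity) clips at ``saturation_level``; channel 2
    responds linearly as ``offset + gain * signal``.  Both carry i.i.d.
    Gaussian noise of sd ``noise_sd``.  Cell positions jitter around their true
    centroids frame to frame with sd ``position_jitter_sd`` (um), emulating the
    small movements seen during imaging.

    Parameters
    ----------
    true_signal : (n_frames, n_cells) array of non-negative intensities.

    Returns
    -------
    DataFrame with columns ``cell_id, time_h, x_um, y_um, ch1, ch2``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sig = np.asarray(true_signal, dtype=float)
    if sig.ndim != 2:
        raise InvalidConfigError("true_signal must be 2-D (n_frames, n_cells)")
    if np.any(sig < 0):
        raise InvalidConfigError("true_signal must be non-negative")
    n_frames, n_cells = sig.shape
    if n_frames != config.n_frames:
        raise InvalidConfigError(
            f"true_signal has {n_frames} frames but config implies {config.n_frames}"
        )
    if centroids is None:
        cfg = config if n_cells == config.n_cells else replace(config, n_cells=n_cells)
        centroids, _ = generate_tissue(cfg, rng)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (n_cells, 2):
        raise InvalidConfigError("centroids shape must match true_signal cells")

    noise1 = rng.normal(0.0, config.noise_sd, size=sig.shape) if config.noise_sd else 0.0
    noise2 = rng.normal(0.0, config.noise_sd, size=sig.shape) if config.noise_sd else 0.0
    ch1 = np.minimum(sig, config.saturation_level) + noise1
    ch2 = config.channel_offset + config.channel_gain * sig + noise2

    jitter = (
        rng.normal(0.0, position_jitter_sd, size=(n_frames, n_cells, 2))
        if position_jitter_sd
        else np.zeros((n_frames, n_cells, 2))
    )
    pos = centroids[None, :, :] + jitter

    times = config.times_h
    frame_idx = np.repeat(np.arange(n_frames), n_cells)
    cell_idx = np.tile(np.arange(n_cells), n_frames)
    return pd.DataFrame(
        {
            "cell_id": cell_idx,
            "time_h": times[frame_idx],
            "x_um": pos[frame_idx, cell_idx, 0],
            "y_um": pos[frame_idx, cell_idx, 1],
            "ch1": np.asarray(ch1)[frame_idx, cell_idx],
            "ch2": np.asarray(ch2)[frame_idx, cell_idx],
        }
    )


def _alternating_profile(
    rng: np.random.Generator,
    T0: float,
    T1: float,
    T2: float,
    beta_L: float,
    beta_H: float,
    horizon: float,
) -> StepProfile:
    """One alternating step function: low (hypoexponential T1+T2 duration)
    then high (exponential T0 duration), truncated at the horizon.

    Starts in the low state, matching a tissue whose genes begin off.
    """
    switch_times: list[float] = []
    levels = [beta_L]
    t = 0.0
    high = False
    while True:
        dur = (
            rng.exponential(T0)
            if high
            else rng.exponential(T1) + rng.exponential(T2)
        )
        t += dur
        if t >= horizon:
            break
        high = not high
        switch_times.append(t)
        levels.append(beta_H if high else beta_L)
    return StepProfile(np.array(switch_times), np.array(levels))


def generate_switch_profiles(
    T0: float,
    T1: float,
    T2: float,
    beta_L: float,
    beta_H: float,
    horizon: float,
    n_cells: int,
    n_candidates: int = 5,
    seed: int = 0,
) -> dict[str, SwitchProfileSet]:
    """Per-cell weighted sets of alternating step-function profiles.

    Emulates the output of Bayesian switch inference: each cell gets
    ``n_candidates`` candidate profiles with Dirichlet(1) occurrence weights.
    High (rate ``beta_H``) episodes last Exp(``T0``); low (rate ``beta_L``)
    episodes last Exp(``T1``) + Exp(``T2``) (hypoexponential).
    """
    if T0 <= 0 or T1 <= 0 or T2 <= 0:
        raise InvalidConfigError("state mean durations must be positive")
    if not beta_H > beta_L >= 0:
        raise InvalidConfigError("need beta_H > beta_L >= 0")
    if n_candidates < 1:
        raise InvalidConfigError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, SwitchProfileSet] = {}
    for i in range(n_cells):
        weights = rng.dirichlet(np.ones(n_candidates))
        cands = [
            StepProfile(p.switch_times, p.levels, w)
            for p, w in zip(
                (
                    _alternating_profile(rng, T0, T1, T2, beta_L, beta_H, horizon)
                    for _ in range(n_candidates)
                ),
                weights,
            )
        ]
        out[str(i)] = SwitchProfileSet(cands)
    return out


def generate_durations(
    T1: float,
    T2: float,
    n: int,
    censor_fraction: float = 0.0,
    seed: int = 0,
    kind: str = "down",
) -> DurationData:
    """Draw hypoexponential (T1 + T2) durations with optional right-censoring.

    Censoring is non-informative: every duration V competes with an
    independent exponential censoring time C whose rate is calibrated so that
    P(C < V) = ``censor_fraction``; observations with C < V are recorded as
    censored at C (always smaller than the duration they truncate).  Under
    this mechanism the standard censored likelihood is the correct one, so
    the MLEs recover the generating means.  With ``T2=0`` the draws are plain
    exponential with mean ``T1`` (used for on-durations).
    """
    if not 0 <= censor_fraction < 1:
        raise InvalidConfigError("censor_fraction must be in [0, 1)")
    if T1 <= 0 or T2 < 0:
        raise InvalidConfigError("duration means must be positive (T2 may be 0)")
    rng = np.random.default_rng(seed)
    draws = rng.exponential(T1, size=n)
    if T2 > 0:
        draws = draws + rng.exponential(T2, size=n)
    if censor_fraction == 0:
        return DurationData(complete=draws, censored=np.empty(0), kind=kind)
    rate = _censor_rate(censor_fraction, T1, T2)
    c_times = rng.exponential(1.0 / rate, size=n)
    mask = c_times < draws
    return DurationData(complete=draws[~mask], censored=c_times[mask], kind=kind)


def _censor_rate(p: float, T1: float, T2: float) -> float:
    """Rate of an independent exponential censoring time with P(C < V) = p.

    P(C < V) = 1 - E[exp(-r V)], the complement of the duration's Laplace
    transform at r; closed form for the exponential case, bisection for the
    hypoexponential one.
    """
    lam1 = 1.0 / T1
    if T2 == 0:
        return lam1 * p / (1.0 - p)

    lam2 = 1.0 / T2

    def frac(r: float) -> float:
        return 1.0 - (lam1 / (r + lam1)) * (lam2 / (r + lam2))

    lo, hi = 1e-12, 1.0 / (T1 + T2)
    while frac(hi) < p:
        hi *= 2.0
    from scipy.optimize import brentq

    return float(brentq(lambda r: frac(r) - p, lo, hi, xtol=1e-14))
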