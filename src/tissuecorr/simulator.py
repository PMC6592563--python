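"""Stochastic tissue model: coupled three-state promoter cycles with mRNA.

Each cell carries ``copies`` (default 4) gene copies cycling through
on -> off -> primed -> on with exponential holding times (means T0, T1, T2;
per-copy rates R0 = 1/(4 T0) etc. so the printed per-cell rates are shared
across the four copies).  mRNA is born at rate beta_H per on copy and beta_L
per off/primed copy and degrades at rate mu per molecule.

Contact coupling: a cell senses n(t), the total number of on copies over its
network neighbours, which accelerates its off->primed and primed->on
transitions by a factor (1 + delta * n(t)) and, optionally, its on-state
transcription by (1 + delta_b * n(t)).

Experimental adjustment: recordings start from a quiescent tissue (all copies
off, no mRNA) and show a bell-shaped mean, so both transcription rates are
modulated by alpha * exp(-t / decay_tau) where alpha normalises the modulation
to integrate to the horizon length (alpha = 4 / (1 - e^-4) for 48 h / 12 h).

The time-dependent transcription rate makes the process nonhomogeneous; the
simulation stays exact by drawing each waiting time from
log U + integral_t^{t+tau} r(s) ds = 0, where the total propensity between
events has the closed form c1 + c2 * exp(-s / decay_tau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from . import synthetic
from .network import sample_network
from .signalling import median_regression

__all__ = [
    "SimParams",
    "SimTrajectory",
    "EVENT_TYPES",
    "propensities",
    "next_event_time",
    "simulate",
    "transcription_profile",
    "slope_experiment",
]

EVENT_TYPES = ("on_off", "off_primed", "primed_on", "mrna_birth", "mrna_death")


@dataclass(frozen=True)
class SimParams:
    """Model rates (per hour) and structural settings.

    Defaults are the estimated lactotroph values: on/refractory/off means of
    11.605 / 3.5 / 15.1 h, per-cell transcription rates 0.275 (low) and 4.25
    (high) split across 4 gene copies, degradation 0.14095 /h.
    """

    T0: float = 11.605  # mean on period (h)
    T1: float = 3.5  # mean refractory period (h)
    T2: float = 15.1  # mean off period (h)
    beta_L_cell: float = 0.275  # low transcription rate per cell (all copies)
    beta_H_cell: float = 4.25  # high transcription rate per cell
    mu: float = 0.14095  # mRNA degradation rate per molecule
    delta: float = 0.3  # gene-cycle coupling strength
    delta_b: float = 0.03  # transcription coupling strength (delta / 10)
    copies: int = 4
    horizon: float = 48.0  # h
    decay_tau: float = 12.0  # h, time constant of the experimental decay
    decay_adjustment: bool = True

    def __post_init__(self) -> None:
        if min(self.T0, self.T1, self.T2) <= 0:
            raise InvalidConfigError("state means must be positive")
        if min(self.beta_L_cell, self.beta_H_cell, self.mu) < 0:
            raise InvalidConfigError("rates must be non-negative")
        if self.delta < 0 or self.delta_b < 0:
            raise InvalidConfigError("coupling strengths must be non-negative")
        if self.copies < 1:
            raise InvalidConfigError("copies must be >= 1")

    # per-copy rates: the per-cell values are split across the gene copies
    @property
    def R0(self) -> float:
        return 1.0 / self.T0 / self.copies

    @property
    def R10(self) -> float:
        return 1.0 / self.T1 / self.copies

    @property
    def R20(self) -> float:
        return 1.0 / self.T2 / self.copies

    @property
    def beta_L(self) -> float:
        return self.beta_L_cell / self.copies

    @property
    def beta_H0(self) -> float:
        return self.beta_H_cell / self.copies

    @property
    def alpha_norm(self) -> float:
        """Normaliser of the decay modulation: integral of alpha e^(-t/tau)
        over the horizon equals the horizon."""
        x = self.horizon / self.decay_tau
        return x / (1.0 - np.exp(-x))


@dataclass
class SimTrajectory:
    """Event log and gridded per-cell series of one tissue simulation."""

    event_times: np.ndarray
    event_cells: np.ndarray
    event_types: np.ndarray  # indices into EVENT_TYPES
    grid_times: np.ndarray  # (T,)
    mrna: np.ndarray  # (T, N)
    n_on: np.ndarray  # (T, N)
    n_off: np.ndarray  # (T, N)
    n_primed: np.ndarray  # (T, N)
    params: SimParams
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.mrna.shape[1]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.event_times,
                "cell_id": self.event_cells,
                "event": [EVENT_TYPES[k] for k in self.event_types],
            }
        )


def propensities(
    n_on: np.ndarray,
    n_off: np.ndarray,
    n_primed: np.ndarray,
    mrna: np.ndarray,
    neighbour_on: np.ndarray,
    t: float,
    params: SimParams,
) -> dict[str, np.ndarray]:
    """Per-cell reaction rates at time ``t``.

    ``neighbour_on`` is n(t): the number of on copies summed over each cell's
    network neighbours (the cell itself excluded).  The returned "mrna_birth"
    already includes the decay adjustment when enabled.
    """
    if np.any(n_on < 0) or np.any(n_off < 0) or np.any(n_primed < 0) or np.any(mrna < 0):
        raise InvalidConfigError("negative counts: inconsistent state")
    coupling = 1.0 + params.delta * neighbour_on
    birth_coeff = (
        params.beta_H0 * (1.0 + params.delta_b * neighbour_on) * n_on
        + params.beta_L * (n_off + n_primed)
    )
    if params.decay_adjustment:
        birth = params.alpha_norm * np.exp(-t / params.decay_tau) * birth_coeff
    else:
        birth = birth_coeff
    return {
        "on_off": params.R0 * n_on,
        "off_primed": params.R10 * coupling * n_off,
        "primed_on": params.R20 * coupling * n_primed,
        "mrna_birth": birth,
        "mrna_death": params.mu * mrna,
    }


def next_event_time(
    t: float, u: float, c1: float, c2: float, decay_tau: float
) -> float:
    """Exact waiting time for total rate r(s) = c1 + c2 * exp(-s / decay_tau).

    Solves log(u) + integral_t^{t+tau} r(s) ds = 0 for tau, i.e.
    c1*tau + c2*decay_tau*exp(-t/decay_tau)*(1 - exp(-tau/decay_tau)) = -log u.
    Closed form when either component vanishes; otherwise Newton iteration on
    the concave increasing integral (monotone convergence from below).
    Returns inf when the remaining integral cannot reach -log(u) (no further
    event).
    """
    if not 0.0 < u < 1.0:
        raise InvalidConfigError("u must be in (0, 1)")
    if c1 < 0 or c2 < 0:
        raise InvalidConfigError("rate components must be non-negative")
    target = -np.log(u)
    k = c2 * decay_tau * np.exp(-t / decay_tau)  # bounded mass of the decaying part
    if c1 == 0.0 and k == 0.0:
        return np.inf
    if c2 == 0.0:
        return target / c1
    if c1 == 0.0:
        if target >= k:
            return np.inf
        return -decay_tau * np.log1p(-target / k)
    # Newton: g(tau) = c1 tau + k (1 - exp(-tau/decay_tau)) - target
    tau = target / (c1 + k / decay_tau)  # start at the homogeneous guess
    for _ in range(100):
        e = np.exp(-tau / decay_tau)
        g = c1 * tau + k * (1.0 - e) - target
        dg = c1 + (k / decay_tau) * e
        step = g / dg
        tau -= step
        if abs(step) < 1e-13 * max(1.0, tau):
            return tau
    return tau


def simulate(
    params: SimParams,
    adjacency: np.ndarray,
    seed: int = 0,
    grid_dt_minutes: float = 15.0,
) -> SimTrajectory:
    """Exact event-driven simulation of the coupled tissue to the horizon.

    All cells start quiescent (#on = 0, #off = copies, #primed = 0,
    #mRNA = 0).  Coupling factors are re-evaluated after every event (they are
    piecewise constant between events, so this is exact).

    ``adjacency`` is the boolean contact matrix from the network module.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    n = adjacency.shape[0]
    if adjacency.shape != (n, n):
        raise InvalidConfigError("adjacency must be square")
    adj_f = adjacency.astype(np.float64)
    rng = np.random.default_rng(seed)

    n_on = np.zeros(n, dtype=np.int64)
    n_off = np.full(n, params.copies, dtype=np.int64)
    n_primed = np.zeros(n, dtype=np.int64)
    mrna = np.zeros(n, dtype=np.int64)
    neighbour_on = np.zeros(n, dtype=np.float64)
    neighbours = [np.flatnonzero(adjacency[i]) for i in range(n)]

    times, cells, types = [], [], []
    t = 0.0
    alpha = params.alpha_norm
    while True:
        coupling = 1.0 + params.delta * neighbour_on
        a_off = params.R0 * n_on
        a_primed = params.R10 * coupling * n_off
        a_on = params.R20 * coupling * n_primed
        death = params.mu * mrna
        birth_coeff = (
            params.beta_H0 * (1.0 + params.delta_b * neighbour_on) * n_on
            + params.beta_L * (n_off + n_primed)
        )
        c1 = a_off.sum() + a_primed.sum() + a_on.sum() + death.sum()
        if params.decay_adjustment:
            c2 = alpha * birth_coeff.sum()
        else:
            c1 += birth_coeff.sum()
            c2 = 0.0
        if c1 == 0.0 and c2 == 0.0:
            break
        tau = next_event_time(t, rng.random(), c1, c2, params.decay_tau)
        t_new = t + tau
        if not np.isfinite(t_new) or t_new > params.horizon:
            break
        # reaction selection uses the instantaneous rates at the event time
        if params.decay_adjustment:
            birth = alpha * np.exp(-t_new / params.decay_tau) * birth_coeff
        else:
            birth = birth_coeff
        rates = np.concatenate((a_off, a_primed, a_on, birth, death))
        cum = np.cumsum(rates)
        pick = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        typ, cell = divmod(pick, n)
        if typ == 0:
            n_on[cell] -= 1
            n_off[cell] += 1
            neighbour_on[neighbours[cell]] -= 1.0
        elif typ == 1:
            n_off[cell] -= 1
            n_primed[cell] += 1
        elif typ == 2:
            n_primed[cell] -= 1
            n_on[cell] += 1
            neighbour_on[neighbours[cell]] += 1.0
        elif typ == 3:
            mrna[cell] += 1
        else:
            mrna[cell] -= 1
        t = t_new
        times.append(t)
        cells.append(cell)
        types.append(typ)

    event_times = np.asarray(times)
    event_cells = np.asarray(cells, dtype=np.int64)
    event_types = np.asarray(types, dtype=np.int64)

    grid = np.arange(0.0, params.horizon + 1e-9, grid_dt_minutes / 60.0)
    series = _grid_series(event_times, event_cells, event_types, grid, n, params.copies)
    return SimTrajectory(
        event_times=event_times,
        event_cells=event_cells,
        event_types=event_types,
        grid_times=grid,
        mrna=series["mrna"],
        n_on=series["n_on"],
        n_off=series["n_off"],
        n_primed=series["n_primed"],
        params=params,
        seed=seed,
    )


def _grid_series(
    event_times: np.ndarray,
    event_cells: np.ndarray,
    event_types: np.ndarray,
    grid: np.ndarray,
    n_cells: int,
    copies: int,
) -> dict[str, np.ndarray]:
    """Reconstruct per-cell counts on a time grid from the event log."""
    T = grid.size
    deltas = {
        "mrna": np.zeros((T, n_cells), dtype=np.int64),
        "n_on": np.zeros((T, n_cells), dtype=np.int64),
        "n_off": np.zeros((T, n_cells), dtype=np.int64),
        "n_primed": np.zeros((T, n_cells), dtype=np.int64),
    }
    if event_times.size:
        idx = np.searchsorted(grid, event_times, side="left")
        keep = idx < T
        idx, cells, types = idx[keep], event_cells[keep], event_types[keep]
        for typ, changes in (
            (0, (("n_on", -1), ("n_off", 1))),
            (1, (("n_off", -1), ("n_primed", 1))),
            (2, (("n_primed", -1), ("n_on", 1))),
            (3, (("mrna", 1),)),
            (4, (("mrna", -1),)),
        ):
            m = types == typ
            for name, d in changes:
                np.add.at(deltas[name], (idx[m], cells[m]), d)
    out = {name: np.cumsum(arr, axis=0) for name, arr in deltas.items()}
    out["n_off"] += copies  # initial condition: all copies off
    return out


def transcription_profile(traj: SimTrajectory, params: SimParams | None = None) -> np.ndarray:
    """Instantaneous transcription rate beta(t) per cell on the grid.

    beta(t) = beta_H * N(t) + beta_L * (F(t) + P(t)) with the base per-copy
    rates: neither the coupling factor nor the experimental decay modulation
    enters this read-out, which is the quantity the correlation analysis of
    inferred profiles sees.
    """
    params = traj.params if params is None else params
    return params.beta_H0 * traj.n_on + params.beta_L * (traj.n_off + traj.n_primed)


def slope_experiment(
    params: SimParams,
    n_reps: int = 200,
    seed: int = 0,
    config: synthetic.SynthConfig | None = None,
    short_range_diameters: float = 2.0,
    tau: float = 0.5,
) -> pd.DataFrame:
    """Distribution of correlation-vs-distance slopes over repeated tissues.

    Per replicate: draw a fresh tissue (positions and diameters), build the
    contact network, simulate, compute pairwise Pearson correlations of the
    mRNA and of the transcription-rate series, and fit the median-regression
    slope of correlation against normalised Euclidean distance -- over all
    pairs and restricted to short range (d_e < ``short_range_diameters``).

    Replicate ``k`` uses seed ``seed + k`` for both the tissue and the
    simulation stream.

    Returns a tidy frame with columns ``rep, level, range, slope``
    (level in {"mrna", "beta"}, range in {"all", "short"}).
    """
    config = synthetic.SynthConfig() if config is None else config
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        centroids, diameters = synthetic.generate_tissue(config, rng)
        adjacency = sample_network(centroids, diameters)
        traj = simulate(params, adjacency, seed=seed + rep,
                        grid_dt_minutes=config.dt_minutes)
        diff = centroids[:, None, :] - centroids[None, :, :]
        d_e = np.sqrt((diff**2).sum(-1)) / config.diameter_mean
        iu = np.triu_indices(centroids.shape[0], k=1)
        for level, series in (
            ("mrna", traj.mrna),
            ("beta", transcription_profile(traj, params)),
        ):
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(series.T)
            r = corr[iu]
            d = d_e[iu]
            ok = np.isfinite(r)
            for rng_name, mask in (
                ("all", ok),
                ("short", ok & (d < short_range_diameters)),
            ):
                slope, _ = median_regression(d[mask], r[mask], tau)
                rows.append(
                    {"rep": rep, "level": level, "range": rng_name, "slope": slope}
                )
    return pd.DataFrame(rows)
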