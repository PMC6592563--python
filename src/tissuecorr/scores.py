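"""Pairwise similarity scores and the pair table.

Three ways to score how alike two cells' transcriptional histories are:

- Pearson correlation of their (reconstructed) signal time series at zero lag;
- Sc1: the expected Pearson correlation between candidate step-function
  transcription profiles, averaging over both cells' candidate distributions
  (sensitive to transcription *levels* over time);
- Sc2: Pearson correlation between signed switch trains, where every switch is
  replaced by a Gaussian bump (sd 3 h) signed + for an up-switch and - for a
  down-switch (sensitive to switch *timing*, not levels).

The pair table collects, for every unordered cell pair, the score r together
with the normalised Euclidean distance d_e and the median geodesic distance
d_g -- the three coordinates on which the signalling tests operate.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidConfigError
from .geometry import EuclideanMatrix
from .network import GeodesicMatrix
from .profiles import StepProfile, SwitchProfileSet

__all__ = ["pearson", "sc1", "sc2", "switch_train", "build_pair_table", "optimal_lag"]

logger = logging.getLogger(__name__)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag Pearson correlation coefficient.

    r = sum((x - xbar)(y - ybar)) / sqrt(sum((x - xbar)^2) sum((y - ybar)^2)).

    Returns NaN for a constant series (undefined correlation); callers flag
    such pairs and exclude them downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidConfigError("series must be 1-D and of equal length")
    if x.size < 3:
        raise InvalidConfigError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float((xc @ yc) / denom)


def _weighted_pair_score(
    a: SwitchProfileSet,
    b: SwitchProfileSet,
    repr_a: list[np.ndarray],
    repr_b: list[np.ndarray],
) -> float:
    """Expected Pearson over the product of the two candidate distributions.

    Terms where either representation is constant (undefined r) are skipped
    and the remaining weights renormalised.
    """
    total, weight_sum, skipped = 0.0, 0.0, 0
    for (ca, ra), (cb, rb) in itertools.product(
        zip(a.candidates, repr_a), zip(b.candidates, repr_b)
    ):
        r = pearson(ra, rb)
        w = ca.weight * cb.weight
        if np.isnan(r):
            skipped += 1
            continue
        total += w * r
        weight_sum += w
    if skipped:
        logger.info("skipped %d degenerate candidate pairs", skipped)
    if weight_sum == 0.0:
        return float("nan")
    return total / weight_sum


def sc1(a: SwitchProfileSet, b: SwitchProfileSet, grid_dt: float = 0.25,
        horizon: float | None = None, aggregation: str = "expected_r") -> float:
    """Level score: probability-weighted Pearson r of candidate profiles.

    Profiles are sampled right-continuously on a grid of spacing ``grid_dt``
    hours over the common horizon (defaults to the latest switch time across
    both sets, or ``grid_dt`` if neither set switches).

    Two defensible aggregations over the candidate distributions exist and
    both are provided; they coincide (and reduce to plain Pearson) when each
    cell has a single candidate:

    - ``"expected_r"`` (default): the expected pairwise correlation under the
      product of the two candidate distributions -- preserves per-candidate
      correlation structure;
    - ``"r_of_mean"``: the correlation of the probability-weighted mean
      profiles.
    """
    if grid_dt <= 0:
        raise InvalidConfigError("grid_dt must be positive")
    if horizon is None:
        latest = [c.switch_times[-1] for c in [*a, *b] if c.switch_times.size]
        horizon = max(latest) + grid_dt if latest else grid_dt
    grid = _grid(horizon, grid_dt)
    if aggregation == "expected_r":
        return _weighted_pair_score(
            a, b, [c.sample(grid) for c in a], [c.sample(grid) for c in b]
        )
    if aggregation == "r_of_mean":
        mean_a = sum(c.weight * c.sample(grid) for c in a)
        mean_b = sum(c.weight * c.sample(grid) for c in b)
        return pearson(mean_a, mean_b)
    raise InvalidConfigError(f"unknown aggregation {aggregation!r}")


def _grid(horizon: float, grid_dt: float) -> np.ndarray:
    grid = np.arange(0.0, horizon + 0.5 * grid_dt, grid_dt)
    if grid.size < 3:  # Pearson needs at least 3 points
        grid = np.arange(3) * grid_dt
    return grid


def switch_train(profile: StepProfile, grid: np.ndarray, sd: float = 3.0) -> np.ndarray:
    """Signed Gaussian switch-train representation of a step profile.

    Every switch contributes a Gaussian density bump of sd ``sd`` hours
    centred at the switch time, signed by the direction of the level change
    (+ up, - down).  Equal amplitudes throughout: only timing and direction
    matter.  A profile without switches maps to the zero train.
    """
    if sd <= 0:
        raise InvalidConfigError("sd must be positive")
    train = np.zeros_like(np.asarray(grid, dtype=float))
    for t_k, s_k in zip(profile.switch_times, profile.switch_directions()):
        if s_k != 0:
            train += s_k * norm.pdf(grid, loc=t_k, scale=sd)
    return train


def sc2(a: SwitchProfileSet, b: SwitchProfileSet, sd: float = 3.0,
        grid_dt: float = 0.25, horizon: float | None = None) -> float:
    """Timing score: expected Pearson r of signed switch trains.

    Same candidate weighting as :func:`sc1`.  Pairs whose candidates all have
    zero trains (no switches) are undefined and return NaN.
    """
    if horizon is None:
        latest = [c.switch_times[-1] for c in [*a, *b] if c.switch_times.size]
        horizon = (max(latest) + 4 * sd) if latest else grid_dt
    grid = _grid(horizon, grid_dt)
    return _weighted_pair_score(
        a, b,
        [switch_train(c, grid, sd) for c in a],
        [switch_train(c, grid, sd) for c in b],
    )


def build_pair_table(
    data: dict[object, np.ndarray] | dict[object, SwitchProfileSet],
    d_e: EuclideanMatrix,
    d_g: GeodesicMatrix | None = None,
    score: str = "pearson",
    grid_dt: float = 0.25,
    sc2_sd: float = 3.0,
) -> pd.DataFrame:
    """Assemble the (cell_i, cell_j, r, d_e, d_g) table over all unordered pairs.

    ``data`` maps cell id -> time series (score="pearson") or cell id ->
    :class:`SwitchProfileSet` (score="sc1"/"sc2"); its keys must match the
    cell ids of the distance matrices.  Degenerate scores are NaN; pairs in
    components disconnected in the median network carry ``d_g`` = inf.
    """
    ids = list(d_e.cell_ids)
    if set(map(str, data.keys())) != set(map(str, ids)):
        raise InvalidConfigError("cell ids of data and distance matrix differ")
    by_str = {str(k): v for k, v in data.items()}
    n = len(ids)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = by_str[str(ids[i])], by_str[str(ids[j])]
            if score == "pearson":
                r = pearson(a, b)
            elif score == "sc1":
                r = sc1(a, b, grid_dt=grid_dt)
            elif score == "sc2":
                r = sc2(a, b, sd=sc2_sd, grid_dt=grid_dt)
            else:
                raise InvalidConfigError(f"unknown score {score!r}")
            rows.append(
                {
                    "cell_i": ids[i],
                    "cell_j": ids[j],
                    "r": r,
                    "d_e": d_e.values[i, j],
                    "d_g": d_g.values[i, j] if d_g is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def optimal_lag(x: np.ndarray, y: np.ndarray, max_lag: int = 12) -> tuple[int, float]:
    """Diagnostic: integer-frame lag maximising Pearson r between two series.

    Positive lag means ``y`` trails ``x``.  The signalling analysis itself
    uses zero lag; this helper only checks that assumption on real pairs.
    """
    best = (0, -np.inf)
    n = len(x)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xs, ys = x[: n - lag or None], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        if len(xs) < 3:
            continue
        r = pearson(xs, ys)
        if not np.isnan(r) and r > best[1]:
            best = (lag, r)
    return best
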