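"""Distance-conditioned median regression tests for signalling mode.

Contact-mediated (juxtacrine) signalling propagates along chains of touching
cells, so among pairs at a similar physical separation the correlation should
fall with the number of contacts (geodesic distance d_g).  Diffusion-mediated
(paracrine) signalling depends on physical separation, so among pairs with the
same d_g the correlation should fall with Euclidean distance d_e.  Each test
is a median (quantile tau=0.5) regression of the pair score r on the relevant
distance inside a conditioning window, with a one-sided test of a negative
slope; the median line is robust to the non-normality that comes from r being
bounded in [-1, 1].

The slope's standard error comes from a bootstrap (resampling pairs with
replacement by default; a cell-level resampling option acknowledges that
pairs sharing a cell are dependent), and the one-sided p-value from a
Student-t reference with n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .errors import DegenerateDesignError, InsufficientDataError, InvalidConfigError

__all__ = [
    "RegressionResult",
    "TestSpec",
    "median_regression",
    "bootstrap_slope_test",
    "run_test",
    "pool_datasets",
    "JUXTACRINE_DE_WINDOWS",
    "PARACRINE_DG_WINDOWS",
]

logger = logging.getLogger(__name__)

# Default conditioning windows, in cell-diameter units for d_e and contact
# counts for d_g.  The juxtacrine windows keep d_e small; the overlapping
# paracrine windows {2,3} and {3,4} hedge against overestimated d_g.
JUXTACRINE_DE_WINDOWS: tuple[tuple[float, float], ...] = (
    (0.0, 1.5),
    (1.5, 2.5),
    (2.5, 3.5),
)
PARACRINE_DG_WINDOWS: tuple[tuple[int, ...], ...] = ((2, 3), (3, 4))

MIN_PAIRS = 10


@dataclass
class RegressionResult:
    """Median-regression slope with its bootstrap test."""

    tau: float
    slope: float
    intercept: float
    n_pairs: int
    p_one_sided: float  # H1: slope < 0; NaN when the subset was too small
    n_boot: int
    seed: int
    se: float = float("nan")
    n_excluded_infinite: int = 0
    mode: str = ""
    window: tuple = ()


@dataclass(frozen=True)
class TestSpec:
    """Which signalling mode to test and the conditioning window.

    mode "juxtacrine": regress r on d_g among pairs with d_e in ``window``
    (an interval (lo, hi]).  mode "paracrine": regress r on d_e among pairs
    with d_g in ``window`` (a set of contact counts > 1).  mode "contact":
    r on d_e among touching pairs (d_g == 1).  mode "network_free": r on d_e
    over all pairs.
    """

    mode: str
    window: tuple = ()

    __test__ = False  # not a test class despite the name

    def __post_init__(self) -> None:
        if self.mode not in {"juxtacrine", "paracrine", "contact", "network_free"}:
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.mode in {"juxtacrine", "paracrine"} and len(self.window) == 0:
            raise InvalidConfigError(f"mode {self.mode!r} needs a window")


def median_regression(
    x: np.ndarray, y: np.ndarray, tau: float = 0.5
) -> tuple[float, float]:
    """Quantile regression of y on x; returns (slope, intercept).

    Minimises the asymmetric absolute loss rho_tau(y - a - b x); tau=0.5 gives
    the conditional-median line.
    """
    if not 0 < tau < 1:
        raise InvalidConfigError("tau must be in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < MIN_PAIRS:
        raise InsufficientDataError(f"need >= {MIN_PAIRS} pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all x values equal: slope undefined")
    design = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IterationLimitWarning)
        fit = sm.QuantReg(y, design).fit(q=tau, max_iter=2000)
    return float(fit.params[1]), float(fit.params[0])


def _clean_subset(pairs: pd.DataFrame, x_var: str) -> tuple[pd.DataFrame, int]:
    """Drop NaN scores and infinite distances; report how many inf were cut."""
    sub = pairs.dropna(subset=["r", x_var])
    n_inf = int(np.isinf(sub[x_var]).sum())
    if n_inf:
        logger.info("excluding %d pairs with infinite %s", n_inf, x_var)
    return sub[np.isfinite(sub[x_var])], n_inf


def bootstrap_slope_test(
    pairs: pd.DataFrame,
    x_var: str = "d_e",
    n_boot: int = 999,
    seed: int = 0,
    tau: float = 0.5,
    resample: str = "pairs",
) -> RegressionResult:
    """Median-regression slope with a one-sided bootstrap t-test (H1: slope < 0).

    The bootstrap standard error is the sd of the slope over ``n_boot``
    resamples; the t statistic slope/SE is referred to Student-t with n-2 df.
    ``resample="cells"`` resamples cells and keeps pairs whose both endpoints
    survive, a block bootstrap respecting within-cell dependence.

    A subset below the minimum size returns a result with ``p_one_sided`` NaN
    rather than raising.
    """
    sub, n_inf = _clean_subset(pairs, x_var)
    n = len(sub)
    if n < MIN_PAIRS or np.ptp(sub[x_var].to_numpy()) == 0:
        logger.warning("subset of %d usable pairs is insufficient for the test", n)
        return RegressionResult(
            tau=tau, slope=float("nan"), intercept=float("nan"), n_pairs=n,
            p_one_sided=float("nan"), n_boot=n_boot, seed=seed,
            n_excluded_infinite=n_inf,
        )
    x = sub[x_var].to_numpy()
    y = sub["r"].to_numpy()
    slope, intercept = median_regression(x, y, tau)

    rng = np.random.default_rng(seed)
    boot_slopes = []
    cells = None
    if resample == "cells":
        cells = np.unique(np.concatenate([sub["cell_i"].unique(), sub["cell_j"].unique()]))
    for _ in range(n_boot):
        if resample == "pairs":
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
        elif resample == "cells":
            chosen = set(rng.choice(cells, size=cells.size, replace=True).tolist())
            m = sub["cell_i"].isin(chosen) & sub["cell_j"].isin(chosen)
            xb, yb = x[m.to_numpy()], y[m.to_numpy()]
        else:
            raise InvalidConfigError(f"unknown resample scheme {resample!r}")
        if xb.size < MIN_PAIRS or np.ptp(xb) == 0:
            continue
        try:
            b, _ = median_regression(xb, yb, tau)
        except (DegenerateDesignError, InsufficientDataError):
            continue
        boot_slopes.append(b)
    if len(boot_slopes) < 2:
        se, p = float("nan"), float("nan")
    else:
        se = float(np.std(boot_slopes, ddof=1))
        if se == 0.0:
            p = 0.0 if slope < 0 else 1.0
        else:
            t_stat = slope / se
            p = float(stats.t.cdf(t_stat, df=n - 2))
    return RegressionResult(
        tau=tau, slope=slope, intercept=intercept, n_pairs=n,
        p_one_sided=p, n_boot=n_boot, seed=seed, se=se,
        n_excluded_infinite=n_inf,
    )


def _apply_window(pairs: pd.DataFrame, spec: TestSpec) -> tuple[pd.DataFrame, str]:
    """Select the conditioning subset and the regressor for a test spec."""
    if spec.mode == "juxtacrine":
        lo, hi = spec.window
        sub = pairs[(pairs["d_e"] > lo) & (pairs["d_e"] <= hi)]
        return sub, "d_g"
    if spec.mode == "paracrine":
        sub = pairs[pairs["d_g"].isin(spec.window)]
        return sub, "d_e"
    if spec.mode == "contact":
        return pairs[pairs["d_g"] == 1], "d_e"
    return pairs, "d_e"  # network_free


def run_test(
    pairs: pd.DataFrame,
    spec: TestSpec,
    n_boot: int = 999,
    seed: int = 0,
    tau: float = 0.5,
    resample: str = "pairs",
) -> RegressionResult:
    """Run one signalling test on a pair table (see :class:`TestSpec`)."""
    sub, x_var = _apply_window(pairs, spec)
    res = bootstrap_slope_test(sub, x_var=x_var, n_boot=n_boot, seed=seed,
                               tau=tau, resample=resample)
    res.mode = spec.mode
    res.window = tuple(spec.window)
    return res


def pool_datasets(
    tables: list[pd.DataFrame],
    spec: TestSpec,
    n_boot: int = 999,
    seed: int = 0,
    tau: float = 0.5,
    resample: str = "pairs",
) -> RegressionResult:
    """Concatenate the conditioning subsets of several datasets, then test.

    Pooling raises power when each dataset's subset is small; empty member
    tables are skipped with a warning.
    """
    if len(tables) < 2:
        raise InvalidConfigError("pooling needs at least 2 tables")
    subsets = []
    for k, tbl in enumerate(tables):
        if tbl is None or len(tbl) == 0:
            warnings.warn(f"dataset {k} is empty; skipped in pooling")
            continue
        sub, x_var = _apply_window(tbl, spec)
        subsets.append(sub)
    pooled = pd.concat(subsets, ignore_index=True)
    res = bootstrap_slope_test(pooled, x_var=x_var, n_boot=n_boot, seed=seed,
                               tau=tau, resample=resample)
    res.mode = spec.mode
    res.window = tuple(spec.window)
    return res
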