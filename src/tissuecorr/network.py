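"""Cell-contact networks and geodesic (contact-count) distances.

Only centroids are observed, not outlines, so the contact network is not known
exactly.  It is sampled: cells are modelled as circles whose diameters are
drawn from the tissue's Gamma size distribution, two cells are in contact when
their circles overlap (centroid distance <= sum of radii, tangency included),
and the geodesic distance between two cells is the smallest number of contacts
on a path between them (infinite when disconnected).  Resampling the diameters
many times (999 by default, odd so the median is itself a sample value) and
taking the per-pair median integrates out the unknown sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import InvalidConfigError

__all__ = [
    "SizeDistribution",
    "GeodesicMatrix",
    "sample_network",
    "geodesic_from_adjacency",
    "median_geodesic",
]

_UNREACHABLE = 255  # uint8 sentinel for "no path" while stacking samples


@dataclass(frozen=True)
class SizeDistribution:
    """Gamma cell-diameter distribution given by its mean and sd (um)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise InvalidConfigError("size distribution needs positive mean and sd")

    @property
    def shape(self) -> float:
        return (self.mean / self.sd) ** 2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=n)


@dataclass(frozen=True)
class GeodesicMatrix:
    """Per-pair median geodesic distance over sampled contact networks."""

    values: np.ndarray  # (N, N) float; np.inf where the median sample is disconnected
    n_samples: int
    frac_disconnected: np.ndarray  # (N, N) share of samples with no path


def sample_network(centroids: np.ndarray, diameters: np.ndarray) -> np.ndarray:
    """Contact adjacency for circular cells of the given diameters.

    Edge iff centroid distance <= (d_i + d_j) / 2; the tangent case counts as
    contact.  Returns a symmetric boolean matrix with a False diagonal.
    """
    centroids = np.asarray(centroids, dtype=float)
    diameters = np.asarray(diameters, dtype=float)
    if diameters.shape[0] != centroids.shape[0]:
        raise InvalidConfigError("need one diameter per centroid")
    if np.any(diameters < 0):
        raise InvalidConfigError("diameters must be non-negative")
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    radii_sum = 0.5 * (diameters[:, None] + diameters[None, :])
    adj = dist <= radii_sum
    np.fill_diagonal(adj, False)
    return adj


def geodesic_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Unweighted shortest-path lengths; np.inf for disconnected pairs."""
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise InvalidConfigError("adjacency must be square")
    graph = csr_matrix(adjacency.astype(np.float64))
    return shortest_path(graph, method="D", directed=False, unweighted=True)


def median_geodesic(
    centroids: np.ndarray,
    dist: SizeDistribution,
    n_samples: int = 999,
    seed: int = 0,
) -> GeodesicMatrix:
    """Median geodesic distance over contact networks with resampled diameters.

    Sample ``s`` uses RNG seed ``seed + s`` so individual samples are
    reproducible in isolation.  ``n_samples`` must be odd: the median of an
    odd number of extended integers is itself one of the samples, so entries
    are integers or infinity, never interpolated halves.
    """
    if n_samples % 2 == 0:
        raise InvalidConfigError("n_samples must be odd for a well-defined median")
    centroids = np.asarray(centroids, dtype=float)
    n = centroids.shape[0]
    stack = np.empty((n_samples, n, n), dtype=np.uint8)
    for s in range(n_samples):
        rng = np.random.default_rng(seed + s)
        adj = sample_network(centroids, dist.rvs(n, rng))
        sp = geodesic_from_adjacency(adj)
        sp[~np.isfinite(sp)] = _UNREACHABLE
        np.clip(sp, 0, _UNREACHABLE, out=sp)
        stack[s] = sp.astype(np.uint8)
    med = np.median(stack, axis=0)
    values = np.where(med >= _UNREACHABLE, np.inf, med)
    frac_disc = (stack == _UNREACHABLE).mean(axis=0)
    return GeodesicMatrix(values=values, n_samples=n_samples, frac_disconnected=frac_disc)
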