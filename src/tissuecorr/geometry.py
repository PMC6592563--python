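"""Tissue geometry: centroids, convex-hull size bounds, Euclidean distances.

Cells move slightly during imaging, so a cell's position is the frame-wise
median of its tracked coordinates and a pair's separation is the median over
frames of the instantaneous centroid distance.  Euclidean distances are
reported dimensionless, normalised by a reference cell diameter, so they are
directly comparable with geodesic (contact-count) distances.

The convex hull of the centroids bounds the average cell area: with N cells of
which N_ch sit on the hull of area A_ch, the average cell area lies between
A_ch/N and A_ch/(N - N_ch), giving diameter bounds sqrt(A_ch/N) and
sqrt(A_ch/(N - N_ch)) under the model of a circle inscribed in the square of
average area.  That inscribed-circle model implies cells cover pi/4 ~ 79% of
the tissue area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .errors import DegenerateHullError, InvalidConfigError

__all__ = [
    "TissueGeometry",
    "EuclideanMatrix",
    "inscribed_circle_coverage",
    "centroids_from_tracks",
    "geometry_from_centroids",
    "cell_size_bounds",
    "euclidean_matrix",
    "pairwise_distance_sd",
]


@dataclass(frozen=True)
class TissueGeometry:
    """Centroid cloud with its convex hull summary."""

    centroids: np.ndarray  # (N, 2) um
    hull_area: float  # A_ch, um^2
    n_cells: int  # N
    n_hull: int  # N_ch


@dataclass(frozen=True)
class EuclideanMatrix:
    """Symmetric matrix of dimensionless pairwise distances."""

    values: np.ndarray  # (N, N), normalised by reference_diameter
    reference_diameter: float  # um
    cell_ids: np.ndarray


def inscribed_circle_coverage() -> float:
    """Area fraction covered by a circle inscribed in its bounding square.

    This is the packing fraction implied by the average-cell model behind
    :func:`cell_size_bounds`: pi r^2 / (2r)^2 = pi/4.
    """
    radius = 0.5
    return float(np.pi * radius**2 / (2.0 * radius) ** 2)


def centroids_from_tracks(
    tracks: pd.DataFrame, expected_ids: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell coordinate-wise median position over the time course.

    Returns ``(cell_ids, centroids)`` with centroids in track units (um).
    If ``expected_ids`` is given, every listed cell must appear in the tracks.
    """
    med = tracks.groupby("cell_id")[["x_um", "y_um"]].median()
    if expected_ids is not None:
        missing = set(np.asarray(expected_ids).tolist()) - set(med.index.tolist())
        if missing:
            raise InvalidConfigError(f"tracks missing cell(s): {sorted(missing)}")
    return med.index.to_numpy(), med.to_numpy()


def geometry_from_centroids(centroids: np.ndarray) -> TissueGeometry:
    """Convex hull of the centroid cloud (N >= 3 non-collinear points)."""
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[0] < 3:
        raise DegenerateHullError("convex hull needs at least 3 cells")
    hull = ConvexHull(centroids)
    return TissueGeometry(
        centroids=centroids,
        hull_area=float(hull.volume),  # 2-D ConvexHull: .volume is the area
        n_cells=centroids.shape[0],
        n_hull=len(hull.vertices),
    )


def cell_size_bounds(geom: TissueGeometry) -> tuple[float, float]:
    """Lower/upper bounds on the average cell diameter, in um.

    sqrt(A_ch / N) and sqrt(A_ch / (N - N_ch)): hull cells straddle the hull
    boundary, so the average cell area lies between the hull area shared over
    all cells and over interior cells only.
    """
    if geom.n_cells <= geom.n_hull:
        raise DegenerateHullError(
            f"N={geom.n_cells} <= N_ch={geom.n_hull}: upper bound undefined"
        )
    lower = float(np.sqrt(geom.hull_area / geom.n_cells))
    upper = float(np.sqrt(geom.hull_area / (geom.n_cells - geom.n_hull)))
    return lower, upper


def _position_cube(tracks: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pivot tracks to (n_frames, n_cells) x/y arrays on the union time grid."""
    x = tracks.pivot_table(index="time_h", columns="cell_id", values="x_um")
    y = tracks.pivot_table(index="time_h", columns="cell_id", values="y_um")
    return x.columns.to_numpy(), x.to_numpy(), y.to_numpy()


def euclidean_matrix(
    tracks: pd.DataFrame, reference_diameter: float
) -> EuclideanMatrix:
    """Pairwise median-over-frames centroid distance, in cell-diameter units.

    Frames where either cell of a pair is missing are dropped for that pair
    before taking the median; pairs with no shared frames are an error.
    """
    if reference_diameter <= 0:
        raise InvalidConfigError("reference_diameter must be positive")
    ids, x, y = _position_cube(tracks)
    if ids.size < 2:
        raise InvalidConfigError("need at least 2 cells")
    dx = x[:, :, None] - x[:, None, :]
    dy = y[:, :, None] - y[:, None, :]
    dist = np.sqrt(dx**2 + dy**2)  # (T, N, N), NaN where a frame is missing
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(dist, axis=0)
    off_diag = ~np.eye(ids.size, dtype=bool)
    if np.any(np.isnan(med[off_diag])):
        bad = np.argwhere(np.isnan(med) & off_diag)
        i, j = bad[0]
        raise InvalidConfigError(
            f"cells {ids[i]} and {ids[j]} share no frames: disjoint time grids"
        )
    np.fill_diagonal(med, 0.0)
    return EuclideanMatrix(
        values=med / reference_diameter,
        reference_diameter=float(reference_diameter),
        cell_ids=ids,
    )


def pairwise_distance_sd(tracks: pd.DataFrame) -> np.ndarray:
    """Temporal sd of each pair's instantaneous distance (um), for QC.

    Small values confirm that cells barely move relative to one another and
    that a single median distance per pair is a faithful summary.
    """
    _, x, y = _position_cube(tracks)
    dx = x[:, :, None] - x[:, None, :]
    dy = y[:, :, None] - y[:, None, :]
    dist = np.sqrt(dx**2 + dy**2)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(dist, axis=0)
    np.fill_diagonal(sd, 0.0)
    return sd
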