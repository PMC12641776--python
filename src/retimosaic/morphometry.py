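"""Masked Voronoi tessellation and per-cell morphometry.

Each detected centroid is assigned the planar Voronoi region of the full
centroid set, clipped to the image rectangle.  The clipped region is the
morphometric proxy for the biological cell: its area (µm²), perimeter (µm)
and the number of Voronoi neighbours sharing an edge of positive length are
recorded per cell.

Clipping is performed exactly by augmenting the centroid set with its mirror
reflections across the four image edges before tessellating: inside the
image rectangle a reflected point can never be closer than its source point,
while the reflection of a point across an edge places a Voronoi boundary
exactly on that edge.  The Voronoi regions of the original points in the
augmented diagram are therefore bounded, tile the rectangle exactly, and
coincide with the rectangle-clipped regions of the plain diagram.

Cells whose region touches the image rectangle, or whose region extends into
masked raster area, are flagged as boundary cells: their truncated geometry
is excluded from morphometric summaries, while their counts still contribute
to density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

from .masking import MaskSet
from .optics import ImageRecord, pixel_to_global_degrees, signed_eccentricity

#: Minimum shared-edge length (px) for two regions to count as neighbours.
EDGE_LENGTH_TOL = 1e-9


class InsufficientPointsError(ValueError):
    """Fewer centroids than a planar Voronoi diagram requires."""


@dataclass(frozen=True)
class CellRecord:
    """Morphometry of one detected cell."""

    centroid_px: Tuple[float, float]
    centroid_deg: Tuple[float, float]
    eccentricity_deg: float
    area: float
    perimeter: float
    n_neighbors: int
    boundary_flag: bool


def _reflect_points(pts: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Mirror (x, y) points across the four edges of [lo, hi]^2."""
    left = pts.copy()
    left[:, 0] = 2 * lo - pts[:, 0]
    right = pts.copy()
    right[:, 0] = 2 * hi - pts[:, 0]
    down = pts.copy()
    down[:, 1] = 2 * lo - pts[:, 1]
    up = pts.copy()
    up[:, 1] = 2 * hi - pts[:, 1]
    return np.vstack([left, right, down, up])


def _polygon_area_perimeter(verts: np.ndarray) -> Tuple[float, float]:
    """Shoelace area and perimeter of a polygon given ordered vertices."""
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * yn - xn * y))
    perimeter = float(np.sum(np.hypot(xn - x, yn - y)))
    return float(area), perimeter


def clipped_voronoi(
    points: np.ndarray, lo: float, hi: float
) -> Tuple[list, np.ndarray, np.ndarray]:
    """Voronoi regions of ``points`` clipped exactly to the square [lo, hi]^2.

    Parameters
    ----------
    points:
        (N, 2) array of (x, y) generator positions, all inside the square.
    lo, hi:
        Bounds of the clipping square.

    Returns
    -------
    polygons : list of (M_i, 2) arrays
        Ordered vertices of each clipped region.
    n_neighbors : (N,) int array
        Number of regions sharing an edge of positive length with each cell.
    touches_rect : (N,) bool array
        Whether the clipped region touches the square boundary.
    neighbor_pairs : set of (i, j) tuples, i < j
        The undirected positive-edge-length adjacency graph.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 4:
        raise InsufficientPointsError(f"need at least 4 centroids, got {n}")
    aug = np.vstack([points, _reflect_points(points, lo, hi)])
    vor = Voronoi(aug)

    polygons = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            # Should not occur with mirrored augmentation; guard regardless.
            raise RuntimeError("unbounded Voronoi region for an interior point")
        verts = vor.vertices[region]
        # Regions are convex: order vertices by angle around the generator.
        ang = np.arctan2(verts[:, 1] - points[i, 1], verts[:, 0] - points[i, 0])
        polygons.append(verts[np.argsort(ang)])

    n_neighbors = np.zeros(n, dtype=int)
    touches_rect = np.zeros(n, dtype=bool)
    neighbor_pairs = set()
    for (a, b), rv in zip(vor.ridge_points, vor.ridge_vertices):
        a_real, b_real = a < n, b < n
        if not (a_real or b_real):
            continue
        if -1 in rv:
            length = np.inf
        else:
            v = vor.vertices[list(rv)]
            length = float(np.hypot(*(v[1] - v[0])))
        if length <= EDGE_LENGTH_TOL:
            continue
        if a_real and b_real:
            n_neighbors[a] += 1
            n_neighbors[b] += 1
            neighbor_pairs.add((min(a, b), max(a, b)))
        elif a_real:
            touches_rect[a] = True
        else:
            touches_rect[b] = True
    return polygons, n_neighbors, touches_rect, neighbor_pairs


def voronoi_morphometry(
    centroids_px: np.ndarray,
    masks: Optional[MaskSet],
    pixel_size_um: float,
    image: Optional[ImageRecord] = None,
) -> pd.DataFrame:
    """Tessellate detected centroids and measure every cell.

    Parameters
    ----------
    centroids_px:
        (N, 2) array of (row, col) centroid positions in pixels.
    masks:
        Mask layers of the image, or None.  When given, a cell whose region
        extends into non-mosaic raster area is flagged as a boundary cell.
    pixel_size_um:
        Retinal pixel size in micrometres; areas scale with its square.
    image:
        When given, global degree coordinates and signed eccentricity are
        attached to every cell; otherwise those columns are NaN.

    Returns
    -------
    pandas.DataFrame
        One row per cell: ``row_px, col_px, x_deg, y_deg, ecc_deg,
        area_um2, perimeter_um, n_neighbors, boundary_flag``.

    Notes
    -----
    Exact duplicate centroids are removed with a warning.  Regions are
    clipped to the image rectangle only; membership of a cell in the mosaic
    is decided by its centroid's raster position upstream, at detection.
    """
    centroids_px = np.asarray(centroids_px, dtype=float).reshape(-1, 2)
    uniq, idx = np.unique(centroids_px, axis=0, return_index=True)
    if len(uniq) < len(centroids_px):
        warnings.warn(
            f"removed {len(centroids_px) - len(uniq)} duplicate centroids",
            stacklevel=2,
        )
    centroids_px = centroids_px[np.sort(idx)]
    if len(centroids_px) < 4:
        raise InsufficientPointsError(
            f"need at least 4 centroids, got {len(centroids_px)}"
        )

    if masks is not None:
        n_px = masks.mosaic.shape[0]
    elif image is not None:
        n_px = image.n_px
    else:
        raise ValueError("either masks or image must be provided")

    # (x, y) = (col, row); pixel (r, c) is the unit square centred on it, so
    # the image rectangle spans [-0.5, n - 0.5] on each axis.
    pts_xy = centroids_px[:, ::-1]
    polygons, n_neighbors, touches_rect, _ = clipped_voronoi(pts_xy, -0.5, n_px - 0.5)

    areas = np.empty(len(pts_xy))
    perims = np.empty(len(pts_xy))
    boundary = touches_rect.copy()
    check_mask = masks is not None and not masks.mosaic.all()
    for i, poly in enumerate(polygons):
        areas[i], perims[i] = _polygon_area_perimeter(poly)
        if check_mask and not boundary[i]:
            cols = np.clip(np.rint(poly[:, 0]).astype(int), 0, n_px - 1)
            rows = np.clip(np.rint(poly[:, 1]).astype(int), 0, n_px - 1)
            if not masks.mosaic[rows, cols].all():
                boundary[i] = True

    df = pd.DataFrame(
        {
            "row_px": centroids_px[:, 0],
            "col_px": centroids_px[:, 1],
            "area_um2": areas * pixel_size_um**2,
            "perimeter_um": perims * pixel_size_um,
            "n_neighbors": n_neighbors,
            "boundary_flag": boundary,
        }
    )
    if image is not None:
        x, y = pixel_to_global_degrees(df["row_px"].to_numpy(), df["col_px"].to_numpy(), image)
        df["x_deg"], df["y_deg"] = x, y
        df["ecc_deg"] = signed_eccentricity(x, y)
    else:
        df["x_deg"] = df["y_deg"] = df["ecc_deg"] = np.nan
    return df[
        [
            "row_px",
            "col_px",
            "x_deg",
            "y_deg",
            "ecc_deg",
            "area_um2",
            "perimeter_um",
            "n_neighbors",
            "boundary_flag",
        ]
    ]
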