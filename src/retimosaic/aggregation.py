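"""Filtering and aggregation of per-cell morphometry.

The cascade applied to every acquisition:

1. images with more than 90% of their area masked are excluded outright;
2. the frame is divided into 256×256 px grid squares; cells are assigned to
   squares by centroid pixel, and only squares holding at least 200 cells
   are kept (small detection islands inside masked areas are unreliable);
3. for cone images only, cells within (−2.5°, 2.5°) of fixation are dropped
   (the instrument does not resolve the central cone mosaic);
4. retained grid summaries are quantized into 25 equal-width signed
   eccentricity bins and descriptor means/SDs are reported per bin.

Local density is a grid-square quantity: cells counted in the square over
the mosaic-visible area of the square, in cells/mm².
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .masking import MaskSet
from .optics import ImageRecord, pixel_to_global_degrees, signed_eccentricity

logger = logging.getLogger(__name__)

DEFAULT_GRID_PX = 256
DEFAULT_MIN_CELLS = 200
DEFAULT_MAX_MASKED_FRACTION = 0.90
DEFAULT_PR_EXCLUSION_DEG = 2.5
DEFAULT_N_BINS = 25
DEFAULT_ECC_RANGE = (-10.0, 10.0)

#: Morphometric descriptors carried through grid summaries and profiles.
DESCRIPTORS = ("local_density", "mean_area", "mean_perimeter", "mean_neighbors")


def exclude_overmasked(masks: MaskSet, max_masked_fraction: float = DEFAULT_MAX_MASKED_FRACTION) -> bool:
    """True when the image must be excluded: strictly more than 90% masked."""
    return masks.masked_fraction > max_masked_fraction


def grid_summaries(
    cells: pd.DataFrame,
    masks: MaskSet,
    image: ImageRecord,
    grid_px: int = DEFAULT_GRID_PX,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Summarize cells over grid squares, dropping sparse squares.

    Every cell is assigned to exactly one square by its centroid pixel.
    Squares with fewer than ``min_cells`` detected cells (boundary-flagged
    cells included — the filter targets detection counts) or with no
    mosaic-visible area are dropped.  Morphometric means use non-boundary
    cells only; ``local_density`` is cells per mm² of mosaic-visible area.
    """
    n = image.n_px
    if n % grid_px:
        raise ValueError(f"image size {n} not divisible by grid size {grid_px}")
    n_grid = n // grid_px
    px_mm = image.pixel_size_um / 1000.0

    gi = np.minimum(cells["row_px"].to_numpy() // grid_px, n_grid - 1).astype(int)
    gj = np.minimum(cells["col_px"].to_numpy() // grid_px, n_grid - 1).astype(int)

    # Mosaic-visible pixel count per square.
    vis = masks.mosaic.reshape(n_grid, grid_px, n_grid, grid_px).sum(axis=(1, 3))

    rows = []
    for i in range(n_grid):
        for j in range(n_grid):
            sel = (gi == i) & (gj == j)
            n_cells = int(sel.sum())
            if n_cells < min_cells:
                continue
            if vis[i, j] == 0:
                logger.info(
                    "dropping grid square (%d, %d) of %s: no visible area",
                    i, j, image.image_id,
                )
                continue
            area_mm2 = float(vis[i, j]) * px_mm**2
            sub = cells.loc[sel]
            interior = sub.loc[~sub["boundary_flag"].astype(bool)]
            cr = i * grid_px + (grid_px - 1) / 2.0
            cc = j * grid_px + (grid_px - 1) / 2.0
            x, y = pixel_to_global_degrees(cr, cc, image)
            rows.append(
                {
                    "image_id": image.image_id,
                    "grid_i": i,
                    "grid_j": j,
                    "x_deg": x,
                    "y_deg": y,
                    "ecc_deg": signed_eccentricity(x, y),
                    "n_cells": n_cells,
                    "visible_area_mm2": area_mm2,
                    "local_density": n_cells / area_mm2,
                    "mean_area": float(interior["area_um2"].mean()) if len(interior) else np.nan,
                    "mean_perimeter": float(interior["perimeter_um"].mean()) if len(interior) else np.nan,
                    "mean_neighbors": float(interior["n_neighbors"].mean()) if len(interior) else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "image_id", "grid_i", "grid_j", "x_deg", "y_deg", "ecc_deg",
            "n_cells", "visible_area_mm2", "local_density",
            "mean_area", "mean_perimeter", "mean_neighbors",
        ],
    )


def pr_central_exclusion(
    records: pd.DataFrame,
    modality: str = "PR",
    band_deg: float = DEFAULT_PR_EXCLUSION_DEG,
) -> pd.DataFrame:
    """Drop cone records strictly inside the central exclusion band.

    Applies only when ``modality == "PR"``: records with
    ``-band_deg < ecc_deg < band_deg`` are removed (the endpoints are kept).
    RPE records pass through untouched.  Idempotent.
    """
    if modality != "PR":
        return records
    ecc = records["ecc_deg"]
    keep = ~((ecc > -band_deg) & (ecc < band_deg))
    return records.loc[keep].reset_index(drop=True)


def eccentricity_profile(
    summaries: pd.DataFrame,
    descriptors: Sequence[str] = DESCRIPTORS,
    n_bins: int = DEFAULT_N_BINS,
    range_deg: Tuple[float, float] = DEFAULT_ECC_RANGE,
) -> pd.DataFrame:
    """Bin grid summaries into equal-width signed-eccentricity bins.

    Returns one row per bin with the bin centre, the number of summaries in
    the bin, and the mean and standard deviation of each descriptor.  Empty
    bins appear with count 0 and NaN statistics.  (Plots conventionally show
    the mean with an error bar two standard deviations wide.)
    """
    edges = np.linspace(range_deg[0], range_deg[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.digitize(summaries["ecc_deg"].to_numpy(), edges) - 1
    in_range = (idx >= 0) & (idx < n_bins)
    # Values exactly at the upper edge belong to the last bin.
    at_top = summaries["ecc_deg"].to_numpy() == edges[-1]
    idx[at_top] = n_bins - 1
    in_range |= at_top

    rows = []
    for b in range(n_bins):
        sel = summaries.loc[in_range & (idx == b)]
        row = {"bin": b, "ecc_center": centers[b], "ecc_lo": edges[b], "ecc_hi": edges[b + 1],
               "count": len(sel)}
        for d in descriptors:
            if len(sel):
                row[f"{d}_mean"] = float(sel[d].mean())
                row[f"{d}_std"] = float(sel[d].std(ddof=1)) if len(sel) > 1 else 0.0
            else:
                row[f"{d}_mean"] = np.nan
                row[f"{d}_std"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def density_heatmap(
    summaries: pd.DataFrame,
    descriptor: str = "local_density",
    bin_deg: float = 6.7 * DEFAULT_GRID_PX / 2048,
    range_deg: Tuple[float, float] = DEFAULT_ECC_RANGE,
    smoothing_sigma_bins: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-descriptor raster over the (x°, y°) plane with Gaussian smoothing.

    The raster resolution defaults to the grid-square angular pitch (the
    sampling distance), and the smoothing sigma defaults to one sampling
    distance.  Bins with no samples are NaN; smoothing is normalized over
    the populated support only, so it redistributes but does not create
    mass.

    Returns ``(grid, x_edges, y_edges)`` with ``grid[iy, ix]``.
    """
    lo, hi = range_deg
    edges = np.arange(lo, hi + bin_deg / 2, bin_deg)
    nb = len(edges) - 1
    sums = np.zeros((nb, nb))
    counts = np.zeros((nb, nb))
    ix = np.digitize(summaries["x_deg"].to_numpy(), edges) - 1
    iy = np.digitize(summaries["y_deg"].to_numpy(), edges) - 1
    ok = (ix >= 0) & (ix < nb) & (iy >= 0) & (iy < nb)
    np.add.at(sums, (iy[ok], ix[ok]), summaries[descriptor].to_numpy()[ok])
    np.add.at(counts, (iy[ok], ix[ok]), 1.0)
    with np.errstate(invalid="ignore"):
        mean = sums / counts
    if smoothing_sigma_bins > 0:
        support = counts > 0
        filled = np.where(support, mean, 0.0)
        num = ndimage.gaussian_filter(filled, smoothing_sigma_bins)
        den = ndimage.gaussian_filter(support.astype(float), smoothing_sigma_bins)
        with np.errstate(invalid="ignore"):
            sm = num / den
        mean = np.where(support, sm, np.nan)
    return mean, edges, edges


def match_rpe_pr_rectangles(
    rpe: pd.DataFrame,
    pr: pd.DataFrame,
    tol_deg: float = 6.7 * DEFAULT_GRID_PX / 2048 / 2,
    descriptors: Sequence[str] = DESCRIPTORS,
) -> pd.DataFrame:
    """Pair cone grid squares with RPE grid squares of the same eye.

    Pairs are matched one-to-one, nearest centroid first, while the centroid
    distance stays below ``tol_deg`` (default: half a grid-square width).
    Unmatched rectangles are dropped.  Each matched row reports the PR/RPE
    ratio of every descriptor and the RPE-square eccentricity for binning.
    """
    if len(rpe) == 0 or len(pr) == 0:
        warnings.warn("no rectangles to match", stacklevel=2)
        return pd.DataFrame(columns=["ecc_deg", *[f"{d}_ratio" for d in descriptors]])
    a = rpe[["x_deg", "y_deg"]].to_numpy()
    b = pr[["x_deg", "y_deg"]].to_numpy()
    tree = cKDTree(b)
    dist, nearest = tree.query(a, k=min(len(b), 8), distance_upper_bound=tol_deg)
    dist = np.atleast_2d(dist)
    nearest = np.atleast_2d(nearest)
    cand = [
        (dist[i, m], i, nearest[i, m])
        for i in range(len(a))
        for m in range(dist.shape[1])
        if np.isfinite(dist[i, m])
    ]
    cand.sort()
    used_a, used_b = set(), set()
    pairs = []
    for d, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, d))
    if not pairs:
        warnings.warn("no rectangle pairs within tolerance", stacklevel=2)
        return pd.DataFrame(columns=["ecc_deg", *[f"{d}_ratio" for d in descriptors]])
    rows = []
    for i, j, d in pairs:
        row = {
            "ecc_deg": float(rpe["ecc_deg"].iloc[i]),
            "distance_deg": d,
            "rpe_image_id": rpe["image_id"].iloc[i] if "image_id" in rpe else "",
            "pr_image_id": pr["image_id"].iloc[j] if "image_id" in pr else "",
        }
        for desc in descriptors:
            row[f"{desc}_ratio"] = float(pr[desc].iloc[j] / rpe[desc].iloc[i])
        rows.append(row)
    return pd.DataFrame(rows)
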